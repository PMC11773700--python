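# Methods

## The recognition model

The unit of recognition is the piRNA seed: a contiguous window of the
piRNA, 1-based inclusive positions `start..end`, default 1–10. The
default reflects teleost piRNA biology, where the first ten 5′
nucleotides of the PIWI-bound guide pair with the transposon transcript;
the window is fully configurable because narrower seeds (2–7, 2–8) are
reported in nematodes and mouse. A TE copy is called a target when its
own 5′→3′ sequence contains, within Hamming distance ≤ *k*, the reverse
complement of the seed (orientation `revcomp` — the antisense duplex).
An optional second orientation, `comp`, searches for the un-reversed
per-base complement of the seed; it is disabled by default and always
labelled separately in output, since the two readings make different
biological claims. Matching is substitution-only: no indels, no G:U
wobble, no thermodynamics. These are deliberate non-goals — the model is
a complementarity screen, not a duplex-energy predictor.

Sequences are normalized once on ingestion: whitespace stripped,
uppercased, U→T (piRNAs are RNA; references are DNA). `N` bases in a TE
never pair — an N under the matching window always counts as a mismatch,
and an N inside a seed is rejected — so assembly gaps cannot create
hits. Every occurrence is a distinct hit (one copy may contain several
sites); counting and enrichment de-duplicate to distinct TE records.

The scanner is a Hamming sliding window (vectorised mismatch counts over
all offsets). The *definition* of a hit, however, is enumeration: the set
of all sequences within Hamming distance ≤ *k* of the pattern
(cardinality Σ_{i=0..k} C(L,i)·3^i), located by exact substring search.
The test suite holds the two routes equal on randomized inputs; the
enumeration route also generates the truth tables for the synthetic
fixtures. Mismatch budgets are "up to k", so hit sets are monotone in
*k* — a property the suite asserts directly.

## Non-seed complementarity score

Each hit carries the percentage of piRNA positions *outside* the seed
window that pair with the TE at the geometry fixed by the seed match.
For a `revcomp` hit occupying `te[offset, offset+L)`, the duplex is
antiparallel: piRNA position `j > seed_end` pairs `te[offset − (j −
seed_end)]`, and `j < seed_start` pairs `te[offset + L − 1 + (seed_start
− j)]`. For `comp` the register mirrors. A position pairs when the TE
base is the exact Watson–Crick complement; positions that fall off the
end of the TE count as unpaired rather than shrinking the denominator,
so the score is monotone in true pairing and comparable across hits (a
hit at a TE edge cannot out-score an interior one by losing its hard
positions). The denominator is always `n − L`; a piRNA whose seed covers
the whole sequence scores 0.0 by convention. Scores are rounded to one
decimal, which is also their CSV serialization precision, making the
CSV round-trip bit-exact. Whether tail pairing should instead be
evaluated against genomic flanking sequence beyond the TE boundary is an
open modelling question; this implementation confines pairing to the
annotated TE.

## Family catalogue and classification

TE families group into seven classes — DNA, LTR, LINE, SINE, RC,
Satellite, Unclassified — via a curated catalogue of 42 family stems
(20 DNA, 9 LTR, 8 LINE, 2 SINE, 1 RC, 2 Satellite) checked against
RepeatMasker/Dfam naming for teleost genomes. Real RepeatMasker names
are compound ("hAT-Charlie", "Tc1-Mariner"), so lookup is
case-insensitive, treats `-` and `_` as equivalent, and matches a stem
anywhere in the family string, longest stem winning (this is what sends
"tRNA-V-RTE" to SINE rather than to LINE via its "RTE" suffix).
Anything unmatched is Unclassified — a first-class category that
participates in counting and enrichment.

## Enrichment test

Let T be the number of distinct TE records matched by the query and
O_c the number of those in class c. Under the null that matched records
are drawn as a simple random sample of the reference, O_c ~
Binomial(T, p_c) with p_c the class's share of reference records. The
reported P-value is the exact upper tail P(X ≥ O_c), computed in log
space (lgamma terms, max-shifted exponentiation, compensated summation)
— accurate to ≥12 significant digits against direct pmf summation for
n ≤ 1000, and cross-checked against an independent statistical library
in the tests. Classes with O_c = 0 report P = 1.0. The test is
one-sided (enrichment only) and uncorrected by default, matching the
single-threshold star annotation (P ≤ 0.05) in the plots; a Bonferroni
option over the ≤7 classes exists for callers who want it. Enrichment is
tested at class level; family counts are reported descriptively, since
class is the unit plotted and the family-level sample sizes in a
single-piRNA scan are typically tiny.

## Reference preparation

Coordinates are 0-based half-open everywhere (the native convention of
the rmsk table and BED), including CSV output. The prep chain is
rmsk TSV → BED6 (`NAME#CLASS/FAMILY` in the name column, order
preserved) → strand-aware extraction from the genome FASTA: plus-strand
records take the slice `[start, end)`, minus-strand records its reverse
complement, so stored sequences are always the TE's own 5′→3′ strand.
The GTF intermediate that full annotation pipelines insert between the
rmsk table and the BED carries no information the BED lacks, so it is
skipped. Headers are written in the dialect
`>NAME#CLASS/FAMILY::CHROM:START-END(STRAND)`; the parser also accepts
degraded headers (missing strand → `+`; missing locus → record counted
but not plotted; missing class/family → inferred from the name).
Chromosome-length tables accept both plain two-column files and
cytoBandIdeo band listings (length = max band end); a leading `chr` is
ignored when matching names, and display order in the ideogram plot is
numeric-aware natural sort.

## Synthetic fixtures

The generator emulates the full input surface: i.i.d.-composition
chromosomes (default uniform), TE copies of catalogued families placed
non-overlapping on both strands (round-robin across chromosomes, gaps
drawn multinomially from the slack; infeasible packings raise an error),
and the derived rmsk/BED/FASTA/length-table files, all byte-reproducible
from one seed. Defaults — 3 chromosomes × 10 kb, 8 families × 2 copies
of 150–400 bp, 3 piRNAs of 26–31 nt — are sized to exercise every code
path (all orientations, both strands, multiple classes) while keeping a
full simulate-scan-validate cycle under a second. Planted sites edit the
genome through the TE's strand and the TE FASTA is re-extracted, so all
files stay mutually consistent; the default plan plants three antisense
0-mismatch sites plus one `comp`-orientation site and one 1-mismatch
site, the latter two invisible at the default scan settings by design.
Crucially, ground truth is *not* the plan: it is recomputed by the
brute-force oracle over the final sequences, so chance background
matches are part of the truth and scan↔truth equality is exact rather
than probabilistic. What the fixtures deliberately do not emulate —
TE nesting, fragmentation, divergence decay, non-uniform insertion
preference — limits what passing tests say about real genomes: they
certify the algorithmic contract, not annotation-quality robustness.

## Numerical and interface choices

- Hit order is (piRNA order, reference order, offset, revcomp-before-
  comp); all outputs inherit it, making CSVs byte-deterministic.
- The hits CSV schema is fixed:
  `pirna_name, pirna_sequence, te_name, te_family, te_class, chrom,
  start, end, te_strand, match_offset, orientation, seed_mismatches,
  complementarity_percent`, RFC 4180 quoting, empty locus fields for
  records without coordinates.
- Bar charts draw only classes with observed > 0 and star P ≤ 0.05 (a
  single tier — the only threshold the method defines); all-zero input
  raises rather than rendering an empty plot. Ideogram marks sit at TE
  interval midpoints, symmetric for long elements.
- CLI defaults equal the method defaults (seed 1–10, zero mismatches,
  antisense only); batch piRNA inputs skip too-short sequences with a
  warning, while a single explicit sequence that cannot carry the window
  is an error.

## Known limitations

Single-threaded pure-Python/numpy scanning: fine for seed-scale patterns
against repeat libraries (~10⁵ copies in seconds), not a genome-wide
aligner. No expression layer: predictions are genomic complementarity,
silent about whether either partner is transcribed in a tissue of
interest. The binomial null ignores TE length and copy-number structure
(longer copies offer more windows); distinct-record counting softens but
does not remove this.
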