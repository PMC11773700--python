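"""Deterministic synthetic fixtures: genome, TE annotation, piRNAs, truth.

The generator emulates the full input surface of the pipeline — a small
multi-chromosome genome, an rmsk-style annotation of TE copies drawn from
catalogued families on both strands, the derived BED and strand-corrected
TE FASTA, a chromosome-length table, and a piRNA set with *planted* seed
complementarity sites — so every stage is testable without downloads.

Ground truth is not the planting plan: after all edits, the expected hit
set is recomputed with the brute-force oracle over the final sequences, so
accidental background matches are part of the truth and exact scan↔truth
equality is a meaningful, non-flaky property.

Everything derives from ``rng_seed``: the same seed yields byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigInfeasible
from .oracle import oracle_scan
from .reference import (
    BedRecord,
    RmskRow,
    TERecord,
    classify_family,
    extract_te_sequences,
    rmsk_to_bed,
    write_bed,
    write_te_fasta,
)
from .report import export_csv
from .scan import COMP, REVCOMP, MatchHit, PiRNA
from .seqcore import SeedSpec, complement, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    """One planted seed-complementarity site: which piRNA into which TE."""

    pirna_index: int
    te_index: int
    orientation: str = REVCOMP  # "revcomp" or "comp"
    mismatches: int = 0         # exact substitutions applied to the pattern


def default_plan() -> tuple[PlantedSite, ...]:
    # revcomp 0-mm sites for every piRNA, one comp-orientation site and one
    # 1-mismatch site; the latter two are invisible at the default
    # revcomp-only / zero-mismatch scan, which makes them useful probes for
    # the "both"-orientation and k>=1 settings.
    return (
        PlantedSite(0, 0, REVCOMP, 0),
        PlantedSite(0, 5, REVCOMP, 0),
        PlantedSite(1, 8, REVCOMP, 0),
        PlantedSite(1, 11, COMP, 0),
        PlantedSite(2, 14, REVCOMP, 1),
    )


@dataclass(frozen=True)
class SimConfig:
    """Fixture parameters; defaults give a small but fully featured bundle.

    3 chromosomes of 10 kb carry 2 copies each of 8 catalogued families
    (16 TEs of 150–400 bp, both strands), scanned by 3 piRNAs of 26–31 nt —
    typical teleost piRNA lengths — with the default 1–10 seed window.
    """

    rng_seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 10_000
    te_families: tuple[str, ...] = (
        "Gypsy", "L1", "hAT", "Helitron", "Alu", "MOSAT", "Copia", "Tc1",
    )
    n_te_per_family: int = 2
    te_length_range: tuple[int, int] = (150, 400)
    n_pirnas: int = 3
    pirna_length_range: tuple[int, int] = (26, 31)
    seed_spec: SeedSpec = field(default_factory=SeedSpec)
    planted_sites: tuple[PlantedSite, ...] = field(default_factory=default_plan)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length, self.n_te_per_family,
               self.n_pirnas) < 0:
            raise ValueError("counts and lengths must be non-negative")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for site in self.planted_sites:
            if site.mismatches >= self.seed_spec.length:
                raise ValueError("planted mismatches must be below the seed length")
            if site.orientation not in (REVCOMP, COMP):
                raise ValueError(f"unknown orientation {site.orientation!r}")
            if site.pirna_index >= self.n_pirnas:
                raise ValueError("planted site references a nonexistent piRNA")

    @property
    def n_te(self) -> int:
        return len(self.te_families) * self.n_te_per_family


@dataclass
class ReferenceBundle:
    """Paths and parsed content of a generated reference."""

    outdir: Path
    genome_fasta: Path
    rmsk_tsv: Path
    bed: Path
    te_fasta: Path
    chrom_table: Path
    chrom_names: list[str]
    bed_records: list[BedRecord]
    te_records: list[TERecord]


@dataclass
class SimBundle(ReferenceBundle):
    """A reference bundle plus planted piRNAs and oracle truth."""

    pirna_fasta: Path = None  # type: ignore[assignment]
    truth_csv: Path = None    # type: ignore[assignment]
    pirnas: list[PiRNA] = field(default_factory=list)
    truth: list[MatchHit] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, length: int,
                composition: Sequence[float]) -> str:
    idx = rng.choice(4, size=length, p=list(composition))
    return _BASES[idx].tobytes().decode("ascii")


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def _rmsk_line(bin_: int, row: RmskRow) -> str:
    # full 17-column UCSC layout; unused numeric columns zero-filled
    return "\t".join(str(x) for x in (
        bin_, 0, 0, 0, 0, row.genoName, row.genoStart, row.genoEnd, 0,
        row.strand, row.repName, row.repClass, row.repFamily, 0, 0, 0, bin_,
    ))


_RMSK_HEADER = "\t".join((
    "#bin", "swScore", "milliDiv", "milliDel", "milliIns", "genoName",
    "genoStart", "genoEnd", "genoLeft", "strand", "repName", "repClass",
    "repFamily", "repStart", "repEnd", "repLeft", "id",
))


def generate_reference(config: SimConfig, outdir: str | Path) -> ReferenceBundle:
    """Write a synthetic genome + TE annotation bundle under ``outdir``.

    TE copies are placed non-overlapping (random gaps from the remaining
    slack), assigned round-robin to chromosomes, with random strands.
    Raises :class:`ConfigInfeasible` when the copies cannot be packed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.rng_seed % (2**31), 11])

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {name: _random_dna(rng, config.chromosome_length, config.base_composition)
              for name in chrom_names}

    # one (family, copy) list, round-robin over chromosomes
    te_plan: list[tuple[str, int]] = [
        (family, copy)
        for copy in range(config.n_te_per_family)
        for family in config.te_families
    ]
    lo, hi = config.te_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in te_plan]
    strands = [rng.choice(["+", "-"]) for _ in te_plan]

    per_chrom: dict[str, list[int]] = {name: [] for name in chrom_names}
    for i in range(len(te_plan)):
        per_chrom[chrom_names[i % len(chrom_names)]].append(i)

    placements: dict[int, tuple[str, int, int]] = {}
    for chrom, indices in per_chrom.items():
        total = sum(lengths[i] for i in indices)
        slack = config.chromosome_length - total
        if slack < 0:
            raise ConfigInfeasible(
                f"cannot place {len(indices)} TEs totalling {total} bp on "
                f"{chrom} of length {config.chromosome_length}")
        gaps = rng.multinomial(slack, [1.0 / (len(indices) + 1)] * (len(indices) + 1)) \
            if indices else []
        cursor = 0
        for g, i in zip(gaps, indices):
            cursor += int(g)
            placements[i] = (chrom, cursor, cursor + lengths[i])
            cursor += lengths[i]

    rows: list[RmskRow] = []
    for i, (family, copy) in enumerate(te_plan):
        chrom, start, end = placements[i]
        rows.append(RmskRow(
            genoName=chrom, genoStart=start, genoEnd=end, strand=str(strands[i]),
            repName=f"{family}-{copy + 1}_SYN", repClass=classify_family(family),
            repFamily=family,
        ))
    rows.sort(key=lambda r: (chrom_names.index(r.genoName), r.genoStart))

    genome_fasta = outdir / "genome.fa"
    rmsk_tsv = outdir / "te_rmsk.tsv"
    bed_path = outdir / "te_annotation.bed"
    te_fasta = outdir / "te_sequences.fa"
    chrom_table = outdir / "chrom_lengths.txt"

    _write_fasta(genome, genome_fasta)
    with open(rmsk_tsv, "w") as fh:
        fh.write(_RMSK_HEADER + "\n")
        for i, row in enumerate(rows):
            fh.write(_rmsk_line(i, row) + "\n")
    bed_records = rmsk_to_bed(rows)
    write_bed(bed_records, bed_path)
    te_records = extract_te_sequences(genome_fasta, bed_records)
    write_te_fasta(te_records, te_fasta)
    with open(chrom_table, "w") as fh:
        for name in chrom_names:
            fh.write(f"{name}\t{config.chromosome_length}\n")

    return ReferenceBundle(
        outdir=outdir, genome_fasta=genome_fasta, rmsk_tsv=rmsk_tsv,
        bed=bed_path, te_fasta=te_fasta, chrom_table=chrom_table,
        chrom_names=chrom_names, bed_records=bed_records, te_records=te_records,
    )


def _apply_mismatches(pattern: str, m: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``m`` positions, each to a different base."""
    if m == 0:
        return pattern
    positions = rng.choice(len(pattern), size=m, replace=False)
    chars = list(pattern)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def plant_and_truth(config: SimConfig, bundle: ReferenceBundle) -> SimBundle:
    """Generate piRNAs, plant their seed sites into the genome, compute truth.

    Each planted site rewrites the target TE's own-strand sequence to carry
    the (possibly mutated) reverse complement or complement of the piRNA
    seed at a random offset; the edit is mapped back through the strand to
    the genome, the genome FASTA is rewritten and the TE FASTA re-extracted,
    so all bundle files stay mutually consistent. Truth is the oracle scan
    of the final sequences at ``config.seed_spec``.
    """
    rng = np.random.default_rng([config.rng_seed % (2**31), 23])
    spec = config.seed_spec

    lo, hi = config.pirna_length_range
    if lo < spec.end:
        raise ConfigInfeasible(
            f"piRNA length range {config.pirna_length_range} cannot cover the "
            f"seed window ending at {spec.end}")
    pirnas = [
        PiRNA(name=f"syn-piRNA-{i + 1}",
              sequence=_random_dna(rng, int(rng.integers(lo, hi + 1)),
                                   config.base_composition))
        for i in range(config.n_pirnas)
    ]

    genome = {k: list(v) for k, v in _read_fasta(bundle.genome_fasta).items()}
    for site in config.planted_sites:
        if site.te_index >= len(bundle.te_records):
            raise ConfigInfeasible(
                f"planted site references TE index {site.te_index} "
                f"but only {len(bundle.te_records)} TEs exist")
        te = bundle.te_records[site.te_index]
        seed = pirnas[site.pirna_index].sequence[spec.start - 1 : spec.end]
        pattern = reverse_complement(seed) if site.orientation == REVCOMP \
            else complement(seed)
        pattern = _apply_mismatches(pattern, site.mismatches, rng)
        L = len(pattern)
        te_len = te.end - te.start
        if L > te_len:
            raise ConfigInfeasible(
                f"seed pattern of length {L} does not fit TE {te.name} "
                f"({te_len} bp)")
        offset = int(rng.integers(0, te_len - L + 1))
        if te.strand == "+":
            g_start = te.start + offset
            genome[te.chrom][g_start : g_start + L] = list(pattern)
        else:
            # TE coordinate offset o maps to genome [end-o-L, end-o)
            g_start = te.end - offset - L
            genome[te.chrom][g_start : g_start + L] = list(reverse_complement(pattern))

    _write_fasta({k: "".join(v) for k, v in genome.items()}, bundle.genome_fasta)
    te_records = extract_te_sequences(bundle.genome_fasta, bundle.bed_records)
    write_te_fasta(te_records, bundle.te_fasta)

    pirna_fasta = bundle.outdir / "pirnas.fa"
    _write_fasta({p.name: p.sequence for p in pirnas}, pirna_fasta)

    truth = oracle_scan(pirnas, te_records, spec)
    truth_csv = bundle.outdir / "truth.csv"
    export_csv(truth, truth_csv)

    return SimBundle(
        outdir=bundle.outdir, genome_fasta=bundle.genome_fasta,
        rmsk_tsv=bundle.rmsk_tsv, bed=bundle.bed, te_fasta=bundle.te_fasta,
        chrom_table=bundle.chrom_table, chrom_names=bundle.chrom_names,
        bed_records=bundle.bed_records, te_records=te_records,
        pirna_fasta=pirna_fasta, truth_csv=truth_csv,
        pirnas=pirnas, truth=truth,
    )


def simulate(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Full fixture pipeline: reference generation plus planting and truth."""
    return plant_and_truth(config, generate_reference(config, outdir))
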