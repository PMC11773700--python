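"""Scan one piRNA against a small in-memory TE reference.

The query is a 28-nt zebrafish piRNA (dre-piRNA-589795). Its default seed
is the first ten nucleotides, TACACGAAGA; a TE silenced by this piRNA
carries the reverse complement of that seed, TCTTCGTGTA, somewhere on its
own 5'→3' strand. Here one of three TE copies does.
"""

from pitescan import PiRNA, SeedSpec, TERecord, reverse_complement, scan_pirna

pirna = PiRNA("dre-piRNA-589795", "TACACGAAGACTGTGGTGTGATTGGGCG")
spec = SeedSpec()  # seed 1-10, zero mismatches, antisense (revcomp) only

site = reverse_complement(pirna.sequence[:10])
reference = [
    TERecord("Gypsy-12", "Gypsy", "LTR", "chr4", 1000, 1021, "+",
             sequence="CATG" + site + "TTACGGA"),
    TERecord("L1-2", "L1", "LINE", "chr1", 500, 530, "+", sequence="ACGT" * 7 + "AC"),
    TERecord("hAT-3", "hAT", "DNA", "chr2", 40, 70, "-", sequence="TTGA" * 7 + "CC"),
]

print(f"piRNA seed (positions 1-10): {pirna.sequence[:10]}")
print(f"antisense pattern searched:  {site}")
for hit in scan_pirna(pirna, reference, spec):
    print(f"hit: {hit.te.name} ({hit.te.te_class}) at offset {hit.offset}, "
          f"{hit.seed_mismatches} mismatches, "
          f"non-seed complementarity {hit.complementarity_percent}%")

# Expected output: exactly one hit, in Gypsy-12 at offset 4 with 0
# mismatches. The complementarity percentage scores how much of the piRNA
# *outside* the seed also pairs with this TE copy (5.6% here — 1 of the 18
# tail positions pairs by chance; the flanks were not designed to pair).
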