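"""Native reference preparation: rmsk table -> BED6 -> strand-aware TE FASTA.

Builds a toy genome and a two-row RepeatMasker table dump, then runs the
same chain used for a real genome: parse the rmsk dump, emit BED6, extract
each TE's own-strand sequence from the genome, and write a TE FASTA whose
headers carry name, class/family, interval and strand.
"""

import tempfile
from pathlib import Path

from pitescan import (
    extract_te_sequences,
    load_te_fasta,
    parse_rmsk,
    rmsk_to_bed,
    write_bed,
    write_te_fasta,
)

HEADER = ("#bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\tgenoStart\t"
          "genoEnd\tgenoLeft\tstrand\trepName\trepClass\trepFamily\t"
          "repStart\trepEnd\trepLeft\tid\n")


def rmsk_row(chrom, start, end, strand, name, cls, fam):
    return "\t".join(map(str, [0, 0, 0, 0, 0, chrom, start, end, 0, strand,
                               name, cls, fam, 0, 0, 0, 0])) + "\n"


with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "genome.fa").write_text(">chr1\nAACCGGTTAACCGGTTAACC\n")
    (tmp / "rmsk.tsv").write_text(
        HEADER
        + rmsk_row("chr1", 2, 10, "+", "Gypsy-1", "LTR", "Gypsy")
        + rmsk_row("chr1", 12, 19, "-", "hAT-1", "DNA", "hAT"))

    beds = rmsk_to_bed(parse_rmsk(tmp / "rmsk.tsv"))
    write_bed(beds, tmp / "te.bed")
    print("BED6:")
    for b in beds:
        print(" ", b.to_line())

    records = extract_te_sequences(tmp / "genome.fa", beds)
    write_te_fasta(records, tmp / "te.fa")
    print("\nTE FASTA records (minus-strand sequences are reverse-complemented):")
    for rec in load_te_fasta(tmp / "te.fa"):
        print(f"  >{rec.header()}")
        print(f"  {rec.sequence}")

# The minus-strand hAT-1 sequence reads as the reverse complement of the
# genome slice chr1:12-19, i.e. the transposon's own transcript-sense
# strand — the strand a piRNA seed match is evaluated on.
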