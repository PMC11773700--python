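"""TE reference model: classification, header parsing, and reference prep.

A TE reference is a FASTA of individual repeat copies whose headers carry
the repeat name, RepeatMasker-style class/family, genomic interval and
strand. The canonical header dialect written (and preferred on read) is::

    >NAME#CLASS/FAMILY::CHROM:START-END(STRAND)

which is what strand-aware, name-keyed interval extraction from a BED6
annotation produces (``bedtools getfasta -s -name`` semantics). Parsing is
tolerant: a missing ``(STRAND)`` defaults to ``+``; a missing locus leaves
the record usable for counting but excluded from chromosomal plots; a
missing ``#CLASS/FAMILY`` infers the family from the name.

Coordinates are 0-based half-open (BED/rmsk native) everywhere, including
CSV output.

The family → class assignment table maps RepeatMasker/Dfam family stems to
the seven classes used for counting and enrichment: DNA, LTR, LINE, SINE,
RC, Satellite, Unclassified.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from pyfaidx import Fasta

from .errors import (
    EmptyReference,
    HeaderParseError,
    IntervalOutOfBounds,
    MalformedRow,
    UnknownChromosome,
)
from .seqcore import normalize, reverse_complement

logger = logging.getLogger(__name__)

#: Deterministic class order used in counting, enrichment and plots.
CLASS_ORDER = ("DNA", "LTR", "LINE", "SINE", "RC", "Satellite", "Unclassified")

UNCLASSIFIED = "Unclassified"

# Family stems per class, as curated against RepeatMasker/Dfam for teleost
# genomes. Lookup is case-insensitive, treats '-' and '_' as equivalent,
# and matches a stem anywhere inside a compound family string
# (e.g. "hAT-Charlie" -> DNA via "hAT"); the longest matching stem wins
# (e.g. "tRNA-V-RTE" -> SINE, not LINE via "RTE").
_FAMILY_TABLE: dict[str, tuple[str, ...]] = {
    "DNA": (
        "hAT", "Tc1", "Tc-Mar", "Harbinger", "Enspm", "Kolobok", "Merlin",
        "Crypton", "PiggyBac", "Dada", "Zatar", "Ginger", "TDR", "Polinton",
        "Maverick", "Acrobat", "Looper", "TZF", "Angel", "Mariner",
    ),
    "LTR": (
        "Gypsy", "DIRS", "Ngaro", "ERV", "Pao", "Copia", "BEL", "HERV",
        "Bhikari",
    ),
    "LINE": (
        "L1", "L2", "L1-Tx1", "Rex-Babar", "RTE", "Penelope", "Keno", "Rex",
    ),
    "SINE": ("Alu", "tRNA-V-RTE"),
    "RC": ("Helitron",),
    "Satellite": ("BRSATI", "MOSAT"),
}


def _norm_token(s: str) -> str:
    return s.strip().lower().replace("_", "-")


# (normalized stem, original stem, class), longest stems first so that the
# most specific match wins.
_STEM_INDEX: list[tuple[str, str, str]] = sorted(
    (
        (_norm_token(stem), stem, cls)
        for cls, stems in _FAMILY_TABLE.items()
        for stem in stems
    ),
    key=lambda t: len(t[0]),
    reverse=True,
)


def table1_catalogue() -> dict[str, list[str]]:
    """The family → class assignment table, as class → list of family stems."""
    return {cls: list(stems) for cls, stems in _FAMILY_TABLE.items()}


def match_family(family: str) -> Optional[tuple[str, str]]:
    """Return ``(stem, te_class)`` for the longest stem contained in ``family``.

    ``None`` when no catalogued stem matches.
    """
    needle = _norm_token(family)
    if not needle:
        return None
    for norm_stem, stem, cls in _STEM_INDEX:
        if norm_stem in needle:
            return stem, cls
    return None


def classify_family(family: str) -> str:
    """TE class for a family string, or ``Unclassified``."""
    hit = match_family(family)
    return hit[1] if hit else UNCLASSIFIED


@dataclass(frozen=True)
class TERecord:
    """One TE copy from the reference.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``sequence`` is the TE's own 5'→3' strand (i.e. reverse-complemented
    relative to the genome when ``strand`` is '-'). Records lacking a
    parseable locus have ``chrom``/``start``/``end`` set to ``None``.
    """

    name: str
    family: str
    te_class: str
    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: str
    sequence: str

    @property
    def has_locus(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None

    @property
    def midpoint(self) -> Optional[float]:
        if not self.has_locus:
            return None
        return (self.start + self.end) / 2

    def header(self) -> str:
        """Render the canonical FASTA header (without '>')."""
        head = f"{self.name}#{self.te_class}/{self.family}"
        if self.has_locus:
            head += f"::{self.chrom}:{self.start}-{self.end}({self.strand})"
        return head


_LOCUS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?:\((?P<strand>[+-])\))?$")


def parse_te_header(header: str) -> TERecord:
    """Parse a TE FASTA header into a :class:`TERecord` (sequence left empty).

    Accepts the canonical dialect and degrades gracefully when the locus,
    strand or class/family annotations are absent.
    """
    text = header[1:] if header.startswith(">") else header
    text = text.split()[0] if text.split() else ""
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand = "+"
    name_part = text
    if "::" in text:
        name_part, locus_part = text.rsplit("::", 1)
        m = _LOCUS_RE.match(locus_part)
        if m:
            chrom = m.group("chrom")
            start = int(m.group("start"))
            end = int(m.group("end"))
            if m.group("strand"):
                strand = m.group("strand")
        else:
            logger.warning("unparseable locus %r in header %r; kept without locus",
                           locus_part, header)
    if "#" in name_part:
        name, classfam = name_part.split("#", 1)
        if "/" in classfam:
            class_token, family = classfam.split("/", 1)
        else:
            class_token, family = classfam, classfam
        te_class = classify_family(family)
        if te_class == UNCLASSIFIED:
            # fall back on the header's own class token when the family
            # stem is not in the catalogue but the class label is standard
            for cls in CLASS_ORDER:
                if _norm_token(class_token) == _norm_token(cls):
                    te_class = cls
                    break
    else:
        name = name_part
        hit = match_family(name)
        family = hit[0] if hit else name
        te_class = hit[1] if hit else UNCLASSIFIED
    if not name:
        raise HeaderParseError(f"empty repeat name in header {header!r}")
    return TERecord(name=name, family=family, te_class=te_class, chrom=chrom,
                    start=start, end=end, strand=strand, sequence="")


def load_te_fasta(path: str | Path) -> list[TERecord]:
    """Load a TE reference FASTA into a list of :class:`TERecord`.

    Sequences are normalized (uppercase, U→T); record order is preserved.
    Raises :class:`EmptyReference` on a file with no records; header or
    sequence errors are re-raised naming the offending record index.
    """
    records: list[TERecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            parsed = parse_te_header(rec.description)
            records.append(replace(parsed, sequence=normalize(str(rec.seq))))
        except Exception as exc:
            raise type(exc)(f"record {i} ({rec.id!r}): {exc}") from exc
    if not records:
        raise EmptyReference(f"no FASTA records in {path}")
    n_uncl = sum(1 for r in records if r.te_class == UNCLASSIFIED)
    logger.info("loaded %d TE records from %s (%d Unclassified)",
                len(records), path, n_uncl)
    return records


# ---------------------------------------------------------------------------
# Native reference preparation: rmsk table -> BED6 -> strand-aware TE FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmskRow:
    """One repeat copy from a UCSC RepeatMasker (rmsk) table dump."""

    genoName: str
    genoStart: int  # 0-based
    genoEnd: int
    strand: str
    repName: str
    repClass: str
    repFamily: str


@dataclass(frozen=True)
class BedRecord:
    """A BED6 interval naming one TE copy as NAME#CLASS/FAMILY."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str

    def to_line(self) -> str:
        return f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t{self.score}\t{self.strand}"


def parse_rmsk(path: str | Path) -> Iterator[RmskRow]:
    """Stream rows from an rmsk TSV dump.

    Handles the 17-column dump (leading ``bin`` column) and the 16-column
    variant without it; a header line containing ``genoName`` is skipped.
    RepeatMasker's 'C' strand notation is mapped to '-'.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if "genoName" in fields:
                continue
            if len(fields) >= 17:
                idx = {"genoName": 5, "genoStart": 6, "genoEnd": 7,
                       "strand": 9, "repName": 10, "repClass": 11, "repFamily": 12}
            elif len(fields) >= 16:
                idx = {"genoName": 4, "genoStart": 5, "genoEnd": 6,
                       "strand": 8, "repName": 9, "repClass": 10, "repFamily": 11}
            else:
                raise MalformedRow(lineno, f"expected >=16 rmsk columns, got {len(fields)}")
            try:
                start = int(fields[idx["genoStart"]])
                end = int(fields[idx["genoEnd"]])
            except ValueError:
                raise MalformedRow(lineno, "non-integer genoStart/genoEnd") from None
            strand = fields[idx["strand"]]
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise MalformedRow(lineno, f"invalid strand {strand!r}")
            if start >= end:
                raise MalformedRow(lineno, f"empty or inverted interval {start}-{end}")
            yield RmskRow(
                genoName=fields[idx["genoName"]],
                genoStart=start,
                genoEnd=end,
                strand=strand,
                repName=fields[idx["repName"]],
                repClass=fields[idx["repClass"]],
                repFamily=fields[idx["repFamily"]],
            )


def rmsk_to_bed(rows: Iterable[RmskRow]) -> list[BedRecord]:
    """Convert rmsk rows to BED6, keeping 0-based coordinates and input order."""
    return [
        BedRecord(
            chrom=r.genoName,
            start=r.genoStart,
            end=r.genoEnd,
            name=f"{r.repName}#{r.repClass}/{r.repFamily}",
            score=0,
            strand=r.strand,
        )
        for r in rows
    ]


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read a BED6 file as written by :func:`write_bed`."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise MalformedRow(lineno, f"expected 6 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise MalformedRow(lineno, "non-integer BED coordinates") from None
            out.append(BedRecord(fields[0], start, end, fields[3], int(fields[4]), fields[5]))
    return out


def extract_te_sequences(genome_fasta: str | Path,
                         bed_records: Iterable[BedRecord]) -> list[TERecord]:
    """Strand-aware extraction of TE sequences from a genome FASTA.

    Plus-strand intervals yield the genome slice [start, end); minus-strand
    intervals yield its reverse complement, so every returned sequence is
    the TE's own 5'→3' strand.
    """
    fa = Fasta(str(genome_fasta), rebuild=True, build_index=True)
    out: list[TERecord] = []
    for rec in bed_records:
        if rec.chrom not in fa:
            raise UnknownChromosome(
                f"chromosome {rec.chrom!r} (record {rec.name!r}) not in {genome_fasta}")
        chrom_len = len(fa[rec.chrom])
        if rec.end > chrom_len or rec.start < 0:
            raise IntervalOutOfBounds(
                f"interval {rec.chrom}:{rec.start}-{rec.end} (record {rec.name!r}) "
                f"exceeds chromosome length {chrom_len}")
        seq = normalize(str(fa[rec.chrom][rec.start:rec.end]))
        if rec.strand == "-":
            seq = reverse_complement(seq)
        parsed = parse_te_header(f">{rec.name}")
        out.append(replace(parsed, chrom=rec.chrom, start=rec.start, end=rec.end,
                           strand=rec.strand, sequence=seq))
    fa.close()
    return out


def write_te_fasta(records: Iterable[TERecord], path: str | Path, width: int = 60) -> None:
    """Write TE records as FASTA with canonical headers."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.header()}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Chromosome-length tables (for ideogram plots)
# ---------------------------------------------------------------------------

class ChromTable:
    """Ordered mapping of chromosome name → length in bases.

    Lookup strips a leading ``chr`` so TE loci annotated as ``4`` match a
    table entry ``chr4`` (and vice versa); the display name as read is
    preserved for plotting.
    """

    def __init__(self, lengths: dict[str, int]):
        for name, length in lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        self._lengths = dict(lengths)
        self._by_key = {self._key(name): name for name in lengths}

    @staticmethod
    def _key(name: str) -> str:
        low = name.lower()
        return low[3:] if low.startswith("chr") else low

    def display_name(self, chrom: str) -> Optional[str]:
        return self._by_key.get(self._key(chrom))

    def get(self, chrom: str) -> Optional[int]:
        name = self.display_name(chrom)
        return None if name is None else self._lengths[name]

    def __contains__(self, chrom: str) -> bool:
        return self._key(chrom) in self._by_key

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self):
        return self._lengths.items()

    def names(self) -> list[str]:
        return list(self._lengths)


def parse_chrom_lengths(path: str | Path) -> ChromTable:
    """Parse a chromosome-length table.

    Accepts both a plain two-column (chrom, length) file and a
    cytoBandIdeo-style band table (chrom, bandStart, bandEnd, ...), in
    which case the length of a chromosome is the maximum band end seen.
    """
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise MalformedRow(lineno, "expected at least 2 columns")
            chrom = fields[0]
            band_style = False
            if len(fields) >= 3:
                try:
                    int(fields[1])
                    end = int(fields[2])
                    band_style = True
                except ValueError:
                    band_style = False
            if band_style:
                value = end
            else:
                try:
                    value = int(fields[1])
                except ValueError:
                    raise MalformedRow(lineno, f"non-numeric length {fields[1]!r}") from None
            if value <= 0:
                raise MalformedRow(lineno, f"non-positive length {value}")
            lengths[chrom] = max(lengths.get(chrom, 0), value)
    return ChromTable(lengths)


def natural_sort_key(name: str):
    """Numeric-aware sort key: chr2 before chr10."""
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", name)]
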