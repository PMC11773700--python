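"""Seed-complementarity scanning of piRNAs against a TE reference.

A piRNA silences a transposon transcript through base-pairing of its
5'-proximal seed (positions 1–10 by default) with the target. On the TE's
own 5'→3' sequence this canonical antisense duplex appears as the
*reverse complement* of the seed — orientation ``revcomp``. The optional
second orientation, ``comp``, searches for the un-reversed per-base
complement of the seed (the "reverse complement" checkbox semantics of
GUI-style piRNA tools); it is off by default.

Each occurrence (TE record × offset × orientation) is a distinct
:class:`MatchHit` carrying its exact Hamming distance and a non-seed
complementarity percentage; downstream counting de-duplicates to distinct
TE records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import EmptyReference, OffsetOutOfRange, SeedOutOfRange
from .reference import TERecord
from .seqcore import (
    BOTH,
    SeedSpec,
    complement,
    extract_seed,
    find_approx,
    hamming,
    normalize,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: Orientation labels. ``revcomp``: reverse complement of the seed found on
#: the TE 5'→3' strand (antisense duplex). ``comp``: un-reversed complement.
REVCOMP = "revcomp"
COMP = "comp"
_ORIENTATION_RANK = {REVCOMP: 0, COMP: 1}


@dataclass(frozen=True)
class PiRNA:
    """A named piRNA sequence, stored 5'→3' in DNA alphabet."""

    name: str
    sequence: str

    @classmethod
    def from_raw(cls, name: str, raw_sequence: str) -> "PiRNA":
        return cls(name=name, sequence=normalize(raw_sequence))


def load_pirna_fasta(path: str | Path) -> list[PiRNA]:
    """Load piRNAs from a FASTA file (piRBase-style names)."""
    pirnas = [PiRNA.from_raw(rec.id, str(rec.seq))
              for rec in SeqIO.parse(str(path), "fasta")]
    if not pirnas:
        raise EmptyReference(f"no piRNA records in {path}")
    return pirnas


@dataclass(frozen=True)
class MatchHit:
    """One seed match of a piRNA inside one TE copy.

    ``offset`` is the 0-based position of the matched window on the TE's
    own 5'→3' sequence; ``seed_mismatches`` the exact Hamming distance;
    ``complementarity_percent`` the fraction of non-seed piRNA positions
    that pair with the TE, as a percentage rounded to one decimal.
    """

    pirna_name: str
    pirna_sequence: str
    te: TERecord
    offset: int
    orientation: str
    seed_mismatches: int
    complementarity_percent: float


def complementarity_percent(pirna_sequence: str, spec: SeedSpec, te_sequence: str,
                            offset: int, orientation: str) -> float:
    """Percent of non-seed piRNA bases pairing with the TE around a seed hit.

    With the seed match occupying ``te[offset, offset+L)``:

    - ``revcomp``: the duplex is antiparallel, so the piRNA 3' tail extends
      toward lower TE coordinates — piRNA position ``j > seed_end`` pairs
      with ``te[offset - (j - seed_end)]`` and position ``j < seed_start``
      pairs with ``te[offset + L - 1 + (seed_start - j)]``.
    - ``comp``: the pairing register is parallel and the directions mirror.

    A tail position scores 1 when the TE base is the Watson–Crick
    complement of the piRNA base; positions falling outside the TE bounds
    score 0 (the denominator is always the number of non-seed positions, so
    percentages are comparable across hits). A piRNA with no tail
    (seed covers the whole sequence) scores 0.0 by definition.
    """
    L = spec.length
    n = len(pirna_sequence)
    if offset < 0 or offset + L > len(te_sequence):
        raise OffsetOutOfRange(
            f"offset {offset} with seed length {L} does not fit TE of length "
            f"{len(te_sequence)}")
    if orientation not in _ORIENTATION_RANK:
        raise ValueError(f"unknown orientation {orientation!r}")
    tail_positions = [j for j in range(1, n + 1) if j < spec.start or j > spec.end]
    if not tail_positions:
        return 0.0
    score = 0
    for j in tail_positions:
        if orientation == REVCOMP:
            t = offset - (j - spec.end) if j > spec.end \
                else offset + L - 1 + (spec.start - j)
        else:
            t = offset + L - 1 + (j - spec.end) if j > spec.end \
                else offset - (spec.start - j)
        if 0 <= t < len(te_sequence):
            te_base = te_sequence[t]
            pi_base = pirna_sequence[j - 1]
            if te_base != "N" and te_base == complement(pi_base):
                score += 1
    return round(100.0 * score / len(tail_positions), 1)


def _patterns(seed: str, spec: SeedSpec) -> list[tuple[str, str]]:
    pats = [(REVCOMP, reverse_complement(seed))]
    if spec.orientation_mode == BOTH:
        pats.append((COMP, complement(seed)))
    return pats


def scan_pirna(pirna: PiRNA, reference: Sequence[TERecord],
               spec: SeedSpec | None = None) -> list[MatchHit]:
    """Scan one piRNA against every TE record.

    Returns all hits ordered by (reference order, offset, orientation),
    with ``revcomp`` before ``comp`` at equal offsets. Overlapping
    occurrences within one TE are all reported.
    """
    if spec is None:
        spec = SeedSpec()
    if not reference:
        raise EmptyReference("empty TE reference")
    seed = extract_seed(pirna.sequence, spec)
    patterns = _patterns(seed, spec)
    hits: list[MatchHit] = []
    for te in reference:
        found: list[tuple[int, int, str, str]] = []
        for orientation, pattern in patterns:
            for off in find_approx(pattern, te.sequence, spec.max_mismatches):
                found.append((off, _ORIENTATION_RANK[orientation], orientation, pattern))
        found.sort(key=lambda t: (t[0], t[1]))
        for off, _rank, orientation, pattern in found:
            mism = hamming(pattern, te.sequence[off : off + len(pattern)])
            pct = complementarity_percent(pirna.sequence, spec, te.sequence,
                                          off, orientation)
            hits.append(MatchHit(
                pirna_name=pirna.name,
                pirna_sequence=pirna.sequence,
                te=te,
                offset=off,
                orientation=orientation,
                seed_mismatches=mism,
                complementarity_percent=pct,
            ))
    return hits


def scan_many(pirnas: Iterable[PiRNA], reference: Sequence[TERecord],
              spec: SeedSpec | None = None) -> list[MatchHit]:
    """Scan a list of piRNAs, preserving piRNA order.

    piRNAs shorter than the seed window are skipped with a warning rather
    than aborting the batch.
    """
    if spec is None:
        spec = SeedSpec()
    pirnas = list(pirnas)
    if not pirnas:
        raise EmptyReference("empty piRNA list")
    hits: list[MatchHit] = []
    for pirna in pirnas:
        try:
            spec.validate_for(pirna.sequence)
        except SeedOutOfRange:
            logger.warning("skipping %s: length %d shorter than seed window %d-%d",
                           pirna.name, len(pirna.sequence), spec.start, spec.end)
            continue
        found = scan_pirna(pirna, reference, spec)
        logger.info("%s: %d hits", pirna.name, len(found))
        hits.extend(found)
    return hits
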