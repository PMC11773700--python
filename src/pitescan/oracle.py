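"""Brute-force reference implementation of the seed scan.

Deliberately naive and independent of :mod:`pitescan.scan`: patterns are
expanded into their full up-to-k mismatch-variant sets and located by exact
substring comparison at every offset. This is the ground-truth definition
used by the synthetic-fixture generator and the equivalence tests; it is
never the production path.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

from .reference import TERecord
from .scan import COMP, REVCOMP, MatchHit, PiRNA
from .seqcore import BOTH, SeedSpec

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _ocomplement(seq: str) -> str:
    return "".join(_PAIR.get(b, "N") for b in seq)


def _variants_upto(pattern: str, k: int) -> set[str]:
    bases = "ACGT"
    out = {pattern}
    for m in range(1, k + 1):
        for pos in itertools.combinations(range(len(pattern)), m):
            for subs in itertools.product(bases, repeat=m):
                if any(pattern[p] == s for p, s in zip(pos, subs)):
                    continue
                chars = list(pattern)
                for p, s in zip(pos, subs):
                    chars[p] = s
                out.add("".join(chars))
    return out


def _odist(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or "N" in (x, y))


def _otail_percent(pirna_seq: str, spec: SeedSpec, te_seq: str, offset: int,
                   orientation: str) -> float:
    n, L = len(pirna_seq), spec.length
    tail = [j for j in range(1, n + 1) if j < spec.start or j > spec.end]
    if not tail:
        return 0.0
    paired = 0
    for j in tail:
        if orientation == REVCOMP:
            # antiparallel: 3' tail walks left of the window, 5' prefix right
            t = offset - (j - spec.end) if j > spec.end else \
                offset + L - 1 + (spec.start - j)
        else:
            t = offset + L - 1 + (j - spec.end) if j > spec.end else \
                offset - (spec.start - j)
        if 0 <= t < len(te_seq) and te_seq[t] == _PAIR.get(pirna_seq[j - 1]):
            paired += 1
    return round(100.0 * paired / len(tail), 1)


def oracle_scan(pirnas: Iterable[PiRNA], reference: Sequence[TERecord],
                spec: SeedSpec) -> list[MatchHit]:
    """Enumerate every hit by exhaustive variant matching.

    Mirrors the ordering contract of the production scan: piRNA order,
    then reference order, then offset, with ``revcomp`` before ``comp``.
    piRNAs shorter than the seed window are skipped.
    """
    hits: list[MatchHit] = []
    for pirna in pirnas:
        if spec.end > len(pirna.sequence):
            continue
        seed = pirna.sequence[spec.start - 1 : spec.end]
        rc = _ocomplement(seed)[::-1]
        patterns = [(0, REVCOMP, rc)]
        if spec.orientation_mode == BOTH:
            patterns.append((1, COMP, _ocomplement(seed)))
        pattern_variants = [(rank, ori, pat, _variants_upto(pat, spec.max_mismatches))
                            for rank, ori, pat in patterns]
        L = len(seed)
        for te in reference:
            found = []
            for rank, ori, pat, variants in pattern_variants:
                for off in range(len(te.sequence) - L + 1):
                    window = te.sequence[off : off + L]
                    if window in variants:
                        found.append((off, rank, ori, pat))
            found.sort(key=lambda t: (t[0], t[1]))
            for off, _rank, ori, pat in found:
                window = te.sequence[off : off + L]
                hits.append(MatchHit(
                    pirna_name=pirna.name,
                    pirna_sequence=pirna.sequence,
                    te=te,
                    offset=off,
                    orientation=ori,
                    seed_mismatches=_odist(pat, window),
                    complementarity_percent=_otail_percent(
                        pirna.sequence, spec, te.sequence, off, ori),
                ))
    return hits
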