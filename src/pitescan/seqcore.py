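"""Nucleotide-sequence primitives.

Sequences are plain Python strings over the DNA alphabet {A, C, G, T, N}.
piRNAs are RNA in vivo, but reference TE sequences are DNA, so input is
normalized once on ingestion: whitespace stripped, case folded, U mapped
to T. All matching downstream is DNA-alphabet and Hamming-distance based
(substitutions only, no indels, no G:U wobble).

``N`` marks ambiguous/assembly-gap bases: an N in the searched text never
pairs with anything (it always counts as a mismatch), and seeds containing
N are rejected outright.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import InvalidAlphabet, SeedOutOfRange

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Orientation modes for a scan. ``revcomp_only`` searches the TE for the
#: reverse complement of the seed (the canonical antisense duplex) and is
#: the default; ``both`` additionally searches for the un-reversed
#: complement of the seed.
REVCOMP_ONLY = "revcomp_only"
BOTH = "both"
ORIENTATION_MODES = (REVCOMP_ONLY, BOTH)


def normalize(seq: str) -> str:
    """Normalize a raw sequence string to uppercase DNA.

    Strips all whitespace, uppercases, and maps U→T. Raises
    :class:`InvalidAlphabet` naming the first offending character and its
    1-based position (position counted in the whitespace-stripped string).
    Normalization is idempotent.
    """
    compact = "".join(seq.split())
    if not compact:
        raise InvalidAlphabet("", 0)
    out = compact.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in ALPHABET:
            raise InvalidAlphabet(compact[i], i + 1)
    return out


def complement(seq: str) -> str:
    """Per-base Watson–Crick complement, without reversal. N maps to N."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement: ``complement(seq)`` read 3'→5'."""
    return complement(seq)[::-1]


@dataclass(frozen=True)
class SeedSpec:
    """Seed window on a piRNA plus matching options.

    Parameters
    ----------
    start, end:
        1-based inclusive positions on the piRNA. The default window 1–10
        is the 5'-proximal region loaded into the PIWI machinery in
        teleosts; narrower windows (e.g. 2–8) reproduce the nematode/mouse
        conventions.
    max_mismatches:
        Allowed Hamming distance between the (reverse-)complemented seed
        and the TE window. Zero by default.
    orientation_mode:
        ``revcomp_only`` (default) or ``both``.
    """

    start: int = 1
    end: int = 10
    max_mismatches: int = 0
    orientation_mode: str = REVCOMP_ONLY

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SeedOutOfRange(
                f"invalid seed window {self.start}-{self.end}: need 1 <= start <= end"
            )
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be non-negative")
        if self.max_mismatches >= self.length:
            raise ValueError(
                f"max_mismatches={self.max_mismatches} must be smaller than "
                f"the seed length ({self.length})"
            )
        if self.orientation_mode not in ORIENTATION_MODES:
            raise ValueError(
                f"orientation_mode must be one of {ORIENTATION_MODES}, "
                f"got {self.orientation_mode!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate_for(self, pirna_sequence: str) -> None:
        """Raise :class:`SeedOutOfRange` if the window overruns the piRNA."""
        if self.end > len(pirna_sequence):
            raise SeedOutOfRange(
                f"seed window {self.start}-{self.end} exceeds piRNA length "
                f"{len(pirna_sequence)}"
            )


def extract_seed(pirna_sequence: str, spec: SeedSpec) -> str:
    """Substring of the piRNA at 1-based inclusive positions [start, end]."""
    spec.validate_for(pirna_sequence)
    return pirna_sequence[spec.start - 1 : spec.end]


def mismatch_variants(seed: str, k: int) -> set[str]:
    """All sequences within Hamming distance ≤ k of ``seed``.

    Includes the seed itself; cardinality is Σ_{i=0..k} C(L,i)·3^i.
    Intended for small seeds (the default 10-mer at k ≤ 2); the scanning
    path does not enumerate variants, this is the reference definition.
    """
    if "N" in seed:
        raise InvalidAlphabet("N", seed.index("N") + 1)
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= len(seed):
        raise ValueError(f"k={k} must be smaller than the seed length {len(seed)}")
    bases = "ACGT"
    out: set[str] = {seed}
    for n_sub in range(1, k + 1):
        for positions in itertools.combinations(range(len(seed)), n_sub):
            alt_sets = [[b for b in bases if b != seed[p]] for p in positions]
            for subs in itertools.product(*alt_sets):
                chars = list(seed)
                for p, b in zip(positions, subs):
                    chars[p] = b
                out.add("".join(chars))
    return out


def find_approx(pattern: str, text: str, k: int) -> list[int]:
    """All 0-based offsets where ``pattern`` matches ``text`` within ≤ k mismatches.

    A Hamming sliding window over the text; overlapping occurrences are all
    reported, in ascending offset order. A text position holding N never
    matches (it is forced to count as a mismatch even against an N in the
    pattern). Returns an empty list when the pattern is longer than the text.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= len(pattern):
        raise ValueError(f"k={k} must be smaller than the pattern length")
    if len(pattern) > len(text):
        return []
    p = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mismatches = ((windows != p) | (windows == ord("N"))).sum(axis=1)
    return [int(i) for i in np.nonzero(mismatches <= k)[0]]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N in either side mismatches."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")
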