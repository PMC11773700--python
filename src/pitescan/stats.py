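"""Hit aggregation and per-class binomial enrichment.

Counting unit: *distinct TE records*, not occurrences — one TE copy hit at
three offsets counts once, keeping the observed counts and the reference
background on the same sample space. The null for class ``c`` is that each
matched record is drawn from the reference with probability equal to the
class's share of reference records; over-representation is scored with the
one-sided binomial tail P(X ≥ observed). No multiple-testing correction is
applied by default (an optional Bonferroni over the ≤7 classes is exposed
for callers who want it); a class is flagged significant at P ≤ 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .reference import CLASS_ORDER, TERecord
from .scan import MatchHit

SIGNIFICANCE_LEVEL = 0.05


def binomial_sf(x: int, n: int, p: float) -> float:
    """Exact one-sided binomial tail P(X ≥ x) for X ~ Binomial(n, p).

    Summation of pmf terms in log space (lgamma binomial coefficients,
    exponentiated after shifting by the largest term and accumulated with
    ``math.fsum``), stable to ≥12 significant digits for n up to the
    thousands.
    """
    if not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"require 0 <= p <= 1, got p={p}")
    if x == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    log_p, log_q = math.log(p), math.log1p(-p)
    log_terms = [
        math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
        + i * log_p + (n - i) * log_q
        for i in range(x, n + 1)
    ]
    m = max(log_terms)
    total = m + math.log(math.fsum(math.exp(t - m) for t in log_terms))
    return min(1.0, math.exp(total))


def distinct_records(hits: Iterable[MatchHit]) -> list[TERecord]:
    """Distinct TE records touched by the hits, in first-hit order."""
    seen: dict[TERecord, None] = {}
    for h in hits:
        seen.setdefault(h.te, None)
    return list(seen)


def count_by_class(hits: Iterable[MatchHit],
                   reference: Sequence[TERecord] | None = None,
                   ) -> tuple[dict[str, int], dict[str, int]]:
    """Per-class and per-family counts of distinct matched TE records.

    Returns ``(class_counts, family_counts)``: class counts cover all seven
    classes in deterministic order (zeros included); family counts list
    only families actually matched.
    """
    class_counts = {cls: 0 for cls in CLASS_ORDER}
    family_counts: dict[str, int] = {}
    for te in distinct_records(hits):
        class_counts[te.te_class] += 1
        family_counts[te.family] = family_counts.get(te.family, 0) + 1
    return class_counts, family_counts


@dataclass(frozen=True)
class EnrichmentResult:
    """Binomial enrichment of one TE class among the matched records."""

    te_class: str
    observed: int       # distinct matched TE records of this class
    total: int          # distinct matched TE records, all classes
    null_p: float       # class share of the reference
    p_value: float      # one-sided binomial tail P(X >= observed)
    significant: bool   # p_value <= 0.05


def enrichment(hits: Iterable[MatchHit], reference: Sequence[TERecord],
               bonferroni: bool = False) -> list[EnrichmentResult]:
    """Per-class binomial enrichment test over the matched TE records.

    Classes with zero observed records get P = 1.0. With ``bonferroni``,
    p-values are multiplied by the number of classes present in the
    reference (capped at 1) before the significance flag is set.
    """
    if not reference:
        raise ValueError("empty TE reference")
    class_counts, _ = count_by_class(hits)
    total = sum(class_counts.values())
    background = {cls: 0 for cls in CLASS_ORDER}
    for te in reference:
        background[te.te_class] += 1
    n_ref = len(reference)
    n_tests = sum(1 for cls in CLASS_ORDER if background[cls] > 0)
    results: list[EnrichmentResult] = []
    for cls in CLASS_ORDER:
        observed = class_counts[cls]
        null_p = background[cls] / n_ref
        if total == 0 or observed == 0:
            p = 1.0
        else:
            p = binomial_sf(observed, total, null_p)
        if bonferroni:
            p = min(1.0, p * max(n_tests, 1))
        results.append(EnrichmentResult(
            te_class=cls, observed=observed, total=total, null_p=null_p,
            p_value=p, significant=p <= SIGNIFICANCE_LEVEL,
        ))
    return results
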