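"""Counting, the binomial tail, and per-class enrichment."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from pitescan import (
    MatchHit,
    SeedSpec,
    binomial_sf,
    count_by_class,
    enrichment,
    scan_pirna,
)
from conftest import make_te


def direct_sf(x, n, p):
    """Oracle: plain summation of exact-coefficient pmf terms."""
    return math.fsum(math.comb(n, i) * p**i * (1 - p) ** (n - i)
                     for i in range(x, n + 1))


def make_hit(te, offset=0, orientation="revcomp", mism=0, pct=0.0,
             pirna="pi-1"):
    return MatchHit(pirna_name=pirna, pirna_sequence="A" * 20, te=te,
                    offset=offset, orientation=orientation,
                    seed_mismatches=mism, complementarity_percent=pct)


class TestBinomialSf:
    @pytest.mark.parametrize("x,n,p,expected", [
        (0, 10, 0.2, 1.0),
        (10, 10, 1.0, 1.0),
        (1, 5, 0.0, 0.0),
        (5, 5, 0.5, 0.5**5),
    ])
    def test_boundary_cases(self, x, n, p, expected):
        assert binomial_sf(x, n, p) == pytest.approx(expected, abs=1e-15)

    def test_worked_value(self):
        assert binomial_sf(5, 10, 0.2) == pytest.approx(0.0327935, abs=5e-8)

    def test_agrees_with_direct_summation_on_random_grid(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = int(rng.integers(1, 1001))
            p = float(rng.uniform(0.01, 0.99))
            # x within ~10 SD of the mean: beyond that the plain-float
            # oracle underflows (the scipy cross-check covers full range)
            x_cap = min(n, int(n * p + 10 * math.sqrt(n * p * (1 - p))) + 1)
            x = int(rng.integers(0, x_cap + 1))
            got = binomial_sf(x, n, p)
            want = direct_sf(x, n, p)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(1, 500))
            x = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.0, 1.0))
            assert binomial_sf(x, n, p) == pytest.approx(
                float(sps.binom.sf(x - 1, n, p)), rel=1e-10, abs=1e-300)

    def test_monotone_non_increasing_in_x(self):
        values = [binomial_sf(x, 50, 0.3) for x in range(51)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("x,n,p", [(-1, 5, 0.5), (6, 5, 0.5), (1, 5, 1.5)])
    def test_domain_errors(self, x, n, p):
        with pytest.raises(ValueError):
            binomial_sf(x, n, p)


class TestCountByClass:
    def test_occurrences_deduplicate_to_distinct_records(self):
        gypsy = make_te(name="Gypsy-12", family="Gypsy", te_class="LTR")
        l1 = make_te(name="L1-2", family="L1", te_class="LINE", start=100)
        hits = [make_hit(gypsy, 0), make_hit(gypsy, 7), make_hit(l1, 3)]
        class_counts, family_counts = count_by_class(hits)
        assert class_counts["LTR"] == 1 and class_counts["LINE"] == 1
        assert family_counts == {"Gypsy": 1, "L1": 1}

    def test_empty_hits_give_all_zero(self):
        class_counts, family_counts = count_by_class([])
        assert set(class_counts.values()) == {0}
        assert list(class_counts) == ["DNA", "LTR", "LINE", "SINE", "RC",
                                      "Satellite", "Unclassified"]
        assert family_counts == {}

    def test_distinct_helitrons_count_individually(self):
        tes = [make_te(name=f"Helitron-{i}", family="Helitron", te_class="RC",
                       start=i * 100) for i in range(3)]
        class_counts, _ = count_by_class([make_hit(te) for te in tes])
        assert class_counts["RC"] == 3


class TestEnrichment:
    def build_reference(self, n_ltr, n_other):
        tes = [make_te(name=f"Gypsy-{i}", family="Gypsy", te_class="LTR",
                       start=i * 10) for i in range(n_ltr)]
        tes += [make_te(name=f"hAT-{i}", family="hAT", te_class="DNA",
                        start=1000 + i * 10) for i in range(n_other)]
        return tes

    def test_enriched_class_detected(self):
        # 20% LTR background; 5 of 10 matched records are LTR
        reference = self.build_reference(5, 20)
        matched = reference[:5] + reference[5:10]
        hits = [make_hit(te) for te in matched]
        results = {r.te_class: r for r in enrichment(hits, reference)}
        ltr = results["LTR"]
        assert (ltr.observed, ltr.total, ltr.null_p) == (5, 10, 0.2)
        assert ltr.p_value == pytest.approx(0.0327935, abs=5e-8)
        assert ltr.significant

    def test_class_at_expected_rate_not_significant(self):
        reference = self.build_reference(4, 16)
        matched = reference[:2] + reference[4:12]
        results = {r.te_class: r for r in
                   enrichment([make_hit(te) for te in matched], reference)}
        assert results["LTR"].p_value == pytest.approx(0.6242, abs=5e-4)
        assert not results["LTR"].significant

    def test_no_hits_gives_unit_pvalues(self):
        results = enrichment([], self.build_reference(4, 16))
        assert all(r.p_value == 1.0 and not r.significant for r in results)

    def test_observed_sums_to_total_and_order_invariant(self):
        reference = self.build_reference(5, 5)
        hits = [make_hit(te) for te in reference[:7]]
        res_fwd = enrichment(hits, reference)
        res_rev = enrichment(list(reversed(hits)), reference)
        assert sum(r.observed for r in res_fwd) == res_fwd[0].total
        assert [(r.te_class, r.p_value) for r in res_fwd] == \
               [(r.te_class, r.p_value) for r in res_rev]

    def test_bonferroni_scales_pvalues(self):
        reference = self.build_reference(5, 20)
        hits = [make_hit(te) for te in reference[:5] + reference[5:10]]
        plain = {r.te_class: r.p_value for r in enrichment(hits, reference)}
        corrected = {r.te_class: r.p_value
                     for r in enrichment(hits, reference, bonferroni=True)}
        assert corrected["LTR"] == pytest.approx(min(1.0, plain["LTR"] * 2))

    def test_significance_flag_flips_exactly_at_threshold(self):
        # synthesise results around the 0.05 boundary via the flag invariant
        reference = self.build_reference(1, 99)
        for n_hit in range(1, 6):
            matched = [reference[0]] + reference[1 : n_hit]
            results = {r.te_class: r for r in
                       enrichment([make_hit(te) for te in matched], reference)}
            r = results["LTR"]
            assert r.significant == (r.p_value <= 0.05)


def test_enrichment_consistent_with_scan_pipeline(canonical_pirna):
    from pitescan import reverse_complement
    pattern = reverse_complement("TACACGAAGA")
    reference = [
        make_te(name="Gypsy-1", family="Gypsy", te_class="LTR",
                sequence="AA" + pattern + "CC"),
        make_te(name="Gypsy-2", family="Gypsy", te_class="LTR", start=500,
                sequence="TT" + pattern + "GG"),
        make_te(name="hAT-1", family="hAT", te_class="DNA", start=1000,
                sequence="A" * 30),
    ]
    hits = scan_pirna(canonical_pirna, reference, SeedSpec())
    results = {r.te_class: r for r in enrichment(hits, reference)}
    assert results["LTR"].observed == 2
    assert results["DNA"].observed == 0 and results["DNA"].p_value == 1.0
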