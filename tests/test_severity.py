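"""Serious vs non-serious comparison: test choice, statistics, calibration."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from faersignal.contingency import ContingencyTable
from faersignal.datasets import NONSERIOUS_TOTAL, SERIOUS_TOTAL
from faersignal.ingest import ReportCase
from faersignal.severity import (
    choose_test,
    compare_all,
    fisher_exact,
    mann_whitney,
    pearson_chi2,
    yates_chi2,
)


def sev_table(n_serious: int, n_nonserious: int) -> ContingencyTable:
    return ContingencyTable(
        n_serious, SERIOUS_TOTAL - n_serious,
        n_nonserious, NONSERIOUS_TOTAL - n_nonserious,
    )


class TestChooseTest:
    @pytest.mark.parametrize(
        "counts, expected",
        [((330, 3), "yates"),     # pneumonia
         ((40, 0), "fisher"),     # eosinophilia and systemic symptoms
         ((10, 33), "pearson")],  # SARS-CoV-2 test positive
    )
    def test_rule(self, counts, expected):
        assert choose_test(sev_table(*counts)) == expected


class TestChiSquare:
    @pytest.mark.parametrize(
        "counts, stat",
        [((246, 425), 204.663), ((361, 277), 11.561)],
    )
    def test_pearson_published_values(self, counts, stat):
        got, p = pearson_chi2(sev_table(*counts))
        assert got == pytest.approx(stat, abs=0.01)
        assert p < 0.05

    def test_pearson_zero_on_proportional_table(self):
        stat, p = pearson_chi2(ContingencyTable(10, 90, 100, 900))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts, stat",
        [((330, 3), 186.728), ((35, 1), 16.663)],
    )
    def test_yates_published_values(self, counts, stat):
        got, _ = yates_chi2(sev_table(*counts))
        assert got == pytest.approx(stat, abs=0.01)

    def test_yates_clamps_to_zero(self):
        # |ad-bc| <= N/2 -> statistic clamped at 0
        stat, p = yates_chi2(ContingencyTable(5, 5, 5, 6))
        assert stat == 0.0 and p == 1.0

    def test_yates_never_exceeds_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 80, 4)))
            assert yates_chi2(t)[0] <= pearson_chi2(t)[0] + 1e-12


def brute_force_fisher(t: ContingencyTable) -> float:
    """Full hypergeometric enumeration with fixed margins."""
    r1, c1, n = t.a + t.b, t.a + t.c, t.n
    r2 = n - r1
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[t.a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize(
        "cells, p",
        [((3, 1, 1, 3), 0.485714), ((5, 5, 5, 5), 1.0)],
    )
    def test_examples(self, cells, p):
        assert fisher_exact(ContingencyTable(*cells)) == pytest.approx(p, abs=1e-6)

    def test_eosinophilia_row(self):
        assert fisher_exact(sev_table(40, 0)) < 0.001

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            t = ContingencyTable(*(int(x) for x in rng.integers(0, 9, 4)))
            assert fisher_exact(t) == pytest.approx(brute_force_fisher(t), rel=1e-8)


class TestMannWhitney:
    def test_hand_example(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert z == pytest.approx(-4.5 / math.sqrt(5.25), abs=1e-3)

    def test_identical_samples(self):
        _, z, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert z == 0 and p == 1

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 500)
        y = rng.normal(1, 1, 500)
        _, _, p = mann_whitney(x, y)
        assert p < 1e-6

    def test_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 20, 80).astype(float)  # heavy ties
        y = rng.integers(3, 23, 60).astype(float)
        _, _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _case(i, serious, pt, age=None):
    return ReportCase(
        primaryid=str(i), caseid=str(i), fda_date=None, sex="unknown",
        age_years=age, weight_kg=None, country=None, reporter="unknown",
        outcomes=frozenset({"hospitalization"}) if serious else frozenset(),
        drugs=(("TARGET", "PS"),), events=frozenset({pt}),
    )


class TestCompareAll:
    def test_min_count_filter(self):
        cases = [_case(i, i % 2 == 0, "Rare") for i in range(29)]
        cases += [_case(100 + i, i % 2 == 0, "Common") for i in range(30)]
        names = {r.name for r in compare_all(cases, min_count=30)}
        assert "Common" in names and "Rare" not in names

    def test_planted_serious_pt_detected(self):
        rng = np.random.default_rng(21)
        cases = []
        i = 0
        for _ in range(400):  # PT X: 90% serious
            cases.append(_case(i, rng.random() < 0.9, "X")); i += 1
        for _ in range(1200):  # background PT: 50% serious
            cases.append(_case(i, rng.random() < 0.5, "BG")); i += 1
        results = {r.name: r for r in compare_all(cases, min_count=30)}
        assert results["X"].p_value < 0.05

    def test_null_p_values_are_uniform(self):
        """Equal serious/non-serious reporting rates -> uniform p-values."""
        rng = np.random.default_rng(7)
        n_s, n_ns, rate = 3000, 2000, 0.08
        pvals = []
        for _ in range(500):
            a = rng.binomial(n_s, rate)
            c = rng.binomial(n_ns, rate)
            t = ContingencyTable(a, n_s - a, c, n_ns - c)
            pvals.append(pearson_chi2(t)[1])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
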