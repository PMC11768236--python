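"""The four disproportionality algorithms against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats as sps

from faersignal import synthetic
from faersignal.contingency import ContingencyTable
from faersignal.ingest import select_target_reports
from faersignal.stats import (
    BCPNNPriors,
    MGPSPrior,
    SignalConfig,
    ZeroCellError,
    bcpnn_ic,
    evaluate_signal,
    fit_mgps_prior,
    mgps_ebgm,
    prr_estimate,
    ror_estimate,
    screen,
)
from faersignal.synthetic import PTSpec


class TestROR:
    @pytest.mark.parametrize(
        "cells, ror, lo, hi",
        [((25, 75, 100, 900), 3.000, 1.824, 4.934),
         ((10, 90, 10, 90), 1.000, None, None),
         ((3, 27, 10, 960), 10.667, 2.777, 40.97)],
    )
    def test_hand_examples(self, cells, ror, lo, hi):
        got, (got_lo, got_hi) = ror_estimate(ContingencyTable(*cells))
        assert got == pytest.approx(ror, abs=5e-3)
        if lo is not None:
            assert got_lo == pytest.approx(lo, abs=5e-3)
            assert got_hi == pytest.approx(hi, abs=5e-2)

    def test_zero_cell_refused_and_continuity_defined(self):
        t = ContingencyTable(3, 27, 0, 970)
        with pytest.raises(ZeroCellError):
            ror_estimate(t)
        ror, (lo, hi) = ror_estimate(t.with_continuity())
        assert lo < ror < hi


class TestPRR:
    @pytest.mark.parametrize(
        "cells, prr, chi2",
        [((25, 75, 100, 900), 2.5, 20.308),
         ((10, 90, 100, 900), 1.0, 0.0),
         ((3, 27, 10, 960), 9.70, 18.24)],
    )
    def test_hand_examples(self, cells, prr, chi2):
        got_prr, got_chi2 = prr_estimate(ContingencyTable(*cells))
        assert got_prr == pytest.approx(prr, abs=5e-3)
        assert got_chi2 == pytest.approx(chi2, abs=6e-3)


def mc_ic_draws(t: ContingencyTable, n_draws: int, rng) -> np.ndarray:
    """Monte-Carlo oracle: exact posterior IC draws from independent Betas."""
    p = BCPNNPriors()
    g = p.gamma(t)
    n = t.n
    p11 = rng.beta(t.a + p.gamma11, n - t.a + g - p.gamma11, size=n_draws)
    p1 = rng.beta(t.a + t.b + p.alpha1, n - (t.a + t.b) + p.alpha - p.alpha1, size=n_draws)
    p2 = rng.beta(t.a + t.c + p.beta1, n - (t.a + t.c) + p.beta - p.beta1, size=n_draws)
    return np.log2(p11 / (p1 * p2))


class TestBCPNN:
    def test_independence_table_has_near_zero_ic(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(10, 90, 90, 810))
        assert abs(ic) < 0.1 and ic025 < 0

    def test_large_n_limit(self):
        ic, _ = bcpnn_ic(ContingencyTable(1000, 9000, 9000, 81000))
        assert abs(ic) < 0.05

    def test_against_dirichlet_monte_carlo(self):
        t = ContingencyTable(25, 75, 100, 900)
        draws = mc_ic_draws(t, 10**6, np.random.default_rng(99))
        ic, ic025 = bcpnn_ic(t)
        assert ic == pytest.approx(float(draws.mean()), abs=0.05)
        assert ic025 == pytest.approx(float(np.quantile(draws, 0.025)), abs=0.05)


def quadrature_ebgm(a: float, e: float, prior: MGPSPrior) -> tuple[float, float]:
    """Numeric-integration oracle for the posterior geometric mean and 5th pct."""
    from faersignal.stats import _posterior_mixture

    comps = _posterior_mixture(a, e, prior)

    def dens(x):
        return sum(w * sps.gamma.pdf(x, sh, scale=1 / ra) for w, sh, ra in comps)

    f = lambda x: math.log(x) * dens(x)
    mean_log = (
        integrate.quad(f, 0, 1, limit=300)[0]
        + integrate.quad(f, 1, np.inf, limit=300)[0]
    )

    def cdf(x):
        return sum(w * sps.gamma.cdf(x, sh, scale=1 / ra) for w, sh, ra in comps)

    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-12, 1e4)
    return math.exp(mean_log), q05


class TestMGPS:
    def test_shrinkage_limits(self):
        # huge expected count with observed/expected = 1 -> EBGM ~ 1
        ebgm, _ = mgps_ebgm(a=10_000, e=10_000)
        assert ebgm == pytest.approx(1.0, abs=0.01)
        # zero observed -> shrunk below 1 for any E >= 1
        for e in (1.0, 5.0, 20.0):
            ebgm, ebgm05 = mgps_ebgm(a=0, e=e)
            assert ebgm05 < ebgm < 1

    def test_against_quadrature(self):
        t = ContingencyTable(25, 75, 100, 900)
        assert t.expected_a == pytest.approx(100 * 125 / 1100)
        got = mgps_ebgm(t)
        want = quadrature_ebgm(25, t.expected_a, MGPSPrior())
        assert got[0] == pytest.approx(want[0], abs=1e-3)
        assert got[1] == pytest.approx(want[1], abs=1e-3)

    def test_prior_recovery(self):
        rng = np.random.default_rng(5)
        n = 5000
        es = rng.uniform(0.5, 20, n)
        true = MGPSPrior()
        comp1 = rng.random(n) < true.w
        lam = np.where(
            comp1,
            rng.gamma(true.a1, 1 / true.b1, n),
            rng.gamma(true.a2, 1 / true.b2, n),
        )
        ns = rng.poisson(lam * es)
        fitted, ll, converged = fit_mgps_prior(zip(ns, es))
        assert converged
        assert fitted.w == pytest.approx(true.w, abs=0.1)

    def test_single_component_data_hits_boundary(self):
        rng = np.random.default_rng(8)
        es = rng.uniform(1, 10, 2000)
        lam = rng.gamma(2.0, 1 / 4.0, 2000)  # second component only
        ns = rng.poisson(lam * es)
        fitted, _, converged = fit_mgps_prior(zip(ns, es))
        assert fitted.w < 0.05 or not converged

    def test_refit_does_not_decrease_loglik(self):
        rng = np.random.default_rng(3)
        es = rng.uniform(0.5, 10, 1000)
        lam = np.where(rng.random(1000) < 0.3, rng.gamma(0.2, 10.0, 1000),
                       rng.gamma(2.0, 0.25, 1000))
        ns = rng.poisson(lam * es)
        pairs = list(zip(ns, es))
        p1, ll1, _ = fit_mgps_prior(pairs)
        p2, ll2, _ = fit_mgps_prior(pairs, start=p1)
        assert ll2 >= ll1 - 1e-6


class TestEvaluateSignal:
    def test_case_count_gate(self):
        # a=2: ROR and PRR flags must be off regardless of magnitude
        m = evaluate_signal(ContingencyTable(2, 8, 10, 980))
        assert not m.flag_ror and not m.flag_prr

    def test_ror_flag_on_strong_table(self):
        m = evaluate_signal(ContingencyTable(25, 75, 100, 900))
        assert m.flag_ror
        assert m.ror_ci95[0] == pytest.approx(1.824, abs=5e-3)

    @pytest.mark.parametrize("ic025, band", [(3.5, "strong"), (2.0, "medium"), (1.0, "low")])
    def test_ic_band_rule(self, ic025, band):
        cfg = SignalConfig()
        if ic025 > cfg.ic_strong:
            assert band == "strong"
        elif ic025 > cfg.ic_medium:
            assert band == "medium"
        else:
            assert band == "low"
        # and the rule as applied end-to-end
        m = evaluate_signal(ContingencyTable(25, 75, 100, 900))
        assert m.ic_band == ("medium" if 1.5 < m.ic025 <= 3.0 else m.ic_band)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.integers(5, 50), b=st.integers(5, 200),
        c=st.integers(5, 200), d=st.integers(200, 5000),
    )
    def test_monotone_in_a_with_margins_fixed(self, a, b, c, d):
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b - 1, c - 1, d + 1)
        m1, m2 = evaluate_signal(t1), evaluate_signal(t2)
        assert m2.ror > m1.ror and m2.prr > m1.prr
        assert m2.ic > m1.ic and m2.ebgm > m1.ebgm

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.integers(2, 60), b=st.integers(1, 300),
        c=st.integers(1, 300), d=st.integers(50, 5000),
    )
    def test_ror_dominates_prr_when_signal_positive(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if a / (a + b) >= c / (c + d):
            ror, _ = ror_estimate(t)
            prr, _ = prr_estimate(t)
            assert ror >= prr - 1e-12


class TestScreen:
    def test_planted_pair_flagged_by_all_four(self):
        config = synthetic.SyntheticConfig(
            n_reports=40_000, exposure_prob=0.05,
            pt_catalog=(
                PTSpec("Sepsis", "Infections and infestations", 0.005),
                PTSpec("Rash", "Skin and subcutaneous tissue disorders", 0.03),
            ),
            planted_effects={"Sepsis": (8.0, ())},
            seed=13,
        )
        cases, truth = synthetic.simulate(config)
        exposed, _ = select_target_reports(cases, {"canakinumab", "ilaris"})
        df = screen(cases, exposed, level="PT")
        row = df.set_index("term").loc["Sepsis"]
        assert row[["flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps"]].all()
        assert bool(row["signal"])

    def test_empty_exposed_set(self, cohort):
        cases, _ = cohort
        df = screen(cases, [], level="PT")
        assert len(df) == 0

    def test_output_sorted_and_annotated(self, cohort, annotation):
        cases, _ = cohort
        exposed, _ = select_target_reports(cases, {"canakinumab", "ilaris"})
        df = screen(cases, exposed, annotation, level="PT")
        assert (df["a"] >= 3).all()
        for _, grp in df.groupby("soc"):
            rors = grp["ror"].dropna().tolist()
            assert rors == sorted(rors, reverse=True)
        assert set(df.loc[df["term"] == "Deafness", "dme"]) <= {True}
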