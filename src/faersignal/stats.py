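"""Disproportionality statistics for spontaneous-report signal detection.

Four estimators of the same question -- is the event reported more often
with the drug than expected? -- each with its conventional signal
criterion:

* ROR, reporting odds ratio ``ad/bc`` with a log-scale Wald 95% CI
  (signal: a >= 3 and CI lower bound > 1);
* PRR, proportional reporting ratio with a Pearson chi-square
  (signal: a >= 3, PRR >= 2, chi2 >= 4);
* BCPNN information component IC = log2 of the shrunken
  observed-to-expected ratio, with IC025 its lower 95% credibility bound
  (signal: IC025 > 0);
* MGPS empirical-Bayes geometric mean EBGM under DuMouchel's
  gamma-Poisson mixture, with EBGM05 the posterior 5th percentile
  (signal: EBGM05 > 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

from .contingency import ContingencyTable, FractionalTable, build_table, pearson_statistic
from .ingest import Annotation, ReportCase

__all__ = [
    "ZeroCellError",
    "BCPNNPriors",
    "MGPSPrior",
    "SignalConfig",
    "SignalMetrics",
    "ror_estimate",
    "prr_estimate",
    "bcpnn_ic",
    "mgps_ebgm",
    "fit_mgps_prior",
    "evaluate_signal",
    "screen",
]

Z95 = 1.959963984540054


class ZeroCellError(ValueError):
    """A statistic's formula requires every cell to be positive."""


def _cells(t: ContingencyTable | FractionalTable) -> tuple[float, float, float, float]:
    return float(t.a), float(t.b), float(t.c), float(t.d)


def ror_estimate(t: ContingencyTable | FractionalTable) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio ``ad/bc`` with its Wald 95% CI.

    CI: ``exp(ln ROR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``. Any zero
    cell raises :class:`ZeroCellError`; callers wanting the Haldane-
    Anscombe correction should pass ``t.with_continuity()``.
    """
    a, b, c, d = _cells(t)
    if min(a, b, c, d) <= 0:
        raise ZeroCellError("ROR undefined with a zero cell")
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(ror) - Z95 * se), math.exp(math.log(ror) + Z95 * se)
    return ror, (lo, hi)


def prr_estimate(t: ContingencyTable | FractionalTable) -> tuple[float, float]:
    """Proportional reporting ratio and its Pearson chi-square (1 df)."""
    a, b, c, d = _cells(t)
    if a + b == 0 or c + d == 0 or c == 0:
        raise ZeroCellError("PRR undefined: zero exposed margin or zero comparator count")
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = pearson_statistic(a, b, c, d)
    return prr, chi2


@dataclass(frozen=True)
class BCPNNPriors:
    """Pseudo-counts of the Bate et al. information-component model.

    Defaults give each margin a Beta(1, 1) prior and the joint cell a
    prior centred on independence.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable | FractionalTable) -> float:
        a, b, c, _ = _cells(t)
        n = t.n
        return (
            self.gamma11
            * (n + self.alpha)
            * (n + self.beta)
            / ((a + b + self.alpha1) * (a + c + self.beta1))
        )


def bcpnn_ic(
    t: ContingencyTable | FractionalTable,
    priors: BCPNNPriors = BCPNNPriors(),
    z: float = Z95,
) -> tuple[float, float]:
    """Closed-form posterior mean and lower credibility bound of the IC.

    IC = log2 p(drug, event) / (p(drug) p(event)) under independent
    Beta/Dirichlet posteriors; the variance expression is the standard
    delta-method form, and ``ic025 = E(IC) - z sqrt(V(IC))``.
    """
    if t.n <= 0:
        raise ValueError("empty table")
    a, b, c, _ = _cells(t)
    n = float(t.n)
    p = priors
    g = p.gamma(t)
    e_ic = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + g) * (a + b + p.alpha1) * (a + c + p.beta1))
    )
    v_ic = (
        (n - a + g - p.gamma11) / ((a + p.gamma11) * (1 + n + g))
        + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
        + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
    ) / (math.log(2) ** 2)
    return e_ic, e_ic - z * math.sqrt(v_ic)


@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    Component i is Gamma(shape ``a_i``, rate ``b_i``); ``w`` is the weight
    of the first. Defaults are DuMouchel's published starting values.
    """

    a1: float = 0.2
    b1: float = 0.1
    a2: float = 2.0
    b2: float = 4.0
    w: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0 or not 0 < self.w < 1:
            raise ValueError("invalid MGPS prior")


def _nb_logpmf(n: float, shape: float, rate: float, e: float) -> float:
    """log P(N=n) when lambda~Gamma(shape, rate) and N|lambda~Poisson(lambda*E)."""
    return (
        special.gammaln(shape + n)
        - special.gammaln(shape)
        - special.gammaln(n + 1)
        + shape * math.log(rate / (rate + e))
        + n * math.log(e / (rate + e))
    )


def _posterior_mixture(a: float, e: float, prior: MGPSPrior):
    """Posterior over lambda: weights and Gamma(shape, rate) components."""
    l1 = math.log(prior.w) + _nb_logpmf(a, prior.a1, prior.b1, e)
    l2 = math.log(1 - prior.w) + _nb_logpmf(a, prior.a2, prior.b2, e)
    m = max(l1, l2)
    w1 = math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))
    return (
        (w1, prior.a1 + a, prior.b1 + e),
        (1 - w1, prior.a2 + a, prior.b2 + e),
    )


def mgps_ebgm(
    t: ContingencyTable | FractionalTable | None = None,
    prior: MGPSPrior = MGPSPrior(),
    *,
    a: float | None = None,
    e: float | None = None,
    quantile: float = 0.05,
) -> tuple[float, float]:
    """EBGM and its posterior 5th percentile (EBGM05).

    Accepts either a contingency table (from which the observed count
    ``a`` and independence expectation ``E = (a+b)(a+c)/N`` are taken) or
    the (a, E) pair directly. EBGM = exp(E[ln lambda | a, E]) from the
    digamma means of the two posterior gamma components; EBGM05 solves
    the mixture CDF = 0.05 by root bracketing to 1e-9.
    """
    if t is not None:
        if t.n <= 0:
            raise ValueError("empty table")
        a = float(t.a)
        e = (t.a + t.b) * (t.a + t.c) / t.n
    if a is None or e is None or e <= 0:
        raise ValueError("need observed count a and expected count E > 0")
    comps = _posterior_mixture(a, e, prior)
    mean_log = sum(w * (special.digamma(shape) - math.log(rate)) for w, shape, rate in comps)
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return sum(w * special.gammainc(shape, rate * x) for w, shape, rate in comps)

    hi = max(shape / rate for _, shape, rate in comps) + 1.0
    tries = 0
    while cdf(hi) < quantile:
        hi *= 2.0
        tries += 1
        if tries > 200:
            raise RuntimeError("EBGM quantile bracketing failed")
    ebgm05 = optimize.brentq(lambda x: cdf(x) - quantile, 0.0, hi, xtol=1e-9)
    return ebgm, ebgm05


def fit_mgps_prior(
    pairs: Iterable[tuple[float, float]],
    start: MGPSPrior = MGPSPrior(),
) -> tuple[MGPSPrior, float, bool]:
    """Empirical-Bayes fit of the mixture prior to (a, E) pairs.

    Maximizes the marginal negative-binomial-mixture likelihood by
    L-BFGS-B on log/logit-transformed parameters. Returns (prior,
    log-likelihood, converged); on optimizer failure the start prior is
    returned with ``converged=False``.
    """
    data = np.asarray(list(pairs), dtype=float)
    if len(data) == 0:
        raise ValueError("no (a, E) pairs supplied")
    ns, es = data[:, 0], data[:, 1]

    def nll(theta: np.ndarray) -> float:
        a1, b1, a2, b2 = np.exp(theta[:4])
        w = 1.0 / (1.0 + math.exp(-theta[4]))
        l1 = (
            special.gammaln(a1 + ns) - special.gammaln(a1) - special.gammaln(ns + 1)
            + a1 * np.log(b1 / (b1 + es)) + ns * np.log(es / (b1 + es))
        )
        l2 = (
            special.gammaln(a2 + ns) - special.gammaln(a2) - special.gammaln(ns + 1)
            + a2 * np.log(b2 / (b2 + es)) + ns * np.log(es / (b2 + es))
        )
        both = np.stack([l1 + math.log(w), l2 + math.log1p(-w)])
        return -float(special.logsumexp(both, axis=0).sum())

    theta0 = np.array([
        math.log(start.a1), math.log(start.b1),
        math.log(start.a2), math.log(start.b2),
        math.log(start.w / (1 - start.w)),
    ])
    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            bounds=[(-10, 10)] * 4 + [(-12, 12)])
    if not res.success or not np.isfinite(res.fun):
        return start, -nll(theta0), False
    a1, b1, a2, b2 = np.exp(res.x[:4])
    w = 1.0 / (1.0 + math.exp(-res.x[4]))
    w = min(max(w, 1e-9), 1 - 1e-9)
    boundary = res.x[4] <= -11.9 or res.x[4] >= 11.9
    return MGPSPrior(a1, b1, a2, b2, w), -res.fun, not boundary


@dataclass(frozen=True)
class SignalConfig:
    """Thresholds and policy for calling a drug--event pair a signal."""

    min_cases: int = 3
    ror_lower_ci: float = 1.0
    prr_threshold: float = 2.0
    chi2_threshold: float = 4.0
    ic025_threshold: float = 0.0
    ebgm05_threshold: float = 2.0
    policy: str = "all4"  # "all4" (PT screening) or "any1" (SOC screening)
    continuity: bool = False  # Haldane-Anscombe +0.5 on zero cells
    ic_z: float = Z95
    bcpnn_priors: BCPNNPriors = field(default_factory=BCPNNPriors)
    mgps_prior: MGPSPrior = field(default_factory=MGPSPrior)
    ic_strong: float = 3.0
    ic_medium: float = 1.5


@dataclass(frozen=True)
class SignalMetrics:
    """All four statistics plus per-algorithm flags for one pair."""

    table: ContingencyTable
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_mgps: bool
    signal: bool
    ic_band: str  # "strong" / "medium" / "low"


def evaluate_signal(t: ContingencyTable, config: SignalConfig = SignalConfig()) -> SignalMetrics:
    """Compute all four statistics and apply the signal policy.

    A zero cell makes ROR/PRR undefined; with ``config.continuity`` the
    +0.5 correction is applied to those two (the Bayesian statistics use
    the raw counts either way), otherwise the error propagates.
    """
    t_freq: ContingencyTable | FractionalTable = t
    if config.continuity and min(t.a, t.b, t.c, t.d) == 0:
        t_freq = t.with_continuity()
    ror, ci = ror_estimate(t_freq)
    prr, chi2 = prr_estimate(t_freq)
    ic, ic025 = bcpnn_ic(t, config.bcpnn_priors, z=config.ic_z)
    ebgm, ebgm05 = mgps_ebgm(t, config.mgps_prior)
    flags = {
        "ror": t.a >= config.min_cases and ci[0] > config.ror_lower_ci,
        "prr": t.a >= config.min_cases
        and prr >= config.prr_threshold
        and chi2 >= config.chi2_threshold,
        "bcpnn": ic025 > config.ic025_threshold,
        "mgps": ebgm05 > config.ebgm05_threshold,
    }
    if config.policy == "all4":
        signal = all(flags.values())
    elif config.policy == "any1":
        signal = any(flags.values())
    else:
        raise ValueError(f"unknown signal policy {config.policy!r}")
    if ic025 > config.ic_strong:
        band = "strong"
    elif ic025 > config.ic_medium:
        band = "medium"
    else:
        band = "low"
    return SignalMetrics(
        table=t, ror=ror, ror_ci95=ci, prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
        flag_ror=flags["ror"], flag_prr=flags["prr"],
        flag_bcpnn=flags["bcpnn"], flag_mgps=flags["mgps"],
        signal=signal, ic_band=band,
    )


def screen(
    cases: Sequence[ReportCase],
    exposed: Sequence[ReportCase],
    annotation: Annotation | None = None,
    level: str = "PT",
    config: SignalConfig | None = None,
):
    """Screen every PT (or SOC) reported with the target drug.

    Returns a pandas DataFrame with one row per term whose exposed count
    reaches ``config.min_cases``, sorted by SOC then descending ROR. The
    per-term death count (death outcome among the ``a`` reports) feeds the
    clinical-priority rubric. PT screening defaults to the strict
    "all four algorithms" policy; SOC screening conventionally uses
    ``policy="any1"``.
    """
    import pandas as pd

    if config is None:
        config = SignalConfig(policy="all4" if level == "PT" else "any1")
    exposed_ids = {c.primaryid for c in exposed}

    def soc_of(pt: str) -> str:
        return annotation.lookup(pt).soc if annotation is not None else "UNMAPPED"

    if level == "PT":
        terms = sorted({pt for case in exposed for pt in case.events})
        def has_term(case: ReportCase, term: str) -> bool:
            return term in case.events
    elif level == "SOC":
        terms = sorted({soc_of(pt) for case in exposed for pt in case.events})
        def has_term(case: ReportCase, term: str) -> bool:
            return any(soc_of(pt) == term for pt in case.events)
    else:
        raise ValueError("level must be 'PT' or 'SOC'")

    rows = []
    for term in terms:
        t = build_table(cases, exposed_ids, lambda c, term=term: has_term(c, term))
        if t.a < config.min_cases:
            continue
        deaths = sum(
            1 for c in exposed if has_term(c, term) and "death" in c.outcomes
        )
        try:
            m = evaluate_signal(t, config)
        except ZeroCellError:
            ic, ic025 = bcpnn_ic(t, config.bcpnn_priors, z=config.ic_z)
            ebgm, ebgm05 = mgps_ebgm(t, config.mgps_prior)
            m = SignalMetrics(
                table=t, ror=float("nan"), ror_ci95=(float("nan"), float("nan")),
                prr=float("nan"), chi2=float("nan"), ic=ic, ic025=ic025,
                ebgm=ebgm, ebgm05=ebgm05, flag_ror=False, flag_prr=False,
                flag_bcpnn=ic025 > config.ic025_threshold,
                flag_mgps=ebgm05 > config.ebgm05_threshold,
                signal=False, ic_band="low",
            )
        ann = annotation.lookup(term) if (annotation and level == "PT") else None
        rows.append({
            "level": level,
            "soc": soc_of(term) if level == "PT" else term,
            "term": term,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": m.ror, "ror_lo": m.ror_ci95[0], "ror_hi": m.ror_ci95[1],
            "prr": m.prr, "chi2": m.chi2,
            "ic": m.ic, "ic025": m.ic025,
            "ebgm": m.ebgm, "ebgm05": m.ebgm05,
            "flag_ror": m.flag_ror, "flag_prr": m.flag_prr,
            "flag_bcpnn": m.flag_bcpnn, "flag_mgps": m.flag_mgps,
            "signal": m.signal, "ic_band": m.ic_band,
            "deaths": deaths,
            "dme": ann.dme if ann else False,
            "ime": ann.ime if ann else False,
            "evidence": ann.evidence if ann else None,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["soc", "ror"], ascending=[True, False]).reset_index(drop=True)
    return df
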