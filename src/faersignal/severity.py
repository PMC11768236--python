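"""Serious vs non-serious comparison of adverse-event profiles.

For each frequent PT the serious and non-serious report groups are
compared on reporting proportion with a 2x2 test chosen by cell size
(Fisher when a with-PT cell is 0, Yates-corrected chi-square when one is
1-4, Pearson otherwise), and age/weight distributions are compared with
the Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .contingency import ContingencyTable, pearson_statistic
from .ingest import ReportCase

__all__ = [
    "SeverityTestResult",
    "choose_test",
    "pearson_chi2",
    "yates_chi2",
    "fisher_exact",
    "mann_whitney",
    "compare_all",
]


@dataclass(frozen=True)
class SeverityTestResult:
    name: str
    n_serious: int
    n_nonserious: int
    test: str  # pearson / yates / fisher / mann_whitney
    statistic: float | None
    p_value: float


def choose_test(t: ContingencyTable) -> str:
    """Pick the 2x2 test from the observed with-PT cells (a and c).

    Zero cell -> Fisher exact; a cell of 1-4 -> Yates continuity
    correction; otherwise plain Pearson.
    """
    smallest = min(t.a, t.c)
    if smallest == 0:
        return "fisher"
    if smallest < 5:
        return "yates"
    return "pearson"


def pearson_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square (1 df) and its p-value."""
    stat = pearson_statistic(t.a, t.b, t.c, t.d)
    return stat, float(sps.chi2.sf(stat, df=1))


def yates_chi2(t: ContingencyTable) -> tuple[float, float]:
    """Yates continuity-corrected chi-square, clamped at zero."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ZeroDivisionError("chi-square undefined: zero margin")
    stat = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2 / denom
    return stat, float(sps.chi2.sf(stat, df=1))


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities
    no larger than the observed table's, margins fixed)."""
    _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Mann-Whitney U with normal approximation: returns (U, Z, two-sided p).

    U is computed from midrank sums; the variance carries the standard
    tie correction; no continuity correction is applied. Z is signed so
    that a smaller-than-expected U of ``x`` is negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mean_u = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u1, 0.0, 1.0
    z = (u1 - mean_u) / math.sqrt(var_u)
    p = 2 * float(sps.norm.sf(abs(z)))
    return u1, z, min(p, 1.0)


def compare_all(
    exposed: Sequence[ReportCase],
    min_count: int = 30,
) -> list[SeverityTestResult]:
    """Compare serious vs non-serious exposed reports.

    One proportion test per PT whose total exposed count reaches
    ``min_count`` (test per :func:`choose_test`), plus Mann-Whitney rows
    for age and weight and Pearson rows for sex (reports with the field
    missing are dropped from that comparison).
    """
    serious = [c for c in exposed if c.serious]
    nonserious = [c for c in exposed if not c.serious]
    n_s, n_ns = len(serious), len(nonserious)
    results: list[SeverityTestResult] = []

    for field, label in (("age_years", "age"), ("weight_kg", "weight")):
        xs = [getattr(c, field) for c in serious if getattr(c, field) is not None]
        ys = [getattr(c, field) for c in nonserious if getattr(c, field) is not None]
        if xs and ys:
            _, z, p = mann_whitney(xs, ys)
            results.append(SeverityTestResult(label, len(xs), len(ys), "mann_whitney", z, p))

    for sex in ("female", "male"):
        a = sum(1 for c in serious if c.sex == sex)
        c_ = sum(1 for c in nonserious if c.sex == sex)
        t = ContingencyTable(a, n_s - a, c_, n_ns - c_)
        try:
            stat, p = pearson_chi2(t)
            results.append(SeverityTestResult(f"sex:{sex}", a, c_, "pearson", stat, p))
        except ZeroDivisionError:
            pass

    pts = sorted({pt for c in exposed for pt in c.events})
    for pt in pts:
        a = sum(1 for c in serious if pt in c.events)
        c_ = sum(1 for c in nonserious if pt in c.events)
        if a + c_ < min_count:
            continue
        t = ContingencyTable(a, n_s - a, c_, n_ns - c_)
        test = choose_test(t)
        if test == "fisher":
            stat: float | None = None
            p = fisher_exact(t)
        elif test == "yates":
            stat, p = yates_chi2(t)
        else:
            stat, p = pearson_chi2(t)
        results.append(SeverityTestResult(pt, a, c_, test, stat, p))
    return results


def results_frame(results: Sequence[SeverityTestResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": r.name,
                "n_serious": r.n_serious,
                "n_nonserious": r.n_nonserious,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
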