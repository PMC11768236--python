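"""Semiquantitative clinical prioritization of detected signals.

Each signal PT is scored 0-2 on five items -- case count, ROR magnitude,
mortality proportion, EMA DME/IME listing, and the grade of supporting
clinical evidence -- and the 0-10 total is banded weak (<=4), moderate
(5-7) or strong (>=8). The default cut-points reproduce the published
canakinumab prioritization shipped in :mod:`faersignal.datasets` and are
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["PTAttributes", "Rubric", "PriorityScore", "score_pt", "band_counts"]


@dataclass(frozen=True)
class PTAttributes:
    """The five rubric inputs for one PT."""

    pt: str
    cases: int
    ror: float
    deaths: int = 0
    dme: bool = False
    ime: bool = False
    evidence: str | None = None  # "++", "+", "-" or None

    def __post_init__(self) -> None:
        if self.cases < 1:
            raise ValueError("a scored PT needs at least one case")
        if not 0 <= self.deaths <= self.cases:
            raise ValueError("deaths must lie in [0, cases]")


@dataclass(frozen=True)
class Rubric:
    """Cut-points of the five-item scale.

    ``cases_mid`` is the [lo, hi] closed range worth 1 point (above it: 2);
    ``ror`` scores 1 from ``ror_mid`` and 2 from ``ror_high``; the death
    proportion scores 1 strictly above ``death_mid`` up to ``death_high``
    and 2 above that. DME listing dominates IME. Evidence "++"/"+"/"-"
    map to 2/1/0.
    """

    cases_mid: tuple[int, int] = (10, 50)
    ror_mid: float = 2.0
    ror_high: float = 5.0
    death_mid: float = 0.25
    death_high: float = 0.50
    evidence_points: dict = field(
        default_factory=lambda: {"++": 2, "+": 1, "-": 0}
    )

    weak_max: int = 4
    moderate_max: int = 7

    def band(self, total: int) -> str:
        if total <= self.weak_max:
            return "weak"
        if total <= self.moderate_max:
            return "moderate"
        return "strong"


@dataclass(frozen=True)
class PriorityScore:
    pt: str
    item_scores: tuple[int, int, int, int, int]  # cases, ror, mortality, listing, evidence
    total: int
    band: str


def score_pt(attrs: PTAttributes, rubric: Rubric = Rubric()) -> PriorityScore:
    """Score one PT on the five-item scale."""
    lo, hi = rubric.cases_mid
    if attrs.cases < lo:
        s_cases = 0
    elif attrs.cases <= hi:
        s_cases = 1
    else:
        s_cases = 2

    if attrs.ror < rubric.ror_mid:
        s_ror = 0
    elif attrs.ror < rubric.ror_high:
        s_ror = 1
    else:
        s_ror = 2

    frac = attrs.deaths / attrs.cases
    if frac < rubric.death_mid:
        s_death = 0
    elif frac <= rubric.death_high:
        s_death = 1
    else:
        s_death = 2

    s_listing = 2 if attrs.dme else (1 if attrs.ime else 0)
    s_evidence = rubric.evidence_points.get(attrs.evidence, 0)

    items = (s_cases, s_ror, s_death, s_listing, s_evidence)
    total = sum(items)
    return PriorityScore(attrs.pt, items, total, rubric.band(total))


def band_counts(scores: Iterable[PriorityScore]) -> tuple[int, int, int]:
    """(n_weak, n_moderate, n_strong) over a collection of scores."""
    weak = moderate = strong = 0
    for s in scores:
        if s.band == "weak":
            weak += 1
        elif s.band == "moderate":
            moderate += 1
        else:
            strong += 1
    return weak, moderate, strong


def score_signal_frame(signals, rubric: Rubric = Rubric()):
    """Score every row of a signal DataFrame (as produced by ``stats.screen``).

    Expects columns term/a/ror/deaths/dme/ime/evidence; returns a new
    DataFrame with per-item scores, total and band.
    """
    import pandas as pd

    rows = []
    for r in signals.to_dict("records"):
        attrs = PTAttributes(
            pt=r["term"], cases=int(r["a"]), ror=float(r["ror"]),
            deaths=int(r.get("deaths", 0)),
            dme=bool(r.get("dme", False)), ime=bool(r.get("ime", False)),
            evidence=r.get("evidence"),
        )
        s = score_pt(attrs, rubric)
        rows.append({
            "pt": s.pt,
            "score_cases": s.item_scores[0],
            "score_ror": s.item_scores[1],
            "score_mortality": s.item_scores[2],
            "score_listing": s.item_scores[3],
            "score_evidence": s.item_scores[4],
            "total": s.total,
            "band": s.band,
        })
    return pd.DataFrame(rows)
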