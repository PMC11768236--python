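"""2x2 contingency tables for drug--event disproportionality.

Every statistic in this package (ROR, PRR, IC, EBGM, severity chi-square)
is a function of the classic spontaneous-report 2x2 table::

                    event     no event
    target drug       a          b
    other drugs       c          d

where counts are deduplicated *reports* (a report with the event means at
least one of its preferred terms satisfies the event predicate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .ingest import ReportCase

__all__ = [
    "ContingencyTable",
    "StratumSpec",
    "build_table",
    "stratified_tables",
    "pearson_statistic",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d); ``a`` is drug-with-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def expected_a(self) -> float:
        """Expected drug-with-event count under independence, (a+b)(a+c)/N."""
        if self.n == 0:
            raise ZeroDivisionError("empty table has no expected count")
        return self.n_exposed * self.n_event / self.n

    def with_continuity(self, k: float = 0.5) -> "FractionalTable":
        return FractionalTable(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class FractionalTable:
    """A continuity-corrected table; cells may be fractional."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class StratumSpec:
    """One stratum of a demographic dimension.

    ``dimension`` is one of ``sex``, ``age``, ``weight``, ``reporter``.
    For numeric dimensions (age in years, weight in kg) ``lo``/``hi``
    bound a half-open interval [lo, hi); for categorical dimensions
    ``categories`` lists the member labels.
    """

    dimension: str
    label: str
    lo: float | None = None
    hi: float | None = None
    categories: frozenset[str] | None = None

    NUMERIC = ("age", "weight")
    CATEGORICAL = ("sex", "reporter")

    def __post_init__(self) -> None:
        if self.dimension in self.NUMERIC:
            if self.categories is not None:
                raise ValueError(f"{self.dimension} strata are numeric intervals")
        elif self.dimension in self.CATEGORICAL:
            if not self.categories:
                raise ValueError(f"{self.dimension} strata need categories")
        else:
            raise ValueError(f"unknown stratification dimension {self.dimension!r}")

    def contains(self, case: ReportCase) -> bool | None:
        """True/False membership, or None when the field is missing."""
        if self.dimension == "age":
            value = case.age_years
        elif self.dimension == "weight":
            value = case.weight_kg
        elif self.dimension == "sex":
            value = case.sex if case.sex != "unknown" else None
        else:
            value = case.reporter if case.reporter != "unknown" else None
        if value is None:
            return None
        if self.categories is not None:
            return value in self.categories
        lo = -float("inf") if self.lo is None else self.lo
        hi = float("inf") if self.hi is None else self.hi
        return lo <= float(value) < hi

    def overlaps(self, other: "StratumSpec") -> bool:
        if self.dimension != other.dimension:
            return False
        if self.categories is not None and other.categories is not None:
            return bool(self.categories & other.categories)
        lo1 = -float("inf") if self.lo is None else self.lo
        hi1 = float("inf") if self.hi is None else self.hi
        lo2 = -float("inf") if other.lo is None else other.lo
        hi2 = float("inf") if other.hi is None else other.hi
        return lo1 < hi2 and lo2 < hi1


def default_strata() -> list[StratumSpec]:
    """Study-style subgroups: sex, age <18/18-59/>=60, weight <50/50-100/>100, reporter type."""
    hp = frozenset({"physician", "pharmacist", "other_health_professional"})
    return [
        StratumSpec("sex", "female", categories=frozenset({"female"})),
        StratumSpec("sex", "male", categories=frozenset({"male"})),
        StratumSpec("age", "<18 years", hi=18),
        StratumSpec("age", "18-59 years", lo=18, hi=60),
        StratumSpec("age", ">=60 years", lo=60),
        StratumSpec("weight", "<50 kg", hi=50),
        StratumSpec("weight", "50-100 kg", lo=50, hi=100.000001),
        StratumSpec("weight", ">100 kg", lo=100.000001),
        StratumSpec("reporter", "health professional", categories=hp),
        StratumSpec("reporter", "consumer", categories=frozenset({"consumer"})),
    ]


EventPredicate = Callable[[ReportCase], bool]


def build_table(
    cases: Sequence[ReportCase],
    exposed_ids: Iterable[str],
    event_predicate: EventPredicate,
    subset_filter: Callable[[ReportCase], bool] | None = None,
) -> ContingencyTable:
    """Count the 2x2 cells over ``cases`` (optionally restricted by ``subset_filter``)."""
    exposed = set(exposed_ids)
    a = b = c = d = 0
    for case in cases:
        if subset_filter is not None and not subset_filter(case):
            continue
        has_event = event_predicate(case)
        if case.primaryid in exposed:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def stratified_tables(
    cases: Sequence[ReportCase],
    exposed_ids: Iterable[str],
    event_predicate: EventPredicate,
    strata: Sequence[StratumSpec],
    subset_filter: Callable[[ReportCase], bool] | None = None,
) -> dict[tuple[str, str], ContingencyTable]:
    """One table per stratum, keyed by (dimension, label).

    Cases whose stratification field is missing are excluded from that
    dimension's tables. Strata within a dimension must be disjoint.
    """
    for i, s in enumerate(strata):
        for t in strata[i + 1 :]:
            if s.overlaps(t):
                raise ValueError(f"overlapping strata {s.label!r} and {t.label!r}")
    exposed = set(exposed_ids)
    out: dict[tuple[str, str], ContingencyTable] = {}
    for spec in strata:

        def in_stratum(case: ReportCase, spec: StratumSpec = spec) -> bool:
            member = spec.contains(case)
            if member is None:
                return False
            if subset_filter is not None and not subset_filter(case):
                return False
            return member

        out[(spec.dimension, spec.label)] = build_table(
            cases, exposed, event_predicate, subset_filter=in_stratum
        )
    return out


def pearson_statistic(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square statistic (1 df, no continuity correction).

    ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``. Shared by the PRR signal
    criterion and the serious/non-serious comparison so there is a single
    source of truth.
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ZeroDivisionError("chi-square undefined: zero margin")
    return n * (a * d - b * c) ** 2 / denom
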