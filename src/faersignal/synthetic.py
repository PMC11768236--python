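"""Synthetic FAERS quarters with fully known ground truth.

The generator emulates the structure of a spontaneous-report extract --
demographics with FAERS unit codes, drug rows with role codes, one or
more PT reactions per report, serious-outcome codes, event/therapy dates,
duplicate case versions, and field-level missingness -- while planting
drug--event associations of known relative risk (optionally modified
within demographic strata) and Weibull-distributed onset times. Every
report's true assignment is retained, so each pipeline stage can be
tested against exact or analytic expectations rather than against itself.

Events are assigned independently per PT given exposure; real
co-reporting correlation is deliberately not modelled (it does not enter
any 2x2 statistic in this package).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import RawTables, ReportCase, IngestLog
from .contingency import ContingencyTable

__all__ = [
    "PTSpec",
    "StratumModifier",
    "SyntheticConfig",
    "GroundTruth",
    "simulate",
    "generate",
    "expected_tables",
    "write_quarter",
    "default_pt_catalog",
]

FILLER_PT = "Drug ineffective"
FILLER_SOC = "General disorders and administration site conditions"
BACKGROUND_DRUGS = ("METHOTREXATE", "PREDNISONE", "IBUPROFEN", "ADALIMUMAB", "COLCHICINE")


@dataclass(frozen=True)
class PTSpec:
    pt: str
    soc: str
    background_prob: float
    serious_prob: float = 0.4
    death_prob: float = 0.02


@dataclass(frozen=True)
class StratumModifier:
    """Multiplies a planted relative risk inside one demographic stratum."""

    dimension: str  # sex / age / weight / reporter
    multiplier: float
    category: str | None = None
    lo: float | None = None
    hi: float | None = None

    def applies(self, sex: str, age: float, weight: float, reporter: str) -> bool:
        if self.dimension == "sex":
            return sex == self.category
        if self.dimension == "reporter":
            return reporter == self.category
        value = age if self.dimension == "age" else weight
        lo = -math.inf if self.lo is None else self.lo
        hi = math.inf if self.hi is None else self.hi
        return lo <= value < hi


def default_pt_catalog() -> tuple[PTSpec, ...]:
    """A small infection-dominated catalog echoing the canakinumab profile."""
    return (
        PTSpec("Pneumonia", "Respiratory, thoracic, and mediastinal disorders", 0.010, 0.85, 0.12),
        PTSpec("Nasopharyngitis", "Respiratory, thoracic, and mediastinal disorders", 0.012, 0.30, 0.01),
        PTSpec("Cough", "Respiratory, thoracic, and mediastinal disorders", 0.020, 0.35, 0.02),
        PTSpec("Infection", "Infections and infestations", 0.008, 0.70, 0.07),
        PTSpec("Gastroenteritis", "Infections and infestations", 0.004, 0.60, 0.01),
        PTSpec("Appendicitis", "Infections and infestations", 0.002, 0.80, 0.00),
        PTSpec("Varicella", "Infections and infestations", 0.001, 0.45, 0.00),
        PTSpec("Deafness", "Ear and labyrinth disorders", 0.002, 0.75, 0.00),
        PTSpec("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.030, 0.35, 0.01),
        PTSpec("Rash", "Skin and subcutaneous tissue disorders", 0.035, 0.30, 0.01),
        PTSpec("Malaise", "General disorders and administration site conditions", 0.030, 0.40, 0.01),
        PTSpec("Abdominal pain", "Gastrointestinal disorders", 0.025, 0.55, 0.01),
        PTSpec("Headache", "Nervous system disorders", 0.040, 0.25, 0.00),
        PTSpec("Pyrexia", "General disorders and administration site conditions", 0.025, 0.45, 0.01),
        PTSpec("C-reactive protein increased", "Investigations", 0.003, 0.55, 0.02),
        PTSpec("Brain oedema", "Injury, poisoning, and procedural complications", 0.0005, 0.95, 0.45),
    )


def default_planted_effects() -> dict[str, tuple[float, tuple[StratumModifier, ...]]]:
    """PT -> (relative risk, stratum modifiers): study-like infection signals."""
    older = StratumModifier("age", 1.8, lo=60)
    heavy = StratumModifier("weight", 1.8, lo=100)
    male = StratumModifier("sex", 1.4, category="male")
    return {
        "Pneumonia": (2.3, (older, heavy, male)),
        "Infection": (2.5, (older, male)),
        "Gastroenteritis": (6.0, ()),
        "Appendicitis": (5.6, ()),
        "Deafness": (3.0, ()),
        "Varicella": (8.0, ()),
        "C-reactive protein increased": (7.0, ()),
        "Brain oedema": (3.0, ()),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic quarter."""

    n_reports: int = 20_000
    exposure_prob: float = 0.05
    pt_catalog: tuple[PTSpec, ...] = field(default_factory=default_pt_catalog)
    planted_effects: dict = field(default_factory=default_planted_effects)
    sex_probs: tuple[float, float] = (0.55, 0.40)  # female, male; rest unknown
    reporter_probs: tuple[float, float, float, float] = (0.41, 0.32, 0.17, 0.08)
    # consumer, physician, pharmacist, other HP; rest unknown
    countries: tuple[tuple[str, float], ...] = (
        ("US", 0.56), ("CA", 0.11), ("JP", 0.10), ("DE", 0.05),
        ("GB", 0.02), ("FR", 0.16),
    )
    tto_alpha: float = 100.0
    tto_beta: float = 0.9
    tto_per_pt: dict = field(default_factory=dict)  # pt -> (alpha, beta)
    duplicate_rate: float = 0.10
    missing_rates: dict = field(
        default_factory=lambda: {
            "age": 0.10, "weight": 0.35, "sex": 0.05, "reporter": 0.05,
            "country": 0.02, "event_dt": 0.35, "start_dt": 0.35,
        }
    )
    concomitant_target_prob: float = 0.01  # unexposed carrying the drug with role C
    seed: int = 0

    def tto_params(self, pt: str) -> tuple[float, float]:
        return self.tto_per_pt.get(pt, (self.tto_alpha, self.tto_beta))


@dataclass
class GroundTruth:
    """Per-report truth plus bookkeeping for the emitted files."""

    records: pd.DataFrame  # one row per unique case (final version)
    config: SyntheticConfig
    n_demo_rows: int
    n_clipped: dict

    @property
    def n_unique_cases(self) -> int:
        return len(self.records)

    def exposed_count(self) -> int:
        return int(self.records["exposed"].sum())

    def contingency(self, pt: str) -> ContingencyTable:
        has = self.records["events"].str.split(";").apply(lambda evs: pt in evs)
        exp = self.records["exposed"].astype(bool)
        return ContingencyTable(
            int((exp & has).sum()), int((exp & ~has).sum()),
            int((~exp & has).sum()), int((~exp & ~has).sum()),
        )

    def tto_days(self, exposed_only: bool = True, window: float | None = 365.0) -> list[float]:
        """Retained onset delays matching compute_tto's rules (0 -> 0.5)."""
        out = []
        for r in self.records.itertuples():
            if exposed_only and not r.exposed:
                continue
            if r.onset_days < 0 or r.event_date == "" or r.start_date == "":
                continue
            v = float(r.onset_days) if r.onset_days > 0 else 0.5
            if window is not None and v > window:
                continue
            out.append(v)
        return out


def _event_prob(
    spec: PTSpec, exposed: bool, config: SyntheticConfig,
    sex: str, age: float, weight: float, reporter: str,
) -> tuple[float, bool]:
    p = spec.background_prob
    if exposed and spec.pt in config.planted_effects:
        rr, mods = config.planted_effects[spec.pt]
        p *= rr
        for m in mods:
            if m.applies(sex, age, weight, reporter):
                p *= m.multiplier
    clipped = p > 1.0
    return min(p, 1.0), clipped


def _draw_demographics(rng: np.random.Generator, config: SyntheticConfig):
    pf, pm = config.sex_probs
    u = rng.random()
    sex = "female" if u < pf else ("male" if u < pf + pm else "unknown")
    # bimodal age: paediatric autoinflammatory cohort plus adults
    if rng.random() < 0.5:
        age = float(np.clip(rng.gamma(3.0, 4.0), 0.1, 17.9))
    else:
        age = float(np.clip(rng.normal(47.0, 18.0), 18.0, 95.0))
    if age < 18:
        weight = float(np.clip(10.0 + 3.2 * age + rng.normal(0.0, 4.0), 3.0, 90.0))
    else:
        weight = float(np.clip(rng.normal(72.0, 16.0), 35.0, 160.0))
    pc, pp, pph, pohp = config.reporter_probs
    u = rng.random()
    if u < pc:
        reporter = "consumer"
    elif u < pc + pp:
        reporter = "physician"
    elif u < pc + pp + pph:
        reporter = "pharmacist"
    elif u < pc + pp + pph + pohp:
        reporter = "other_health_professional"
    else:
        reporter = "unknown"
    labels, weights = zip(*config.countries)
    cum = np.cumsum(np.asarray(weights) / sum(weights))
    country = labels[int(np.searchsorted(cum, rng.random()))]
    return sex, age, weight, reporter, country


def simulate(config: SyntheticConfig) -> tuple[list[ReportCase], GroundTruth]:
    """Draw one cohort; returns analysis-ready cases plus the ground truth.

    The returned cases are the *deduplicated* view (one per caseid);
    duplicate versions only exist in the file representation produced by
    :func:`write_quarter` / :func:`generate`.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.pt_catalog
    records = []
    cases: list[ReportCase] = []
    n_clipped: dict[str, int] = {}
    n_demo_rows = 0
    base = _dt.date(2018, 1, 1)

    for i in range(config.n_reports):
        caseid = str(1_000_000 + i)
        exposed = rng.random() < config.exposure_prob
        sex, age, weight, reporter, country = _draw_demographics(rng, config)

        events = []
        serious_outcomes: set[str] = set()
        for spec in specs:
            p, clipped = _event_prob(spec, exposed, config, sex, age, weight, reporter)
            if clipped:
                n_clipped[spec.pt] = n_clipped.get(spec.pt, 0) + 1
            if rng.random() < p:
                events.append(spec.pt)
                u = rng.random()
                if u < spec.death_prob:
                    serious_outcomes.add("death")
                elif u < spec.serious_prob:
                    v = rng.random()
                    if v < 0.70:
                        serious_outcomes.add("hospitalization")
                    elif v < 0.95:
                        serious_outcomes.add("other_serious")
                    elif v < 0.98:
                        serious_outcomes.add("life_threatening")
                    else:
                        serious_outcomes.add("disability")
        if not events:
            events.append(FILLER_PT)
            if rng.random() < 0.25:
                serious_outcomes.add("other_serious")

        start_date = base + _dt.timedelta(days=int(rng.integers(0, 2190)))
        onset_pt = events[int(rng.integers(0, len(events)))]
        al, be = config.tto_params(onset_pt)
        onset = int(round(al * (-math.log(rng.random())) ** (1.0 / be)))
        event_date = start_date + _dt.timedelta(days=onset)
        fda_date = event_date + _dt.timedelta(days=int(rng.integers(5, 120)))

        miss = {f: rng.random() < r for f, r in config.missing_rates.items()}
        # emitted age unit: months for infants sometimes, decades rarely
        if miss["age"]:
            age_str, age_cod = "", ""
        elif age < 2 and rng.random() < 0.5:
            age_str, age_cod = str(int(round(age * 12))), "MON"
        elif rng.random() < 0.03:
            age_str, age_cod = str(int(age // 10)), "DEC"
        else:
            age_str, age_cod = f"{age:.1f}", "YR"
        if miss["weight"]:
            wt_str, wt_cod = "", ""
        elif rng.random() < 0.25:
            wt_str, wt_cod = f"{weight / 0.45359237:.1f}", "LBS"
        else:
            wt_str, wt_cod = f"{weight:.1f}", "KG"

        sex_code = {"female": "F", "male": "M", "unknown": ""}[sex] if not miss["sex"] else ""
        occp = {
            "consumer": "CN", "physician": "MD", "pharmacist": "PH",
            "other_health_professional": "OT", "unknown": "",
        }[reporter] if not miss["reporter"] else ""
        country_str = country if not miss["country"] else ""
        event_dt_str = event_date.strftime("%Y%m%d") if not miss["event_dt"] else ""
        start_dt_str = start_date.strftime("%Y%m%d") if not miss["start_dt"] else ""

        drugs: list[tuple[str, str]] = []
        if exposed:
            drugs.append(("CANAKINUMAB" if rng.random() < 0.5 else "ILARIS", "PS"))
        elif rng.random() < config.concomitant_target_prob:
            drugs.append(("CANAKINUMAB", "C"))
        n_bg = int(rng.integers(1, 4))
        for j in range(n_bg):
            drugs.append((
                BACKGROUND_DRUGS[int(rng.integers(0, len(BACKGROUND_DRUGS)))],
                "PS" if (not exposed and j == 0) else ("SS" if rng.random() < 0.5 else "C"),
            ))

        duplicate = rng.random() < config.duplicate_rate
        n_demo_rows += 2 if duplicate else 1
        final_pid = f"{caseid}2" if duplicate else f"{caseid}1"

        # the analysis-ready case mirrors exactly what the parser would yield
        case_age = None
        if age_str:
            case_age = float(age_str) * {"MON": 1 / 12, "DEC": 10.0, "YR": 1.0}[age_cod]
        case_wt = None
        if wt_str:
            case_wt = float(wt_str) * (0.45359237 if wt_cod == "LBS" else 1.0)
        cases.append(ReportCase(
            primaryid=final_pid,
            caseid=caseid,
            fda_date=fda_date,
            sex=sex if sex_code else "unknown",
            age_years=case_age,
            weight_kg=case_wt,
            country=country_str or None,
            reporter=reporter if occp else "unknown",
            outcomes=frozenset(serious_outcomes),
            drugs=tuple(drugs),
            events=frozenset(events),
            event_date=event_date if event_dt_str else None,
            therapy_start=start_date if start_dt_str else None,
        ))
        records.append({
            "caseid": caseid,
            "primaryid": final_pid,
            "duplicate": duplicate,
            "exposed": exposed,
            "drugs": "|".join(f"{name}:{role}" for name, role in drugs),
            "sex": sex, "age": age, "weight": weight,
            "reporter": reporter, "country": country,
            "events": ";".join(events),
            "serious": bool(serious_outcomes),
            "death": "death" in serious_outcomes,
            "onset_days": onset if (event_dt_str and start_dt_str) else -1,
            "onset_pt": onset_pt,
            "age_str": age_str, "age_cod": age_cod,
            "wt_str": wt_str, "wt_cod": wt_cod,
            "sex_code": sex_code, "occp": occp,
            "country_str": country_str,
            "event_date": event_dt_str, "start_date": start_dt_str,
            "fda_date": fda_date.strftime("%Y%m%d"),
            "outcomes": ";".join(sorted(serious_outcomes)),
        })

    truth = GroundTruth(
        records=pd.DataFrame(records),
        config=config,
        n_demo_rows=n_demo_rows,
        n_clipped=n_clipped,
    )
    for pt, count in n_clipped.items():
        if count > 0.05 * config.n_reports:
            import warnings

            warnings.warn(
                f"planted effect on {pt!r} clipped in {count} draws; "
                "relative risk inconsistent with background probability",
                stacklevel=2,
            )
    return cases, truth


OUTCOME_TO_CODE = {
    "death": "DE", "life_threatening": "LT", "hospitalization": "HO",
    "disability": "DS", "other_serious": "OT",
}


def _raw_frames(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    demo_rows, drug_rows, reac_rows, outc_rows, ther_rows = [], [], [], [], []
    rng = np.random.default_rng(truth.config.seed + 17)
    for r in truth.records.itertuples():
        versions = [(f"{r.caseid}1", r.fda_date)]
        if r.duplicate:
            earlier = (
                _dt.datetime.strptime(r.fda_date, "%Y%m%d").date()
                - _dt.timedelta(days=int(rng.integers(30, 200)))
            ).strftime("%Y%m%d")
            versions = [(f"{r.caseid}1", earlier), (f"{r.caseid}2", r.fda_date)]
        # children are replicated for every version so dedup has real work to do
        for pid, fda in versions:
            demo_rows.append({
                "primaryid": pid, "caseid": r.caseid, "fda_dt": fda,
                "event_dt": r.event_date, "age": r.age_str, "age_cod": r.age_cod,
                "sex": r.sex_code, "wt": r.wt_str, "wt_cod": r.wt_cod,
                "reporter_country": r.country_str, "occp_cod": r.occp,
            })
            for pt in r.events.split(";"):
                reac_rows.append({"primaryid": pid, "caseid": r.caseid, "pt": pt})
            for oc in (r.outcomes.split(";") if r.outcomes else []):
                outc_rows.append({
                    "primaryid": pid, "caseid": r.caseid,
                    "outc_cod": OUTCOME_TO_CODE[oc],
                })
            for seq, entry in enumerate(r.drugs.split("|"), start=1):
                name, role = entry.rsplit(":", 1)
                drug_rows.append({
                    "primaryid": pid, "caseid": r.caseid, "drug_seq": str(seq),
                    "role_cod": role, "drugname": name,
                })
            ther_rows.append({
                "primaryid": pid, "caseid": r.caseid, "dsg_drug_seq": "1",
                "start_dt": r.start_date, "end_dt": "",
            })
    return {
        "demo": pd.DataFrame(demo_rows, dtype="string"),
        "drug": pd.DataFrame(drug_rows, dtype="string"),
        "reac": pd.DataFrame(reac_rows, dtype="string"),
        "outc": pd.DataFrame(outc_rows, dtype="string") if outc_rows else
                pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"], dtype="string"),
        "ther": pd.DataFrame(ther_rows, dtype="string"),
    }


def write_quarter(truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write the FAERS-dialect files plus ground-truth and config sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = _raw_frames(truth)
    paths = {}
    for name, df in frames.items():
        path = directory / f"{name.upper()}.txt"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write("$".join("" if pd.isna(v) else str(v) for v in row) + "\n")
        paths[name] = path
    truth.records.to_csv(directory / "ground_truth.csv", index=False)
    cfg = dataclasses.asdict(truth.config)
    cfg["pt_catalog"] = [dataclasses.asdict(s) for s in truth.config.pt_catalog]
    cfg["planted_effects"] = {
        pt: {"relative_risk": rr, "modifiers": [dataclasses.asdict(m) for m in mods]}
        for pt, (rr, mods) in truth.config.planted_effects.items()
    }
    (directory / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    paths["ground_truth"] = directory / "ground_truth.csv"
    paths["config"] = directory / "config.json"
    return paths


def generate(config: SyntheticConfig, directory: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Simulate a cohort and write it as a FAERS-format quarter."""
    _, truth = simulate(config)
    paths = write_quarter(truth, directory)
    return paths, truth


def _demographic_sample(config: SyntheticConfig, n: int = 100_000):
    rng = np.random.default_rng(12345)  # fixed: a quadrature device, not a data seed
    return [_draw_demographics(rng, config) for _ in range(n)]


def expected_tables(config: SyntheticConfig) -> dict[str, ContingencyTable]:
    """Analytic expected 2x2 cells per catalog PT (real-valued, pre-sampling).

    For planted effects with stratum modifiers the marginal exposed-event
    probability integrates the clipped per-stratum probability over the
    demographic distribution; that integral is evaluated on a fixed
    deterministic quadrature sample, so the result does not depend on the
    cohort seed.
    """
    n = config.n_reports
    pe = config.exposure_prob
    needs_demo = any(
        mods for _, mods in config.planted_effects.values()
    )
    demo = _demographic_sample(config) if needs_demo else None
    out: dict[str, ContingencyTable] = {}

    class _Real(ContingencyTable):  # allow float cells for expectations
        def __post_init__(self):
            pass

    for spec in config.pt_catalog:
        if spec.pt in config.planted_effects:
            rr, mods = config.planted_effects[spec.pt]
            if mods:
                ps = [
                    _event_prob(spec, True, config, sex, age, wt, rep)[0]
                    for sex, age, wt, rep, _ in demo
                ]
                p_exp = float(np.mean(ps))
            else:
                p_exp = min(spec.background_prob * rr, 1.0)
        else:
            p_exp = spec.background_prob
        p_bg = spec.background_prob
        a = n * pe * p_exp
        b = n * pe * (1 - p_exp)
        c = n * (1 - pe) * p_bg
        d = n * (1 - pe) * (1 - p_bg)
        out[spec.pt] = _Real(a, b, c, d)
    return out
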