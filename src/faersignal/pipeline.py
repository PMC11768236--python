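"""End-to-end orchestration: quarters in, analysis tables out.

``run_all`` executes ingest -> dedup -> describe -> PT/SOC screening ->
clinical prioritization -> stratified serious-SOC analysis -> serious vs
non-serious comparison -> time-to-onset, writing one CSV per stage plus a
manifest (config hash, seed, per-stage record counts) so the whole flow
can be accounted for from the artifact directory alone.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import contingency, ingest, priority, severity, stats, tto

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "describe", "run_all"]


class PipelineConfig(BaseModel):
    """Validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    quarters: list[str]
    pt_to_soc: str | None = None
    dme: str | None = None
    ime: str | None = None
    evidence: str | None = None
    drug_names: list[str] = Field(default_factory=lambda: ["canakinumab", "ilaris"])
    roles: list[str] = Field(default_factory=lambda: ["PS"])
    dedup_strategy: str = "caseid-latest"
    min_cases: int = 3
    pt_policy: str = "all4"
    soc_policy: str = "any1"
    continuity: bool = False
    min_severity_count: int = 30
    serious_soc: str = "Infections and infestations"
    tto_window: float | None = 365.0
    output_dir: str = "faersignal_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


OUTCOME_ORDER = [
    ("hospitalization", "Hospitalization - Initial or Prolonged"),
    ("other_serious", "Other Serious Events"),
    ("death", "Death"),
    ("disability", "Disability"),
    ("life_threatening", "Threat to Life"),
]


def describe(
    cases: Sequence[ingest.ReportCase],
    exposed: Sequence[ingest.ReportCase],
) -> pd.DataFrame:
    """Descriptive summary of the exposed cohort (long-format table).

    Counts and percentages by sex, reporter and top countries; age and
    weight medians with quartiles; serious-outcome categories (a report
    can carry several); reports per year.
    """
    n = len(exposed)
    rows: list[dict] = []

    def add(section: str, label: str, value, pct: float | None = None) -> None:
        rows.append({"section": section, "label": label, "value": value, "pct": pct})

    add("cohort", "exposed reports", n)
    add("cohort", "total reports", len(cases))
    for sex in ("female", "male", "unknown"):
        k = sum(1 for c in exposed if c.sex == sex)
        add("sex", sex, k, 100 * k / n if n else 0.0)
    ages = [c.age_years for c in exposed if c.age_years is not None]
    if ages:
        s = pd.Series(ages)
        add("age_years", "median", float(s.median()))
        add("age_years", "q1", float(s.quantile(0.25)))
        add("age_years", "q3", float(s.quantile(0.75)))
    weights = [c.weight_kg for c in exposed if c.weight_kg is not None]
    if weights:
        s = pd.Series(weights)
        add("weight_kg", "median", float(s.median()))
    countries = pd.Series([c.country for c in exposed if c.country]).value_counts()
    for country, k in countries.head(5).items():
        add("country", str(country), int(k), 100 * int(k) / n if n else 0.0)
    for rep in ("consumer", "physician", "pharmacist", "other_health_professional", "unknown"):
        k = sum(1 for c in exposed if c.reporter == rep)
        add("reporter", rep, k, 100 * k / n if n else 0.0)
    for key, label in OUTCOME_ORDER:
        k = sum(1 for c in exposed if key in c.outcomes)
        add("outcome", label, k, 100 * k / n if n else 0.0)
    years = pd.Series(
        [c.fda_date.year for c in exposed if c.fda_date is not None]
    ).value_counts().sort_index()
    for year, k in years.items():
        add("reporting_year", str(year), int(k), 100 * int(k) / n if n else 0.0)
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory. Returns its path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    try:
        quarters = [ingest.read_quarter(q) for q in config.quarters]
        raw = ingest.concat_quarters(quarters)
        stage("ingest", **raw.row_counts())

        deduped = ingest.deduplicate(raw, config.dedup_strategy)
        stage("dedup", demo_in=len(raw.demo), demo_out=len(deduped.demo))

        cases = ingest.normalize_cases(deduped)
        exposed, _ = ingest.select_target_reports(
            cases, config.drug_names, config.roles
        )
        exposed_ids = {c.primaryid for c in exposed}
        stage("select", cases=len(cases), exposed=len(exposed))

        describe(cases, exposed).to_csv(out / "describe.csv", index=False)

        annotation = None
        if config.pt_to_soc:
            annotation = ingest.Annotation.from_tsvs(
                config.pt_to_soc, config.dme, config.ime, config.evidence
            )

        sig_cfg = stats.SignalConfig(
            min_cases=config.min_cases, policy=config.pt_policy,
            continuity=config.continuity,
        )
        pt_signals = stats.screen(cases, exposed, annotation, "PT", sig_cfg)
        pt_signals.to_csv(out / "signals_pt.csv", index=False)
        stage("screen_pt", terms=len(pt_signals),
              signals=int(pt_signals["signal"].sum()) if len(pt_signals) else 0)

        soc_cfg = stats.SignalConfig(
            min_cases=config.min_cases, policy=config.soc_policy,
            continuity=config.continuity,
        )
        soc_signals = stats.screen(cases, exposed, annotation, "SOC", soc_cfg)
        soc_signals.to_csv(out / "signals_soc.csv", index=False)
        stage("screen_soc", terms=len(soc_signals),
              signals=int(soc_signals["signal"].sum()) if len(soc_signals) else 0)

        flagged = pt_signals[pt_signals["signal"]] if len(pt_signals) else pt_signals
        scores = priority.score_signal_frame(flagged) if len(flagged) else pd.DataFrame()
        scores.to_csv(out / "priority.csv", index=False)
        if len(scores):
            w, m, s = (
                int((scores["band"] == b).sum()) for b in ("weak", "moderate", "strong")
            )
        else:
            w = m = s = 0
        stage("priority", weak=w, moderate=m, strong=s)

        if annotation is not None:
            soc_pts = {
                pt for pt in annotation.pt_to_soc
                if annotation.pt_to_soc[pt] == config.serious_soc
            }

            def serious_soc_event(case: ingest.ReportCase) -> bool:
                return case.serious and any(
                    annotation.lookup(pt).soc == config.serious_soc for pt in case.events
                )

            strata = contingency.default_strata()
            tables = contingency.stratified_tables(
                cases, exposed_ids, serious_soc_event, strata
            )
            strat_rows = []
            for (dim, label), t in tables.items():
                row = {"dimension": dim, "stratum": label,
                       "a": t.a, "b": t.b, "c": t.c, "d": t.d}
                try:
                    ror, (lo, hi) = stats.ror_estimate(t)
                    row.update(ror=ror, ror_lo=lo, ror_hi=hi)
                except stats.ZeroCellError:
                    row.update(ror=float("nan"), ror_lo=float("nan"), ror_hi=float("nan"))
                strat_rows.append(row)
            pd.DataFrame(strat_rows).to_csv(out / "stratified.csv", index=False)
            stage("stratify", strata=len(strat_rows))

        sev = severity.compare_all(exposed, config.min_severity_count)
        severity.results_frame(sev).to_csv(out / "severity.csv", index=False)
        stage("severity", comparisons=len(sev))

        sample = tto.compute_tto(exposed, window=config.tto_window)
        tto_rows = []
        if sample.n:
            med, (q1, q3), k = tto.tto_summary(sample)
            row = {"group": "all", "n": k, "median": med, "q1": q1, "q3": q3}
            try:
                fit = tto.weibull_mle(sample)
                row.update(
                    alpha=fit.alpha, alpha_lo=fit.alpha_ci95[0], alpha_hi=fit.alpha_ci95[1],
                    beta=fit.beta, beta_lo=fit.beta_ci95[0], beta_hi=fit.beta_ci95[1],
                    failure_type=fit.failure_type,
                )
            except ValueError as err:
                row.update(failure_type=f"unfit ({err})")
            tto_rows.append(row)
        pd.DataFrame(tto_rows).to_csv(out / "tto.csv", index=False)
        stage("tto", retained=sample.n, excluded_missing=sample.n_excluded_missing,
              excluded_negative=sample.n_excluded_negative)
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        done = ", ".join(manifest["stages"]) or "none"
        raise RuntimeError(
            f"pipeline failed after stages [{done}]: {err}"
        ) from err

    manifest["finished_utc"] = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
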