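"""Bundled reference tables from the published canakinumab FAERS analysis.

Two small TSVs ship with the package and serve as regression fixtures:

* ``canakinumab_pt_signals``: the 71 preferred terms that met all four
  disproportionality criteria, with their printed case counts, ROR (and
  CI), IC (and IC025), death counts, EMA DME/IME listing, evidence grade,
  and the published clinical-priority band and score.
* ``canakinumab_severity``: the 37 frequent PTs (n >= 30) compared
  between serious and non-serious reports, with the printed counts, test
  choice and chi-square statistic. The group totals were 17,955 serious
  and 10,541 non-serious reports.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "canakinumab_pt_signals",
    "canakinumab_severity",
    "SERIOUS_TOTAL",
    "NONSERIOUS_TOTAL",
]

SERIOUS_TOTAL = 17_955
NONSERIOUS_TOTAL = 10_541


def _read(name: str) -> pd.DataFrame:
    with resources.files("faersignal.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def canakinumab_pt_signals() -> pd.DataFrame:
    """The 71-PT signal table with priority attributes and published scores."""
    df = _read("canakinumab_pt_signals.tsv")
    df["dme"] = df["listing"] == "DME"
    df["ime"] = df["listing"] == "IME"
    return df


def canakinumab_severity() -> pd.DataFrame:
    """Serious vs non-serious per-PT counts, printed statistics and test choice."""
    return _read("canakinumab_severity.tsv")
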