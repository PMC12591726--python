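"""Cohort container and plain-CSV persistence.

A cohort is carried as two pandas DataFrames:

* ``baseline`` — one row per participant (wide): arm, covariates, repeated
  MSK-HQ scores, utilities, absence days, and cost components in EUR.
  Missing values are NaN (written as empty CSV fields).
* ``panel`` — long person-month table: ``id, month, absence_fraction,
  benefit_received`` for months 1..follow-up.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASELINE_COLUMNS = [
    "id", "arm", "age", "sex", "education", "workability",
    "physical_activity", "prior_absence_days", "baseline_absence_days",
    "employer_followup", "risk_group",
    "mskhq_0", "mskhq_3", "mskhq_6", "mskhq_9", "mskhq_12",
    "utility_baseline", "utility_12m",
    "absence_days", "unpaid_hours",
    "cost_intervention", "cost_healthcare_primary", "cost_healthcare_secondary",
    "cost_absenteeism", "cost_unpaid", "cost_total",
]

PANEL_COLUMNS = ["id", "month", "absence_fraction", "benefit_received"]

COST_COMPONENTS = [
    "cost_intervention", "cost_healthcare_primary", "cost_healthcare_secondary",
    "cost_absenteeism", "cost_unpaid",
]

MSKHQ_COLUMNS = ["mskhq_0", "mskhq_3", "mskhq_6", "mskhq_9", "mskhq_12"]

# preplanned adjustment set shared by the effectiveness and costing analyses
ADJUSTMENT_COVARIATES = [
    "age", "sex", "education", "prior_absence_days", "workability",
    "mskhq_0", "physical_activity", "employer_followup",
]


class CohortValidationError(ValueError):
    """An invariant violation, citing the offending table/row."""


@dataclass
class Cohort:
    baseline: pd.DataFrame
    panel: pd.DataFrame
    months: int = 12
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def n(self) -> int:
        return len(self.baseline)

    def arms(self) -> list[str]:
        return list(pd.unique(self.baseline["arm"]))

    def participant(self, pid) -> pd.Series:
        """One participant's baseline record (their panel via ``panel_for``)."""
        rows = self.baseline[self.baseline["id"] == pid]
        if rows.empty:
            raise KeyError(f"no participant with id {pid!r}")
        return rows.iloc[0]

    def panel_for(self, pid) -> pd.DataFrame:
        return self.panel[self.panel["id"] == pid].sort_values("month")

    def copy(self) -> "Cohort":
        return Cohort(self.baseline.copy(), self.panel.copy(), self.months,
                      dict(self.meta))

    # ---- invariants --------------------------------------------------------

    def validate(self) -> None:
        b, p = self.baseline, self.panel
        for col in BASELINE_COLUMNS:
            if col not in b.columns:
                raise CohortValidationError(f"baseline table lacks column {col!r}")
        for col in PANEL_COLUMNS:
            if col not in p.columns:
                raise CohortValidationError(f"panel table lacks column {col!r}")
        if b["id"].duplicated().any():
            dup = b.loc[b["id"].duplicated(), "id"].iloc[0]
            raise CohortValidationError(f"duplicate participant id {dup!r} in baseline table")

        def _bad_row(df: pd.DataFrame, mask: pd.Series, table: str, msg: str):
            if mask.any():
                row = int(np.flatnonzero(mask.to_numpy())[0])
                raise CohortValidationError(f"{table} row {row}: {msg}")

        frac = p["absence_fraction"]
        _bad_row(p, (frac < 0) | (frac > 1), "panel",
                 "absence_fraction outside [0, 1]")
        for col in MSKHQ_COLUMNS:
            v = b[col]
            _bad_row(b, v.notna() & ((v < 0) | (v > 56)), "baseline",
                     f"{col} outside [0, 56]")
        for col in COST_COMPONENTS + ["cost_total"]:
            v = b[col]
            _bad_row(b, v.notna() & (v < 0), "baseline", f"{col} negative")
        for col in ("utility_baseline", "utility_12m"):
            v = b[col]
            _bad_row(b, v.notna() & ((v < -0.594) | (v > 1)), "baseline",
                     f"{col} outside [-0.594, 1]")
        if self.n:
            counts = p.groupby("id")["month"].count()
            wrong = counts[counts != self.months]
            if len(wrong):
                raise CohortValidationError(
                    f"participant {wrong.index[0]!r} has {wrong.iloc[0]} panel months, "
                    f"expected {self.months}"
                )

    # ---- persistence -------------------------------------------------------

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(directory / "baseline.csv", index=False)
        self.panel.to_csv(directory / "panel.csv", index=False)

    @classmethod
    def read(cls, directory, months: int = 12) -> "Cohort":
        directory = Path(directory)
        baseline = pd.read_csv(directory / "baseline.csv",
                               dtype={"id": str, "arm": str, "sex": str})
        panel = pd.read_csv(directory / "panel.csv", dtype={"id": str})
        if len(baseline) == 0:
            baseline = _empty_baseline()
            panel = _empty_panel()
        else:
            panel["benefit_received"] = panel["benefit_received"].astype(int)
        try:
            return cls(baseline, panel, months=months)
        except CohortValidationError as exc:
            raise CohortValidationError(f"while reading {directory}: {exc}") from exc


def _empty_baseline() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="object" if c in ("id", "arm", "sex",
                                                              "education",
                                                              "physical_activity",
                                                              "risk_group")
                                      else "float") for c in BASELINE_COLUMNS})


def _empty_panel() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="object" if c == "id" else "float")
                         for c in PANEL_COLUMNS})


def empty_cohort(months: int = 12) -> Cohort:
    return Cohort(_empty_baseline(), _empty_panel(), months=months)
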