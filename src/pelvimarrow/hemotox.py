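"""Hematologic toxicity (HT) grading from serial blood counts.

The nadir (lowest recorded value) of each of WBC, ANC, HGB and PLT during
treatment is graded against a CTCAE-style threshold table shipped as an
editable YAML config.  The overall HT grade is the maximum of the four
cytopenia grades; patients with overall grade >= 3 form the G3+ group,
the rest G0-2.

Grading convention: for each analyte the table lists decreasing lower
bounds for grades 1-4; grade 0 applies at or above the first bound (the
lower limit of normal), and a value exactly equal to a bound takes the
milder grade.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ANALYTES",
    "BloodSeries",
    "GradeThresholdTable",
    "HTResult",
    "load_threshold_table",
    "default_threshold_table",
    "nadir",
    "grade_analyte",
    "ht_result",
]

#: analyte column name -> toxicity name, in reporting order
ANALYTES = {
    "wbc": "leukopenia",
    "anc": "neutropenia",
    "hgb": "anemia",
    "plt": "thrombocytopenia",
}


@dataclass(frozen=True)
class BloodSeries:
    """Ordered complete-blood-count records for one patient.

    The first record is the pre-treatment baseline; later records are
    weekly (or more frequent) on-treatment counts.
    """

    patient_id: str
    records: pd.DataFrame  # columns: day, wbc, anc, hgb, plt

    def __post_init__(self) -> None:
        missing = {"day", *ANALYTES} - set(self.records.columns)
        if missing:
            raise ValueError(f"blood series missing columns {sorted(missing)}")
        if len(self.records) < 2:
            raise ValueError("need a baseline plus at least one on-treatment record")
        vals = self.records[list(ANALYTES)].to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("blood counts must be nonnegative")
        object.__setattr__(self, "records", self.records.sort_values("day").reset_index(drop=True))


@dataclass(frozen=True)
class GradeThresholdTable:
    """Per-analyte decreasing lower bounds for grades 1-4."""

    bounds: dict[str, tuple[float, float, float, float]]
    version: str = "5.0"

    def __post_init__(self) -> None:
        for analyte, b in self.bounds.items():
            if len(b) != 4 or any(x <= y for x, y in zip(b, b[1:])):
                raise ValueError(f"{analyte}: bounds must be 4 strictly decreasing values, got {b}")

    def grade_interval(self, analyte: str, grade: int) -> tuple[float, float]:
        """Half-open value interval [lo, hi) mapped to ``grade`` (hi = inf for grade 0)."""
        b = self.bounds[analyte]
        if grade == 0:
            return b[0], np.inf
        if grade == 4:
            return 0.0, b[3]
        return b[grade], b[grade - 1]


def load_threshold_table(path: str | os.PathLike) -> GradeThresholdTable:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    bounds = {a: tuple(float(x) for x in spec["bounds"]) for a, spec in cfg["analytes"].items()}
    return GradeThresholdTable(bounds=bounds, version=str(cfg.get("version", "?")))


def default_threshold_table() -> GradeThresholdTable:
    """The packaged CTCAE v5-style table."""
    ref = importlib.resources.files("pelvimarrow").joinpath("data/ctcae_v5.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_threshold_table(path)


def nadir(series: BloodSeries, analyte: str, include_baseline: bool = True) -> float:
    """Lowest recorded value of ``analyte``; the baseline record counts by default."""
    if analyte not in ANALYTES:
        raise KeyError(f"unknown analyte {analyte!r}; expected one of {sorted(ANALYTES)}")
    vals = series.records[analyte].to_numpy(dtype=float)
    if not include_baseline:
        vals = vals[1:]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"{series.patient_id}: no recorded {analyte} values")
    return float(vals.min())


def grade_analyte(value: float, analyte: str, table: GradeThresholdTable) -> int:
    """CTCAE grade of a single value: the number of bounds strictly above it."""
    if value < 0:
        raise ValueError(f"count must be nonnegative, got {value}")
    if analyte not in table.bounds:
        raise KeyError(f"unknown analyte {analyte!r}")
    return int(sum(value < b for b in table.bounds[analyte]))


@dataclass(frozen=True)
class HTResult:
    patient_id: str
    grades: dict[str, int]  # toxicity name -> grade 0..4
    overall_grade: int = field(init=False)
    group: str = field(init=False)

    def __post_init__(self) -> None:
        expected = set(ANALYTES.values())
        if set(self.grades) != expected:
            raise ValueError(f"grades must cover {sorted(expected)}")
        overall = max(self.grades.values())
        object.__setattr__(self, "overall_grade", overall)
        object.__setattr__(self, "group", "G3plus" if overall >= 3 else "G0_2")


def ht_result(
    series: BloodSeries,
    table: GradeThresholdTable | None = None,
    include_baseline: bool = True,
) -> HTResult:
    """Grade all four cytopenias from nadirs and derive the overall HT grade."""
    if table is None:
        table = default_threshold_table()
    grades = {
        toxicity: grade_analyte(nadir(series, analyte, include_baseline), analyte, table)
        for analyte, toxicity in ANALYTES.items()
    }
    return HTResult(patient_id=series.patient_id, grades=grades)


def ht_table(results: list[HTResult]) -> pd.DataFrame:
    """Tidy per-patient HT rows: one column per toxicity plus overall grade and group."""
    short = {
        "leukopenia": "g_leuko",
        "neutropenia": "g_neutro",
        "anemia": "g_anemia",
        "thrombocytopenia": "g_thrombo",
    }
    rows = []
    for r in results:
        row = {"patient_id": r.patient_id}
        row.update({short[t]: g for t, g in r.grades.items()})
        row["ht_grade"] = r.overall_grade
        row["ht_group"] = r.group
        rows.append(row)
    columns = ["patient_id", *short.values(), "ht_grade", "ht_group"]
    return pd.DataFrame(rows, columns=columns)
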