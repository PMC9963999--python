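"""Cohort tables: loading, validation, derived covariates, round-trip I/O.

A cohort file is a CSV/TSV with one screened athlete per row.  Mandatory
columns: ``athlete_id``, ``ethnicity``, ``chronological_age``, and either
``bsa`` or both ``height`` and ``weight``.  Optional covariates:
``biological_age``, ``heart_rate``.  Every remaining numeric column is
treated as an echocardiographic measure, in the native unit declared by
the measure catalog (mm for linear dimensions, g for LV mass, mL for
volumes, cm/s for velocities, ms for DecT, % for LVEF, dimensionless for
ratios).  Column-name aliases and cm-declared columns are handled by an
:class:`IOConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .bsa import compute_bsa
from .errors import CohortParseError, CohortSchemaError, CohortValidationError

COVARIATE_COLUMNS = (
    "athlete_id", "ethnicity", "chronological_age", "biological_age",
    "height", "weight", "bsa", "heart_rate",
)

STUDY_AGE_RANGE = (11.0, 18.0)

#: canonical measure catalog: name -> (unit, model family)
MEASURE_CATALOG = {
    "LVIDd": ("mm", "structural"),
    "IVSd": ("mm", "structural"),
    "PWTd": ("mm", "structural"),
    "LV mass": ("g", "structural"),
    "LV volume": ("mL", "structural"),
    "aortic root": ("mm", "structural"),
    "LAD": ("mm", "structural"),
    "LA volume": ("mL", "structural"),
    "LVEF": ("%", "lvef"),
    "E": ("cm/s", "functional"),
    "A": ("cm/s", "functional"),
    "E/A": ("", "functional"),
    "DecT": ("ms", "functional"),
    "septal e'": ("cm/s", "functional"),
    "septal a'": ("cm/s", "functional"),
    "septal s'": ("cm/s", "functional"),
    "lateral e'": ("cm/s", "functional"),
    "lateral a'": ("cm/s", "functional"),
    "lateral s'": ("cm/s", "functional"),
    "septal E/e'": ("", "functional"),
    "lateral E/e'": ("", "functional"),
    "average E/e'": ("", "functional"),
}


@dataclass(frozen=True)
class MeasureInfo:
    name: str
    unit: str
    family: str  # structural | functional | lvef


@dataclass
class IOConfig:
    """Loader configuration.

    ``column_aliases`` maps canonical names (covariates or measures) to the
    column name actually present in the file.  ``cm_columns`` lists measure
    columns recorded in cm; the loader converts them to mm.  ``bsa_formula``
    is applied when BSA must be derived from height and weight.
    """

    bsa_formula: str = "mosteller"
    column_aliases: dict = field(default_factory=dict)
    cm_columns: tuple = ()
    bsa_tolerance: float = 1e-9

    @classmethod
    def from_yaml(cls, path) -> "IOConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            bsa_formula=raw.get("bsa_formula", "mosteller"),
            column_aliases=raw.get("column_aliases", {}),
            cm_columns=tuple(raw.get("cm_columns", ())),
            bsa_tolerance=float(raw.get("bsa_tolerance", 1e-9)),
        )


@dataclass
class AthleteRecord:
    """One screened athlete: covariates plus a measure -> value map."""

    athlete_id: str
    ethnicity: str
    chronological_age: float
    bsa: float
    height: float | None = None
    weight: float | None = None
    biological_age: float | None = None
    heart_rate: float | None = None
    measurements: dict = field(default_factory=dict)

    def validate(self, config: IOConfig | None = None, context: str = "") -> None:
        cfg = config or IOConfig()
        if not (self.chronological_age > 0):
            raise CohortValidationError(
                f"{context}chronological_age must be > 0, got {self.chronological_age}"
            )
        if not (STUDY_AGE_RANGE[0] <= self.chronological_age <= STUDY_AGE_RANGE[1]):
            warnings.warn(
                f"{context}chronological_age {self.chronological_age:g} outside "
                f"the study range {STUDY_AGE_RANGE}", stacklevel=2,
            )
        if not (self.bsa > 0):
            raise CohortValidationError(f"{context}bsa must be > 0, got {self.bsa}")
        if self.height is not None and self.weight is not None:
            expected = compute_bsa(self.height, self.weight, cfg.bsa_formula)
            if abs(expected - self.bsa) > cfg.bsa_tolerance:
                raise CohortValidationError(
                    f"{context}bsa {self.bsa!r} inconsistent with "
                    f"{cfg.bsa_formula}(height={self.height}, weight={self.weight}) "
                    f"= {expected!r}"
                )
        for name, value in self.measurements.items():
            if not np.isfinite(value) or value <= 0:
                raise CohortValidationError(
                    f"{context}measurement {name!r} must be finite and > 0, "
                    f"got {value}"
                )


class CohortTable:
    """Ordered collection of :class:`AthleteRecord` with a measure catalog."""

    def __init__(self, records, measure_catalog=None, config: IOConfig | None = None):
        self.records = list(records)
        self.config = config or IOConfig()
        ids = [r.athlete_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate athlete_id values: {dupes}")
        present = set()
        for r in self.records:
            present.update(r.measurements)
        if measure_catalog is None:
            measure_catalog = [
                MeasureInfo(name, *MEASURE_CATALOG.get(name, ("", "functional")))
                for name in sorted(present, key=str)
            ]
        self.measure_catalog = [m for m in measure_catalog if m.name in present]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def measures(self):
        return [m.name for m in self.measure_catalog]

    def family(self, measure: str) -> str:
        for m in self.measure_catalog:
            if m.name == measure:
                return m.family
        raise KeyError(f"measure {measure!r} not in catalog")

    def covariate(self, name: str) -> np.ndarray:
        """Covariate column as a float array; missing values are NaN."""
        vals = [getattr(r, name) for r in self.records]
        return np.array([np.nan if v is None else float(v) for v in vals])

    @property
    def ethnicity(self) -> np.ndarray:
        return np.array([r.ethnicity for r in self.records])

    def values(self, measure: str) -> np.ndarray:
        """Measurement column as a float array; missing values are NaN."""
        return np.array(
            [float(r.measurements.get(measure, np.nan)) for r in self.records]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "athlete_id": r.athlete_id,
                "ethnicity": r.ethnicity,
                "chronological_age": r.chronological_age,
                "biological_age": r.biological_age,
                "height": r.height,
                "weight": r.weight,
                "bsa": r.bsa,
                "heart_rate": r.heart_rate,
            }
            row.update({m.name: r.measurements.get(m.name) for m in self.measure_catalog})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: IOConfig | None = None,
                       source: str = "<dataframe>") -> "CohortTable":
        return _table_from_frame(df, config or IOConfig(), source)


def _table_from_frame(df: pd.DataFrame, config: IOConfig, source: str) -> CohortTable:
    # resolve aliases back to canonical names
    rename = {v: k for k, v in config.column_aliases.items() if v in df.columns}
    df = df.rename(columns=rename)

    for col in ("athlete_id", "ethnicity", "chronological_age"):
        if col not in df.columns:
            raise CohortSchemaError(f"{source}: missing mandatory column {col!r}")
    has_hw = "height" in df.columns and "weight" in df.columns
    if "bsa" not in df.columns and not has_hw:
        raise CohortSchemaError(
            f"{source}: needs a 'bsa' column or both 'height' and 'weight'"
        )

    numeric_cols = [c for c in df.columns if c not in ("athlete_id", "ethnicity")]
    parsed = {}
    for col in numeric_cols:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise CohortParseError(
                f"{source}: non-numeric value {raw.iloc[i]!r} in row {i}, "
                f"column {col!r}"
            )
        # pd.to_numeric's string parser is not correctly rounded; re-parse
        # with Python's float() so write/load round-trips bit-exactly
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        num = raw.where(~blank, np.nan).astype(float)
        if col in config.cm_columns:
            num = num * 10.0  # declared in cm -> store mm
        parsed[col] = num

    records, failures = [], []
    for i in range(len(df)):
        def get(col):
            if col not in parsed:
                return None
            v = parsed[col].iloc[i]
            return None if pd.isna(v) else float(v)

        height, weight, bsa = get("height"), get("weight"), get("bsa")
        if bsa is None and height is not None and weight is not None:
            bsa = compute_bsa(height, weight, config.bsa_formula)
        measurements = {}
        for col in numeric_cols:
            if col in COVARIATE_COLUMNS:
                continue
            v = parsed[col].iloc[i]
            if not pd.isna(v):
                measurements[col] = float(v)
        try:
            if bsa is None:
                raise CohortValidationError("bsa missing and not derivable")
            if get("chronological_age") is None:
                raise CohortValidationError("chronological_age missing")
            rec = AthleteRecord(
                athlete_id=str(df["athlete_id"].iloc[i]),
                ethnicity=str(df["ethnicity"].iloc[i]).strip().lower(),
                chronological_age=get("chronological_age"),
                biological_age=get("biological_age"),
                height=height, weight=weight, bsa=bsa,
                heart_rate=get("heart_rate"),
                measurements=measurements,
            )
            rec.validate(config, context=f"{source} row {i}: ")
        except CohortValidationError as exc:
            failures.append(str(exc) if str(exc).startswith(source)
                            else f"{source} row {i}: {exc}")
            continue
        records.append(rec)
    if failures:
        raise CohortValidationError(
            "rejected rows:\n  " + "\n  ".join(failures)
        )
    return CohortTable(records, config=config)


def load_cohort(path, config: IOConfig | None = None) -> CohortTable:
    """Read and validate a cohort CSV/TSV into a :class:`CohortTable`."""
    config = config or IOConfig()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except FileNotFoundError:
        raise
    return _table_from_frame(df, config, source=str(path))


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort back to CSV at full float precision (round-trip safe)."""
    df = table.to_dataframe()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
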