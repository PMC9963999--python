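"""Nomogram rendering and longitudinal athlete tracking.

The CSV produced from :func:`paedz.zscores.nomogram_table` is the source
of truth for a nomogram; the figure is derived from it.  Plot styling
follows the usual reference-chart convention: solid mean line, dashed
Z = ±1, solid Z = ±2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .zscores import (FunctionalModel, StructuralModel, ZScoreResult,
                      compute_z, nomogram_table)

#: between-visit Z drift that flags a tracking series for review.  This is
#: a chart-review heuristic, not a validated clinical threshold.
DEFAULT_DRIFT_THRESHOLD = 1.5


def plot_nomogram(model, grid, age=None, cohort=None, ax=None):
    """Draw Z = 0, ±1, ±2 reference lines, optionally over cohort points."""
    table = nomogram_table(model, grid, z_lines=(-2, -1, 0, 1, 2), age=age)
    xcol = "bsa" if isinstance(model, StructuralModel) else "age"
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    styles = {0: ("-", 1.8), 1: ("--", 1.0), -1: ("--", 1.0),
              2: ("-", 1.2), -2: ("-", 1.2)}
    for z, sub in table.groupby("z"):
        ls, lw = styles[int(z)]
        ax.plot(sub[xcol], sub["value"], ls, linewidth=lw,
                color="C0" if abs(z) < 2 else "C3",
                label=f"Z = {int(z):+d}" if z else "Z = 0")
    if cohort is not None:
        obs = cohort.values(model.measure)
        x = (cohort.covariate("bsa") if xcol == "bsa"
             else cohort.covariate("chronological_age"))
        ax.plot(x, obs, "o", ms=3, alpha=0.4, color="0.4", label="cohort")
    xlabel = "BSA (m²)" if xcol == "bsa" else "chronological age (y)"
    ax.set_xlabel(xlabel)
    unit = f" ({model.unit})" if model.unit else ""
    ax.set_ylabel(f"{model.measure}{unit}")
    if isinstance(model, StructuralModel):
        ax.set_title(f"{model.measure} at age {age:g} y")
    ax.legend(fontsize=8)
    return ax


def render_nomogram(model, grid, out_csv, out_png=None, age=None, cohort=None):
    """Write the nomogram table as CSV and, optionally, a derived figure."""
    table = nomogram_table(model, grid, z_lines=(-2, -1, 0, 1, 2), age=age)
    table.to_csv(out_csv, index=False, float_format="%.17g")
    if out_png is not None:
        ax = plot_nomogram(model, grid, age=age, cohort=cohort)
        ax.figure.savefig(out_png, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return table


# ---------------------------------------------------------------------------
# longitudinal tracking


@dataclass(frozen=True)
class Visit:
    date: str           # ISO date, used only for ordering/reporting
    age: float          # chronological age at the visit (y)
    bsa: float          # m²
    measurements: dict  # measure -> observed value


@dataclass
class TrackingSeries:
    """Per-visit Z-scores for one athlete across annual follow-up."""

    athlete_id: str
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD

    def flagged(self) -> pd.DataFrame:
        return self.rows[self.rows.out_of_range | self.rows.drift]


def track_athlete(athlete_id, visits, models,
                  drift_threshold: float = DEFAULT_DRIFT_THRESHOLD) -> TrackingSeries:
    """Z-score every visit's measurements and flag out-of-range and drift.

    Visits must be date-ordered with non-decreasing ages.  A drift flag is
    raised on a visit whose Z differs from the previous visit's by at least
    ``drift_threshold`` for the same measure; covariates outside a model's
    validity envelope set a per-row warning flag rather than aborting.
    """
    visits = list(visits)
    if not visits:
        raise ValueError("need at least one visit")
    dates = [v.date for v in visits]
    if dates != sorted(dates):
        raise ValueError("visits must be ordered by date")
    ages = [v.age for v in visits]
    if any(a2 < a1 for a1, a2 in zip(ages, ages[1:])):
        raise ValueError("ages must be non-decreasing across visits")

    rows = []
    last_z: dict = {}
    for v in visits:
        for measure, observed in v.measurements.items():
            model = models.get(measure)
            if model is None:
                continue
            if isinstance(model, StructuralModel):
                res = compute_z(observed, model, bsa=v.bsa, age=v.age)
            elif isinstance(model, FunctionalModel):
                res = compute_z(observed, model, age=v.age)
            else:
                res = compute_z(observed, model)
            dz = res.z - last_z[measure] if measure in last_z else 0.0
            rows.append({
                "date": v.date, "age": v.age, "bsa": v.bsa, "measure": measure,
                "observed": observed, "z": res.z, "centile": res.centile,
                "out_of_range": res.out_of_range,
                "drift": abs(dz) >= drift_threshold,
                "delta_z": dz,
                "out_of_envelope": res.out_of_envelope,
                "hr_caution": res.hr_caution,
            })
            last_z[measure] = res.z
    return TrackingSeries(athlete_id, pd.DataFrame(rows),
                          drift_threshold=drift_threshold)
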