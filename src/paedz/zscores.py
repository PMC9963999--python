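"""Normative Z-score models for paediatric-athlete echocardiography.

Two equation families are implemented:

* **Structural** (chamber, wall and vessel dimensions): an allometric mean
  in body surface area with an additive chronological-age term,

      mean(BSA, age) = a * BSA**b + c * age          (default, additive_age)

  or, selectably, the age-in-exponent variant ``a * BSA**(b + c*age)``
  (exponent_age).  The residual SD is modelled linearly in both covariates
  ("regressed SD"): rsd = d + e*BSA + f*age.

* **Functional** (Doppler / tissue-Doppler velocities and ratios): a
  second-order polynomial of chronological age,

      mean(age) = a*age**2 + b*age + c,   rsd = d + e*age.

* **LVEF**: a plain normal model (mean, SD) independent of body size and
  age; the lower reference limit is mean - 2*SD (Z = -2).

Z = (observed - mean) / rsd throughout; the Z is always signed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import CohortSchemaError, EnvelopeError

#: measures whose Z-scores retain a residual heart-rate association and
#: should be interpreted with caution in athletes with unusual resting HR
HR_DEPENDENT_MEASURES = frozenset({"A", "E/A", "septal a'"})

#: covariate envelope over which fitted models are declared valid
DEFAULT_BSA_RANGE = (0.8, 2.4)
DEFAULT_AGE_RANGE = (11.0, 18.0)

MEAN_FORMS = ("additive_age", "exponent_age")


@dataclass(frozen=True)
class StructuralModel:
    """Allometric BSA + age Z-score model for one structural measure.

    Coefficients ``a, b, c`` parameterise the mean, ``d, e, f`` the
    regressed SD (d + e*BSA + f*age).  ``a`` must be positive and the RSD
    must be positive over the declared validity envelope; both are checked
    at construction.
    """

    measure: str
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    unit: str = "mm"
    mean_form: str = "additive_age"
    bsa_formula: str = "mosteller"
    bsa_range: tuple = DEFAULT_BSA_RANGE
    age_range: tuple = DEFAULT_AGE_RANGE

    def __post_init__(self):
        if self.mean_form not in MEAN_FORMS:
            raise ValueError(f"mean_form must be one of {MEAN_FORMS}")
        if self.a <= 0:
            raise ValueError(f"{self.measure}: scale coefficient a must be > 0")
        # RSD is affine in (BSA, age): positivity on the 4 envelope corners
        # implies positivity on the whole rectangle.
        for bsa, age in itertools.product(self.bsa_range, self.age_range):
            if self.d + self.e * bsa + self.f * age <= 0:
                raise ValueError(
                    f"{self.measure}: regressed SD non-positive at "
                    f"BSA={bsa}, age={age} inside the validity envelope"
                )

    # -- evaluation ------------------------------------------------------
    def mean(self, bsa, age):
        bsa = np.asarray(bsa, dtype=float)
        age = np.asarray(age, dtype=float)
        if np.any(bsa <= 0):
            raise ValueError("BSA must be strictly positive")
        if self.mean_form == "additive_age":
            out = self.a * bsa**self.b + self.c * age
        else:
            out = self.a * bsa ** (self.b + self.c * age)
        return out if out.ndim else float(out)

    def rsd(self, bsa, age):
        bsa = np.asarray(bsa, dtype=float)
        age = np.asarray(age, dtype=float)
        out = self.d + self.e * bsa + self.f * age
        if np.any(out <= 0):
            bad = np.argmax(np.atleast_1d(out) <= 0)
            b_bad = np.broadcast_to(bsa, np.shape(out) or (1,)).ravel()[bad]
            a_bad = np.broadcast_to(age, np.shape(out) or (1,)).ravel()[bad]
            raise EnvelopeError(
                f"{self.measure}: regressed SD <= 0 at BSA={b_bad:g}, age={a_bad:g}"
            )
        return out if out.ndim else float(out)

    def in_envelope(self, bsa, age) -> bool:
        return (
            self.bsa_range[0] <= bsa <= self.bsa_range[1]
            and self.age_range[0] <= age <= self.age_range[1]
        )


@dataclass(frozen=True)
class FunctionalModel:
    """Age-polynomial Z-score model for one Doppler/TDI measure.

    mean = a*age² + b*age + c; rsd = d + e*age, positive over the declared
    age envelope (checked at construction).
    """

    measure: str
    a: float
    b: float
    c: float
    d: float
    e: float
    unit: str = "cm/s"
    age_range: tuple = DEFAULT_AGE_RANGE

    def __post_init__(self):
        for age in self.age_range:
            if self.d + self.e * age <= 0:
                raise ValueError(
                    f"{self.measure}: regressed SD non-positive at age={age} "
                    "inside the validity envelope"
                )

    def mean(self, age):
        age = np.asarray(age, dtype=float)
        out = self.a * age**2 + self.b * age + self.c
        return out if out.ndim else float(out)

    def rsd(self, age):
        age = np.asarray(age, dtype=float)
        out = self.d + self.e * age
        if np.any(out <= 0):
            raise EnvelopeError(f"{self.measure}: regressed SD <= 0 at age={age}")
        return out if out.ndim else float(out)

    def in_envelope(self, age) -> bool:
        return self.age_range[0] <= age <= self.age_range[1]


@dataclass(frozen=True)
class LvefModel:
    """Normal model for LV ejection fraction (%): Z = (obs - mean)/sd.

    The lower reference limit is mean - n_sd*sd (default n_sd = 2, so the
    limit sits at Z = -2; 1.96 is available).
    """

    mean: float
    sd: float
    measure: str = "LVEF"
    unit: str = "%"
    n_sd: float = 2.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("LVEF SD must be > 0")
        limit = self.lower_reference_limit
        if not (0 < limit < self.mean <= 100):
            raise ValueError(
                f"LVEF lower reference limit {limit:.1f}% outside (0, mean]"
            )

    @property
    def lower_reference_limit(self) -> float:
        return self.mean - self.n_sd * self.sd


@dataclass(frozen=True)
class ZScoreResult:
    """One Z-score evaluation: observed value, model prediction, flags."""

    measure: str
    observed: float
    predicted_mean: float
    rsd: float
    z: float
    centile: float
    out_of_range: bool
    hr_caution: bool
    out_of_envelope: bool = False

    @property
    def abs_z(self) -> float:
        return abs(self.z)

    def __str__(self):
        flags = []
        if self.out_of_range:
            flags.append("|Z| >= 2")
        if self.hr_caution:
            flags.append("HR-dependent: interpret with caution")
        if self.out_of_envelope:
            flags.append("covariates outside validity envelope")
        tail = f"  [{'; '.join(flags)}]" if flags else ""
        return (
            f"{self.measure}: observed {self.observed:g}, "
            f"predicted {self.predicted_mean:.2f} (RSD {self.rsd:.3f}), "
            f"Z = {self.z:.2f}, centile {self.centile:.1f}%{tail}"
        )


def compute_z(observed, model, bsa=None, age=None) -> ZScoreResult:
    """Z-score an observation against a normative model.

    Covariates required by the model family must be given explicitly:
    structural models need ``bsa`` and ``age``, functional models ``age``,
    the LVEF model neither.  Missing covariates raise rather than default.
    """
    out_of_env = False
    if isinstance(model, StructuralModel):
        if bsa is None:
            raise ValueError(f"{model.measure}: structural model requires bsa")
        if age is None:
            raise ValueError(f"{model.measure}: structural model requires age")
        mean = model.mean(bsa, age)
        rsd = model.rsd(bsa, age)
        out_of_env = not model.in_envelope(bsa, age)
    elif isinstance(model, FunctionalModel):
        if age is None:
            raise ValueError(f"{model.measure}: functional model requires age")
        mean = model.mean(age)
        rsd = model.rsd(age)
        out_of_env = not model.in_envelope(age)
    elif isinstance(model, LvefModel):
        mean, rsd = model.mean, model.sd
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    z = (float(observed) - mean) / rsd
    return ZScoreResult(
        measure=model.measure,
        observed=float(observed),
        predicted_mean=mean,
        rsd=rsd,
        z=z,
        centile=float(norm.cdf(z) * 100.0),
        out_of_range=abs(z) >= 2.0,
        hr_caution=model.measure in HR_DEPENDENT_MEASURES,
        out_of_envelope=out_of_env,
    )


def invert_z(model, z, bsa=None, age=None):
    """Measurement value lying at a given Z for given covariates.

    Exact algebraic inverse of :func:`compute_z`: mean + z*rsd.
    """
    if isinstance(model, StructuralModel):
        if bsa is None or age is None:
            raise ValueError(f"{model.measure}: structural model requires bsa and age")
        return model.mean(bsa, age) + z * model.rsd(bsa, age)
    if isinstance(model, FunctionalModel):
        if age is None:
            raise ValueError(f"{model.measure}: functional model requires age")
        return model.mean(age) + z * model.rsd(age)
    if isinstance(model, LvefModel):
        return model.mean + z * model.sd
    raise TypeError(f"unsupported model type {type(model).__name__}")


def nomogram_table(model, grid, z_lines=(-2, -1, 0, 1, 2), age=None) -> pd.DataFrame:
    """Reference-line table for nomogram plotting.

    For a structural model ``grid`` is a sequence of BSA values evaluated
    at a fixed ``age``; for a functional model it is a sequence of ages.
    Returns a tidy frame with one row per (grid point, z line); values are
    monotone increasing in z at every grid point because rsd > 0.
    """
    grid = np.asarray(list(grid), dtype=float)
    z_lines = sorted(z_lines)
    if grid.size == 0 or len(z_lines) == 0:
        raise ValueError("nomogram grid and z_lines must be non-empty")
    rows = []
    if isinstance(model, StructuralModel):
        if age is None:
            raise ValueError("structural nomogram requires a fixed age")
        for g in grid:
            for z in z_lines:
                rows.append((model.measure, g, float(age), z,
                             float(invert_z(model, z, bsa=g, age=age))))
        cols = ["measure", "bsa", "age", "z", "value"]
    elif isinstance(model, FunctionalModel):
        for g in grid:
            for z in z_lines:
                rows.append((model.measure, g, z,
                             float(invert_z(model, z, age=g))))
        cols = ["measure", "age", "z", "value"]
    else:
        raise TypeError("nomograms are defined for structural/functional models")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# coefficient-file round trip (JSON)

def _model_to_record(model, n_fit=None) -> dict:
    if isinstance(model, StructuralModel):
        return {
            "measure": model.measure,
            "family": "structural",
            "unit": model.unit,
            "bsa_formula": model.bsa_formula,
            "mean_form": model.mean_form,
            "coefficients": {"a": model.a, "b": model.b, "c": model.c},
            "rsd_coefficients": {"d": model.d, "e": model.e, "f": model.f},
            "n_fit": n_fit,
        }
    if isinstance(model, FunctionalModel):
        return {
            "measure": model.measure,
            "family": "functional",
            "unit": model.unit,
            "bsa_formula": None,
            "mean_form": "polynomial_age",
            "coefficients": {"a": model.a, "b": model.b, "c": model.c},
            "rsd_coefficients": {"d": model.d, "e": model.e},
            "n_fit": n_fit,
        }
    if isinstance(model, LvefModel):
        return {
            "measure": model.measure,
            "family": "lvef",
            "unit": model.unit,
            "bsa_formula": None,
            "mean_form": "normal",
            "coefficients": {"mean": model.mean, "sd": model.sd, "n_sd": model.n_sd},
            "rsd_coefficients": {},
            "n_fit": n_fit,
        }
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _record_to_model(rec: dict):
    try:
        family = rec["family"]
        co = rec["coefficients"]
        rs = rec.get("rsd_coefficients", {})
        if family == "structural":
            return StructuralModel(
                measure=rec["measure"], unit=rec.get("unit", "mm"),
                mean_form=rec.get("mean_form", "additive_age"),
                bsa_formula=rec.get("bsa_formula") or "mosteller",
                a=co["a"], b=co["b"], c=co["c"],
                d=rs["d"], e=rs["e"], f=rs["f"],
            )
        if family == "functional":
            return FunctionalModel(
                measure=rec["measure"], unit=rec.get("unit", "cm/s"),
                a=co["a"], b=co["b"], c=co["c"], d=rs["d"], e=rs["e"],
            )
        if family == "lvef":
            return LvefModel(mean=co["mean"], sd=co["sd"],
                             n_sd=co.get("n_sd", 2.0),
                             measure=rec.get("measure", "LVEF"),
                             unit=rec.get("unit", "%"))
    except KeyError as exc:
        raise CohortSchemaError(
            f"coefficient record for {rec.get('measure', '?')!r} is missing "
            f"field {exc}"
        ) from None
    raise CohortSchemaError(f"unknown model family {family!r}")


def write_models(models, path, n_fit=None) -> None:
    """Write models (mapping measure -> model, or iterable) to a JSON file."""
    if isinstance(models, dict):
        models = models.values()
    if n_fit is None:
        n_fit = {}
    records = [
        _model_to_record(m, n_fit.get(m.measure) if isinstance(n_fit, dict) else n_fit)
        for m in models
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
        fh.write("\n")


def read_models(path) -> dict:
    """Read a coefficient JSON file -> {measure: model}."""
    with open(path) as fh:
        records = json.load(fh)
    models = {}
    for rec in records:
        m = _record_to_model(rec)
        if m.measure in models:
            warnings.warn(f"duplicate coefficient record for {m.measure}; last wins")
        models[m.measure] = m
    return models
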