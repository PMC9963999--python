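"""Synthetic cohorts with the covariate and noise structure the normative
models assume.

The generator emulates a pre-participation screening population of male
paediatric athletes: 297 Arab and 120 black athletes aged 11-18 y, BSA
growing linearly with age around a cohort mean of ~1.6 m² (SD ~0.2-0.3),
biological (skeletal) age running ahead of chronological age with an extra
+0.5 y offset in the black group, and resting heart rate declining with
age.  Structural measures follow the allometric mean with SD linear in BSA
and age; functional measures follow the age-polynomial mean with SD linear
in age; LVEF is drawn independently of body size and age.

Two measures use the published worked-example coefficients as generating
truth (IVSd; average E/e'); every other entry in the default model set is
a synthetic invention chosen to sit at physiologically plausible
adolescent-athlete values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .cohort import MEASURE_CATALOG, AthleteRecord, CohortTable, MeasureInfo
from .zscores import FunctionalModel, LvefModel, StructuralModel

BSA_TRUNCATION = (0.8, 2.4)  # m², the structural validity envelope


@dataclass(frozen=True)
class GrowthModel:
    """Linear covariate model: value = intercept + slope*age + N(0, sd)."""
    intercept: float
    slope: float
    sd: float


@dataclass(frozen=True)
class BioAgeModel:
    """biological age = chronological age + baseline + black_extra·1[black] + N(0, sd)."""
    baseline: float
    black_extra: float
    sd: float


def default_true_models() -> dict:
    """Default generating models, one per catalog measure.

    IVSd and average E/e' carry the published worked-example coefficients;
    the rest are synthetic plausible values (they are generator defaults,
    not clinical references).
    """
    s = StructuralModel
    f = FunctionalModel
    models = [
        s("LVIDd", a=36.0, b=0.50, c=0.20, d=2.5, e=0.6, f=0.0, unit="mm"),
        s("IVSd", a=6.055, b=-0.020, c=0.031, d=1.100, e=0.062, f=-0.008, unit="mm"),
        s("PWTd", a=6.0, b=0.30, c=0.10, d=0.9, e=0.3, f=0.0, unit="mm"),
        s("LV mass", a=60.0, b=1.20, c=2.00, d=10.0, e=5.0, f=0.3, unit="g"),
        s("LV volume", a=55.0, b=1.10, c=1.50, d=8.0, e=4.0, f=0.2, unit="mL"),
        s("aortic root", a=22.0, b=0.40, c=0.25, d=1.5, e=0.5, f=0.02, unit="mm"),
        s("LAD", a=24.0, b=0.40, c=0.15, d=1.8, e=0.6, f=0.0, unit="mm"),
        s("LA volume", a=24.0, b=1.00, c=0.40, d=4.0, e=2.0, f=0.1, unit="mL"),
        f("E", a=-0.05, b=0.50, c=95.0, d=10.0, e=0.10, unit="cm/s"),
        f("A", a=0.02, b=-0.60, c=55.0, d=7.0, e=0.0, unit="cm/s"),
        f("E/A", a=0.004, b=-0.12, c=3.10, d=0.45, e=0.0, unit=""),
        f("DecT", a=0.0, b=2.0, c=130.0, d=22.0, e=0.5, unit="ms"),
        f("septal e'", a=-0.02, b=0.30, c=11.0, d=1.6, e=0.0, unit="cm/s"),
        f("septal a'", a=0.01, b=-0.25, c=12.0, d=1.3, e=0.0, unit="cm/s"),
        f("septal s'", a=0.005, b=0.05, c=8.0, d=1.2, e=0.0, unit="cm/s"),
        f("lateral e'", a=-0.03, b=0.60, c=13.0, d=2.2, e=0.0, unit="cm/s"),
        f("lateral a'", a=0.01, b=-0.20, c=10.0, d=1.6, e=0.0, unit="cm/s"),
        f("lateral s'", a=0.0, b=0.15, c=9.0, d=1.8, e=0.0, unit="cm/s"),
        f("septal E/e'", a=0.010, b=-0.40, c=11.50, d=1.5, e=-0.02, unit=""),
        f("lateral E/e'", a=0.008, b=-0.35, c=10.00, d=1.3, e=-0.02, unit=""),
        f("average E/e'", a=0.009, b=-0.418, c=10.485, d=1.413, e=-0.025, unit=""),
        LvefModel(mean=60.0, sd=5.8),
    ]
    return {m.measure: m for m in models}


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_cohort`.

    Defaults reproduce the screening cohort the models were built for:
    n = 297 + 120, uniform ages 11-18 y, BSA = 0.5125 + 0.075·age + N(0,
    0.13) truncated to [0.8, 2.4] m² (cohort mean ≈ 1.6, SD ≈ 0.2,
    corr(age, BSA) ≈ 0.75), biological age ≈ chronological + 1.0 y with an
    extra +0.5 y in black athletes, HR = 95 − 1.5·age + N(0, 10) bpm.
    """

    n_arab: int = 297
    n_black: int = 120
    age_range: tuple = (11.0, 18.0)
    bsa_growth: GrowthModel = field(default_factory=lambda: GrowthModel(0.5125, 0.075, 0.13))
    bio_age: BioAgeModel = field(default_factory=lambda: BioAgeModel(1.0, 0.5, 0.6))
    hr_model: GrowthModel = field(default_factory=lambda: GrowthModel(95.0, -1.5, 10.0))
    true_models: dict = field(default_factory=default_true_models)
    noise_scale: float = 1.0
    seed: int = 0
    rsd_floor: float = 1e-3

    def __post_init__(self):
        if self.n_arab + self.n_black < 2:
            raise ValueError("need at least 2 athletes in total")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")
        for name, sd in (("bsa_growth", self.bsa_growth.sd),
                         ("bio_age", self.bio_age.sd),
                         ("hr_model", self.hr_model.sd)):
            if sd < 0:
                raise ValueError(f"{name}.sd must be >= 0")

    @classmethod
    def from_yaml(cls, path, seed=None) -> "SimulationConfig":
        """Load overrides from YAML; unrecognised keys are rejected.

        Only scalar/grouped covariate settings are configurable from file;
        ``true_models`` overrides use the coefficient-file JSON format.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("n_arab", "n_black", "seed", "rsd_floor", "noise_scale"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "age_range" in raw:
            kwargs["age_range"] = tuple(raw.pop("age_range"))
        if "bsa_growth" in raw:
            kwargs["bsa_growth"] = GrowthModel(**raw.pop("bsa_growth"))
        if "bio_age" in raw:
            kwargs["bio_age"] = BioAgeModel(**raw.pop("bio_age"))
        if "hr_model" in raw:
            kwargs["hr_model"] = GrowthModel(**raw.pop("hr_model"))
        if raw:
            raise ValueError(f"unknown simulation config keys: {sorted(raw)}")
        cfg = cls(**kwargs)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _truncated_normal(rng, mean, sd, lo, hi):
    """Rejection sampler; one redraw loop per record keeps the stream
    reproducible for a fixed config."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    x = mean + sd * rng.standard_normal()
    while not (lo <= x <= hi):
        x = mean + sd * rng.standard_normal()
    return float(x)


def simulate_cohort(config: SimulationConfig | None = None) -> CohortTable:
    """Draw a synthetic cohort under the configured generating models.

    Determinism: a fixed config (including seed) yields a bit-identical
    table.  Draw order per athlete: age, BSA (truncated rejection),
    biological age, heart rate; then measure noise in catalog order.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_arab + cfg.n_black
    ethnicity = ["arab"] * cfg.n_arab + ["black"] * cfg.n_black

    records = []
    for i in range(n):
        eth = ethnicity[i]
        age = float(rng.uniform(*cfg.age_range))
        g = cfg.bsa_growth
        bsa = _truncated_normal(rng, g.intercept + g.slope * age, g.sd, *BSA_TRUNCATION)
        b = cfg.bio_age
        bio = age + b.baseline + (b.black_extra if eth == "black" else 0.0)
        bio += b.sd * rng.standard_normal() if b.sd else 0.0
        h = cfg.hr_model
        hr = h.intercept + h.slope * age
        hr += h.sd * rng.standard_normal() if h.sd else 0.0

        measurements = {}
        for name in MEASURE_CATALOG:
            model = cfg.true_models.get(name)
            if model is None:
                continue
            if isinstance(model, StructuralModel):
                mean, sd = model.mean(bsa, age), model.d + model.e * bsa + model.f * age
            elif isinstance(model, FunctionalModel):
                mean, sd = model.mean(age), model.d + model.e * age
            else:  # LVEF: independent of covariates by construction
                mean, sd = model.mean, model.sd
            if sd < 0:
                warnings.warn(
                    f"generating SD for {name!r} non-positive at "
                    f"BSA={bsa:.2f}, age={age:.1f}; floored at {cfg.rsd_floor}",
                    stacklevel=2,
                )
                sd = cfg.rsd_floor
            sd *= cfg.noise_scale
            measurements[name] = float(mean + sd * rng.standard_normal()) if sd else float(mean)

        records.append(AthleteRecord(
            athlete_id=f"{'A' if eth == 'arab' else 'B'}{i + 1:04d}",
            ethnicity=eth,
            chronological_age=age,
            biological_age=float(bio),
            bsa=bsa,
            heart_rate=float(hr),
            measurements=measurements,
        ))
    catalog = [MeasureInfo(name, *MEASURE_CATALOG[name]) for name in MEASURE_CATALOG
               if name in cfg.true_models]
    return CohortTable(records, measure_catalog=catalog)


def true_z(cohort: CohortTable, measure: str, model) -> np.ndarray:
    """Z of each record's measurement under a given (e.g. generating) model.

    Vectorised convenience for diagnostics and calibration tests; NaN where
    the measurement is missing.
    """
    obs = cohort.values(measure)
    age = cohort.covariate("chronological_age")
    if isinstance(model, StructuralModel):
        bsa = cohort.covariate("bsa")
        return (obs - model.mean(bsa, age)) / model.rsd(bsa, age)
    if isinstance(model, FunctionalModel):
        return (obs - model.mean(age)) / model.rsd(age)
    if isinstance(model, LvefModel):
        return (obs - model.mean) / model.sd
    raise TypeError(f"unsupported model type {type(model).__name__}")
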