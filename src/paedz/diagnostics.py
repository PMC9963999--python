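"""Model-adequacy battery for normative Z-scores.

A reference model is adequate for a population when the Z-scores it
assigns are independent of the covariates it claims to have adjusted for.
The battery checks: Pearson residual correlations of Z against BSA,
chronological age, biological age and heart rate (effect at p <= 0.05,
interaction at p <= 0.01); a pooled-variance t-test for an ethnicity
effect on Z; the additional variance explained by ethnicity-specific
coefficients (ΔR², clinically significant at >= 5%); and per-ethnicity
exceedance rates (Z >= 2 / Z <= -2, boundary inclusive).  No
multiple-testing correction is applied across the battery: p-values are
reported raw, deliberately, and should be read as screening statistics.

The same battery runs against externally published Z-score equations via
:class:`ExternalModelSpec`, which accepts user-supplied coefficients in
any of four common forms (including the log-linear BSA form used by
log-transformation-based references).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .errors import CohortSchemaError, FitError, SampleSizeError
from .fitting import FunctionalZ, StructuralZ
from .zscores import FunctionalModel, LvefModel, StructuralModel

ALPHA_EFFECT = 0.05
ALPHA_INTERACTION = 0.01
DELTA_R2_THRESHOLD = 0.05

BATTERY_COVARIATES = ("bsa", "chronological_age", "biological_age", "heart_rate")


@dataclass
class CorrelationEntry:
    covariate: str
    r: float
    p: float
    n: int
    significant: bool      # p <= 0.05
    interaction: bool      # p <= 0.01
    note: str = ""


@dataclass
class EthnicityTest:
    mean_z_arab: float
    mean_z_black: float
    mean_difference: float  # black - arab
    t_statistic: float
    p_value: float
    significant: bool


@dataclass
class DeltaR2:
    pooled_r2: float
    stratified_r2: float
    delta: float
    clinically_significant: bool  # delta >= 0.05


@dataclass
class DiagnosticsReport:
    measure: str
    correlations: list = field(default_factory=list)
    ethnicity_test: EthnicityTest | None = None
    delta_r2: DeltaR2 | None = None
    exceedance: dict = field(default_factory=dict)
    hr_dependency_note: str = ""
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def __str__(self):
        lines = [f"Diagnostics: {self.measure}", "-" * 60]
        for c in self.correlations:
            flag = " **" if c.interaction else (" *" if c.significant else "")
            note = f"  ({c.note})" if c.note else ""
            lines.append(
                f"  Z ~ {c.covariate:<18} r = {c.r:7.3f}  p = {c.p:.4f}  "
                f"n = {c.n}{flag}{note}"
            )
        if self.ethnicity_test:
            e = self.ethnicity_test
            lines.append(
                f"  ethnicity (black-arab) diff = {e.mean_difference:7.3f}  "
                f"t = {e.t_statistic:.3f}  p = {e.p_value:.4f}"
                f"{'  *' if e.significant else ''}"
            )
        if self.delta_r2:
            d = self.delta_r2
            lines.append(
                f"  ΔR² (ethnic-specific)  {d.delta:7.4f}  "
                f"({'clinically significant' if d.clinically_significant else 'clinically insignificant'})"
            )
        for group, rates in self.exceedance.items():
            lines.append(
                f"  exceedance {group:<10} Z>=2: {rates['high']:5.2f}%   "
                f"Z<=-2: {rates['low']:5.2f}%"
            )
        if self.hr_dependency_note:
            lines.append(f"  NOTE: {self.hr_dependency_note}")
        for s in self.skipped:
            lines.append(f"  skipped: {s}")
        return "\n".join(lines)


def residual_correlations(z, cohort: CohortTable,
                          covariates=BATTERY_COVARIATES,
                          alpha_effect=ALPHA_EFFECT,
                          alpha_interaction=ALPHA_INTERACTION):
    """Pearson correlation of Z with each covariate, with two-sided p.

    Pairs with missing Z or covariate are dropped per covariate; covariates
    with fewer than 3 complete pairs or zero variance yield a flagged
    entry with r undefined (NaN).
    """
    z = np.asarray(z, dtype=float)
    if z.size != len(cohort):
        raise ValueError("z vector not aligned with cohort rows")
    entries = []
    for cov in covariates:
        x = cohort.covariate(cov)
        ok = np.isfinite(z) & np.isfinite(x)
        n = int(ok.sum())
        if n < 3:
            entries.append(CorrelationEntry(cov, np.nan, np.nan, n, False,
                                            False, note="fewer than 3 pairs; skipped"))
            continue
        if np.std(x[ok]) == 0 or np.std(z[ok]) == 0:
            entries.append(CorrelationEntry(cov, np.nan, np.nan, n, False,
                                            False, note="zero variance"))
            continue
        r, p = stats.pearsonr(x[ok], z[ok])
        entries.append(CorrelationEntry(cov, float(r), float(p), n,
                                        bool(p <= alpha_effect),
                                        bool(p <= alpha_interaction)))
    return entries


def ethnicity_effect(z, ethnicity, alpha=ALPHA_EFFECT) -> EthnicityTest:
    """Pooled-variance two-sample t-test for an ethnicity effect on Z.

    Exactly two ethnicity levels with >= 2 non-missing Z each are required.
    The signed mean difference is reported as black − arab (second level −
    first level alphabetically when the labels differ from the study's).
    """
    z = np.asarray(z, dtype=float)
    ethnicity = np.asarray(ethnicity)
    ok = np.isfinite(z)
    levels = sorted(set(ethnicity[ok]))
    if len(levels) != 2:
        raise ValueError(f"need exactly two ethnicity levels, got {levels}")
    g1, g2 = (z[ok & (ethnicity == lev)] for lev in levels)
    if min(g1.size, g2.size) < 2:
        raise ValueError("each ethnicity group needs at least 2 Z values")
    t, p = stats.ttest_ind(g2, g1, equal_var=True)  # second - first = black - arab
    if np.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return EthnicityTest(
        mean_z_arab=float(np.mean(g1)), mean_z_black=float(np.mean(g2)),
        mean_difference=float(np.mean(g2) - np.mean(g1)),
        t_statistic=float(t), p_value=float(p), significant=bool(p <= alpha),
    )


def _mean_fit_rss(cohort_mask, cohort, measure, family, mean_form):
    """Residual sum of squares of the mean fit on a subset of records."""
    sub = CohortTable([r for r, keep in zip(cohort.records, cohort_mask) if keep],
                      measure_catalog=cohort.measure_catalog, config=cohort.config)
    if family == "structural":
        res = StructuralZ(sub, measure, mean_form=mean_form).fit()
    else:
        res = FunctionalZ(sub, measure).fit()
    if not res.converged:
        raise FitError(f"{measure}: mean fit failed on stratum of size {len(sub)}")
    return float(np.sum(res.resid**2)), res


def delta_r2_ethnicity(cohort: CohortTable, measure: str, family=None,
                       mean_form="additive_age",
                       threshold=DELTA_R2_THRESHOLD) -> DeltaR2:
    """Additional variance explained by ethnicity-specific coefficients.

    Both the pooled and the stratified R² use the grand total sum of
    squares as denominator, so delta = stratified − pooled is the extra
    fraction of overall variance captured by per-ethnicity refits; a
    delta >= 5% is flagged clinically significant.
    """
    family = family or cohort.family(measure)
    obs = cohort.values(measure)
    eth = cohort.ethnicity
    ok = np.isfinite(obs)
    tss = float(np.sum((obs[ok] - np.mean(obs[ok])) ** 2))
    if tss == 0:
        return DeltaR2(0.0, 0.0, 0.0, False)

    pooled_rss, _ = _mean_fit_rss(np.ones(len(cohort), bool), cohort, measure,
                                  family, mean_form)
    strat_rss = 0.0
    for lev in sorted(set(eth)):
        try:
            rss, _ = _mean_fit_rss(eth == lev, cohort, measure, family, mean_form)
        except (SampleSizeError, FitError) as exc:
            raise FitError(f"stratum {lev!r}: {exc}") from exc
        strat_rss += rss
    pooled_r2 = 1.0 - pooled_rss / tss
    strat_r2 = 1.0 - strat_rss / tss
    delta = strat_r2 - pooled_r2
    return DeltaR2(pooled_r2, strat_r2, float(delta),
                   bool(delta >= threshold))


def exceedance_rates(z, ethnicity) -> dict:
    """Percentage of each group with Z >= 2 and Z <= -2 (boundary included).

    Denominator is the non-missing Z count in the group; empty groups are
    absent from the result.  Invariant to record order and to any unit
    rescaling of the underlying measure (Z is dimensionless).
    """
    z = np.asarray(z, dtype=float)
    ethnicity = np.asarray(ethnicity)
    out = {}
    for lev in sorted(set(ethnicity)):
        zi = z[(ethnicity == lev) & np.isfinite(z)]
        if zi.size == 0:
            continue
        out[str(lev)] = {
            "high": float(100.0 * np.mean(zi >= 2.0)),
            "low": float(100.0 * np.mean(zi <= -2.0)),
            "n": int(zi.size),
        }
    return out


# ---------------------------------------------------------------------------
# external (published) model evaluation

EXTERNAL_FORMS = ("structural_additive", "structural_exponent",
                  "polynomial_age", "log_linear_bsa")

_REQUIRED_COEFFS = {
    "structural_additive": ("a", "b", "c", "d", "e", "f"),
    "structural_exponent": ("a", "b", "c", "d", "e", "f"),
    "polynomial_age": ("a", "b", "c", "d", "e"),
    "log_linear_bsa": ("alpha", "beta", "sigma"),
}


@dataclass
class ExternalModelSpec:
    """A user-supplied published Z-score equation for one measure.

    ``log_linear_bsa`` implements the log-transformation convention used by
    several published references: z = (ln(obs) − (alpha + beta·ln(BSA)))/sigma.
    """

    measure: str
    form: str
    coefficients: dict
    source_label: str = ""

    def __post_init__(self):
        if self.form not in EXTERNAL_FORMS:
            raise CohortSchemaError(
                f"unknown external model form {self.form!r}; "
                f"choose one of {EXTERNAL_FORMS}"
            )
        missing = [k for k in _REQUIRED_COEFFS[self.form]
                   if k not in self.coefficients]
        if missing:
            raise CohortSchemaError(
                f"{self.measure} ({self.form}): missing coefficients {missing}"
            )

    @classmethod
    def from_json(cls, path) -> list:
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw, dict):
            raw = [raw]
        return [cls(measure=r["measure"], form=r["form"],
                    coefficients=r["coefficients"],
                    source_label=r.get("source_label", "")) for r in raw]

    def zscores(self, cohort: CohortTable) -> np.ndarray:
        obs = cohort.values(self.measure)
        age = cohort.covariate("chronological_age")
        c = self.coefficients
        if self.form == "log_linear_bsa":
            bsa = cohort.covariate("bsa")
            with np.errstate(invalid="ignore"):
                return ((np.log(obs) - (c["alpha"] + c["beta"] * np.log(bsa)))
                        / c["sigma"])
        if self.form in ("structural_additive", "structural_exponent"):
            bsa = cohort.covariate("bsa")
            mean_form = ("additive_age" if self.form == "structural_additive"
                         else "exponent_age")
            model = StructuralModel(self.measure, a=c["a"], b=c["b"], c=c["c"],
                                    d=c["d"], e=c["e"], f=c["f"],
                                    mean_form=mean_form)
            return (obs - model.mean(bsa, age)) / model.rsd(bsa, age)
        model = FunctionalModel(self.measure, a=c["a"], b=c["b"], c=c["c"],
                                d=c["d"], e=c["e"])
        return (obs - model.mean(age)) / model.rsd(age)


def run_battery(cohort: CohortTable, z, measure: str,
                delta_r2_measure: bool = False,
                mean_form: str = "additive_age") -> DiagnosticsReport:
    """Residual correlations + ethnicity test + exceedance for given Z."""
    report = DiagnosticsReport(measure=measure)
    report.correlations = residual_correlations(z, cohort)
    for c in report.correlations:
        if c.note:
            report.skipped.append(f"correlation with {c.covariate}: {c.note}")
    hr = [c for c in report.correlations
          if c.covariate == "heart_rate" and c.significant]
    if hr:
        report.hr_dependency_note = (
            f"Z retains a heart-rate association (r = {hr[0].r:.3f}, "
            f"p = {hr[0].p:.4f}); interpret with caution in athletes with "
            "unusually low or high resting HR"
        )
    try:
        report.ethnicity_test = ethnicity_effect(z, cohort.ethnicity)
    except ValueError as exc:
        report.skipped.append(f"ethnicity test: {exc}")
    if delta_r2_measure:
        try:
            report.delta_r2 = delta_r2_ethnicity(cohort, measure,
                                                 mean_form=mean_form)
        except (FitError, SampleSizeError, KeyError) as exc:
            report.skipped.append(f"delta-R²: {exc}")
    report.exceedance = exceedance_rates(z, cohort.ethnicity)
    return report


def evaluate_external_model(cohort: CohortTable,
                            spec: ExternalModelSpec) -> DiagnosticsReport:
    """Run the full adequacy battery for a published Z-score equation."""
    z = spec.zscores(cohort)
    report = run_battery(cohort, z, spec.measure)
    if spec.source_label:
        report.measure = f"{spec.measure} [{spec.source_label}]"
    return report


def evaluate_fitted_model(cohort: CohortTable, model,
                          delta_r2_measure: bool = True) -> DiagnosticsReport:
    """Adequacy battery for one of this package's fitted/known models."""
    from .simulate import true_z  # vectorised Z under a model object
    z = true_z(cohort, model.measure, model)
    return run_battery(
        cohort, z, model.measure,
        delta_r2_measure=delta_r2_measure and not isinstance(model, LvefModel),
        mean_form=getattr(model, "mean_form", "additive_age"),
    )
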