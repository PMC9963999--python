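"""Estimation of normative Z-score models from a cohort.

The interface follows the model/results idiom: construct a model object
from a cohort (``StructuralZ``, ``FunctionalZ``, ``LvefZ``), call
``.fit()``, and work with the returned results object — fitted
coefficients, the regressed-SD fit, convergence status, residual Z
summary, ``summary()`` text, Z-scoring, nomograms and plots.  The
module-level ``fit_structural`` / ``fit_functional`` / ``fit_lvef`` /
``estimate_rsd`` functions are thin convenience wrappers.

Fitting procedure
-----------------
Structural measures: stage 1 estimates the allometric mean
``a·BSA^b + c·age`` (or ``a·BSA^(b+c·age)``) by trust-region nonlinear
least squares, deterministically initialised from a log-log regression of
the measure on BSA (slope → b, exp(intercept) → a, c = 0).  Stage 2
estimates the regressed SD by ordinary least squares of the scaled
absolute residuals ``k·|r|`` on BSA and age, with k = sqrt(pi/2) so that
under normal errors E[k·|r|] equals the residual SD (half-normal
identity).  An optional stage 3 performs a single reweighted mean refit
with weights 1/rsd² (off by default).

Functional measures: ordinary least squares on {age², age, 1}, then the
same RSD regression against age.

LVEF: sample mean and SD, a Shapiro-Wilk normality screen (warning only),
the lower reference limit mean − 2·SD, and a Pearson association screen
against BSA, chronological and biological age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .cohort import CohortTable
from .errors import FitError, SampleSizeError
from .zscores import (FunctionalModel, LvefModel, StructuralModel,
                      compute_z, nomogram_table)

#: half-normal correction: E|X| = sigma*sqrt(2/pi), so sigma = sqrt(pi/2)*E|X|
HALF_NORMAL_K = float(np.sqrt(np.pi / 2.0))

DEFAULT_SAMPLE_FLOOR = 30


@dataclass
class RSDFit:
    """Regressed-SD fit: linear model for the residual SD in the covariates.

    ``coefficients`` holds (intercept, slopes...) aligned with
    ``covariate_names``; ``scaling_constant`` is the half-normal factor
    applied to absolute residuals before the regression.
    """

    coefficients: np.ndarray
    covariate_names: tuple
    scaling_constant: float
    n: int
    r2: float
    floor: float = 1e-6
    degenerate: bool = False

    def __call__(self, covariates) -> np.ndarray:
        """Evaluate the fitted SD surface, floored at a positive minimum."""
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != len(self.covariate_names):
            X = X.T
        sd = self.coefficients[0] + X @ self.coefficients[1:]
        return np.maximum(sd, self.floor)


def estimate_rsd(residuals, covariates=None, k: float = HALF_NORMAL_K,
                 floor: float = 1e-6, names: tuple = ()) -> RSDFit:
    """Fit the regressed SD by OLS of scaled absolute residuals.

    Parameters
    ----------
    residuals : array, length n
        Raw residuals from the mean fit (measure units).
    covariates : array (n, p) or None
        Covariate columns the SD may depend on; None → intercept only.
    k : float
        Scaling applied to |residual| before the regression.  The default
        sqrt(pi/2) makes the fit unbiased for the SD of normal errors.
    floor : float
        Positive minimum applied when the fitted surface is evaluated.
    """
    r = np.asarray(residuals, dtype=float)
    if covariates is None:
        X = np.empty((r.size, 0))
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != r.size:
            X = X.T
    if r.size < X.shape[1] + 2:
        raise SampleSizeError(
            f"need at least {X.shape[1] + 2} residuals for the RSD regression, "
            f"got {r.size}"
        )
    if not names:
        names = tuple(f"x{j}" for j in range(X.shape[1]))

    y = k * np.abs(r)
    if np.allclose(r, 0.0):
        warnings.warn("all residuals are zero; RSD intercept set to floor",
                      stacklevel=2)
        coef = np.zeros(X.shape[1] + 1)
        coef[0] = floor
        return RSDFit(coef, names, k, r.size, r2=0.0, floor=floor, degenerate=True)

    design = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, design).fit()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("singular design in the RSD regression")
    return RSDFit(np.asarray(res.params), names, k, r.size,
                  r2=float(res.rsquared) if X.shape[1] else 0.0, floor=floor)


# ---------------------------------------------------------------------------
# results objects


class _ZResultsBase:
    """Shared surface of the fitted-model results objects."""

    def __init__(self, model, spec, rsd_fit, converged, n_iter, n_obs, resid, resid_z):
        self.model = model                 # the estimator object
        self.model_spec = spec             # StructuralModel/FunctionalModel/LvefModel
        self.rsd_fit = rsd_fit
        self.converged = converged
        self.n_iter = n_iter
        self.n_obs = n_obs
        self.resid = resid
        self.resid_z = resid_z

    @property
    def residual_summary(self) -> dict:
        z = self.resid_z
        return {"mean_z": float(np.mean(z)), "sd_z": float(np.std(z, ddof=1))}

    def zscore(self, observed, **covariates):
        if self.model_spec is None:
            raise FitError("fit did not converge; no model available")
        return compute_z(observed, self.model_spec, **covariates)

    def nomogram(self, grid, z_lines=(-2, -1, 0, 1, 2), age=None):
        return nomogram_table(self.model_spec, grid, z_lines=z_lines, age=age)

    def plot_nomogram(self, grid, age=None, scatter=True, ax=None):
        from .reporting import plot_nomogram
        cohort = self.model.cohort if scatter else None
        return plot_nomogram(self.model_spec, grid, age=age, cohort=cohort, ax=ax)

    def _summary_rows(self):
        raise NotImplementedError

    def summary(self) -> str:
        rs = self.residual_summary
        lines = [
            f"{type(self.model).__name__} results: {self.model.measure}",
            "=" * 58,
            f"n obs                 {self.n_obs}",
            f"converged             {self.converged} ({self.n_iter} iterations)",
        ]
        lines += self._summary_rows()
        lines += [
            f"residual Z mean       {rs['mean_z']:8.4f}",
            f"residual Z SD         {rs['sd_z']:8.4f}",
            "=" * 58,
        ]
        return "\n".join(lines)


class StructuralZResults(_ZResultsBase):
    def _summary_rows(self):
        m = self.model_spec
        return [
            f"mean form             {m.mean_form}",
            f"mean  a, b, c         {m.a:10.4f} {m.b:10.4f} {m.c:10.4f}",
            f"RSD   d, e, f         {m.d:10.4f} {m.e:10.4f} {m.f:10.4f}",
            f"RSD regression R²     {self.rsd_fit.r2:8.4f}",
        ]

    def predict(self, bsa, age):
        return self.model_spec.mean(bsa, age)


class FunctionalZResults(_ZResultsBase):
    def _summary_rows(self):
        m = self.model_spec
        return [
            f"mean  a, b, c         {m.a:10.4f} {m.b:10.4f} {m.c:10.4f}",
            f"RSD   d, e            {m.d:10.4f} {m.e:10.4f}",
            f"RSD regression R²     {self.rsd_fit.r2:8.4f}",
        ]

    def predict(self, age):
        return self.model_spec.mean(age)


class LvefZResults(_ZResultsBase):
    def __init__(self, *args, shapiro_p=None, normality_ok=None, associations=None,
                 **kwargs):
        super().__init__(*args, **kwargs)
        self.shapiro_p = shapiro_p
        self.normality_ok = normality_ok
        self.associations = associations or {}

    def _summary_rows(self):
        m = self.model_spec
        rows = [
            f"mean (SD)             {m.mean:8.2f} ({m.sd:.2f}) %",
            f"lower reference limit {m.lower_reference_limit:8.2f} %  (Z = -{m.n_sd:g})",
            f"Shapiro-Wilk p        {self.shapiro_p:8.4f}",
        ]
        for cov, (r, p) in self.associations.items():
            flag = "  *significant (p<=0.01)" if p <= 0.01 else ""
            rows.append(f"assoc. {cov:<15}r={r:7.3f}, p={p:.4f}{flag}")
        return rows


# ---------------------------------------------------------------------------
# estimators


class _ZModelBase:
    def __init__(self, cohort: CohortTable, measure: str,
                 sample_floor: int = DEFAULT_SAMPLE_FLOOR):
        self.cohort = cohort
        self.measure = measure
        self.sample_floor = sample_floor

    def _complete_case(self, covariate_names):
        obs = self.cohort.values(self.measure)
        covs = [self.cohort.covariate(n) for n in covariate_names]
        mask = np.isfinite(obs)
        for c in covs:
            mask &= np.isfinite(c)
        n = int(mask.sum())
        if n < self.sample_floor:
            raise SampleSizeError(
                f"{self.measure}: {n} complete records < sample floor "
                f"{self.sample_floor}"
            )
        return obs[mask], [c[mask] for c in covs], mask


class StructuralZ(_ZModelBase):
    """Allometric BSA + age normative model for one structural measure."""

    def __init__(self, cohort, measure, mean_form: str = "additive_age",
                 sample_floor: int = DEFAULT_SAMPLE_FLOOR, reweight: bool = False):
        super().__init__(cohort, measure, sample_floor)
        self.mean_form = mean_form
        self.reweight = reweight

    @classmethod
    def from_dataframe(cls, df, measure, **kwargs):
        return cls(CohortTable.from_dataframe(df), measure, **kwargs)

    def _mean(self, theta, bsa, age):
        a, b, c = theta
        if self.mean_form == "additive_age":
            return a * bsa**b + c * age
        return a * bsa ** (b + c * age)

    def fit(self, max_iter: int = 200, xtol: float = 1e-10,
            rsd_floor: float = 1e-6) -> StructuralZResults:
        obs, (bsa, age), _ = self._complete_case(["bsa", "chronological_age"])

        # deterministic log-log initialisation (no random restarts)
        slope, intercept = np.polyfit(np.log(bsa), np.log(obs), 1)
        x0 = np.array([np.exp(intercept), slope, 0.0])

        def residual_fn(theta, weights=None):
            r = obs - self._mean(theta, bsa, age)
            return r if weights is None else r * weights

        sol = optimize.least_squares(
            residual_fn, x0, method="trf",
            bounds=([1e-8, -np.inf, -np.inf], np.inf),
            max_nfev=max_iter * (len(x0) + 1), xtol=xtol, ftol=xtol, gtol=xtol,
        )
        converged = bool(sol.status > 0)
        n_iter = int(sol.nfev)
        theta = sol.x
        resid = obs - self._mean(theta, bsa, age)

        rsd_fit = estimate_rsd(resid, np.column_stack([bsa, age]),
                               floor=rsd_floor, names=("bsa", "age"))

        if self.reweight and converged and not rsd_fit.degenerate:
            w = 1.0 / rsd_fit(np.column_stack([bsa, age]))
            sol = optimize.least_squares(
                lambda t: residual_fn(t, w), theta, method="trf",
                bounds=([1e-8, -np.inf, -np.inf], np.inf),
                max_nfev=max_iter * (len(x0) + 1), xtol=xtol, ftol=xtol, gtol=xtol,
            )
            converged = bool(sol.status > 0)
            n_iter += int(sol.nfev)
            theta = sol.x
            resid = obs - self._mean(theta, bsa, age)
            rsd_fit = estimate_rsd(resid, np.column_stack([bsa, age]),
                                   floor=rsd_floor, names=("bsa", "age"))

        spec = None
        if converged:
            d, e, f = rsd_fit.coefficients
            unit = {m.name: m.unit for m in self.cohort.measure_catalog}
            lo, hi = np.min(bsa), np.max(bsa)
            alo, ahi = np.min(age), np.max(age)
            try:
                spec = StructuralModel(
                    measure=self.measure, unit=unit.get(self.measure, ""),
                    a=float(theta[0]), b=float(theta[1]), c=float(theta[2]),
                    d=float(d), e=float(e), f=float(f),
                    mean_form=self.mean_form,
                    bsa_formula=self.cohort.config.bsa_formula,
                    bsa_range=(float(lo), float(hi)),
                    age_range=(float(alo), float(ahi)),
                )
            except ValueError as exc:
                warnings.warn(f"fitted model rejected: {exc}", stacklevel=2)
                converged = False
        rsd_vals = rsd_fit(np.column_stack([bsa, age]))
        return StructuralZResults(self, spec, rsd_fit, converged, n_iter,
                                  obs.size, resid, resid / rsd_vals)


class FunctionalZ(_ZModelBase):
    """Second-order age-polynomial normative model for a Doppler/TDI measure."""

    @classmethod
    def from_dataframe(cls, df, measure, **kwargs):
        return cls(CohortTable.from_dataframe(df), measure, **kwargs)

    def fit(self, rsd_floor: float = 1e-6) -> FunctionalZResults:
        obs, (age,), _ = self._complete_case(["chronological_age"])
        if np.allclose(obs, obs[0]):
            warnings.warn(f"{self.measure}: constant measure column; "
                          "degenerate RSD", stacklevel=2)
        X = sm.add_constant(np.column_stack([age**2, age]), has_constant="add")
        ols = sm.OLS(obs, X).fit()
        c0, a, b = ols.params  # const, age², age
        resid = obs - (a * age**2 + b * age + c0)
        rsd_fit = estimate_rsd(resid, age[:, None], floor=rsd_floor, names=("age",))
        d, e = rsd_fit.coefficients
        unit = {m.name: m.unit for m in self.cohort.measure_catalog}
        try:
            spec = FunctionalModel(
                measure=self.measure, unit=unit.get(self.measure, ""),
                a=float(a), b=float(b), c=float(c0), d=float(d), e=float(e),
                age_range=(float(np.min(age)), float(np.max(age))),
            )
            converged = True
        except ValueError as exc:
            warnings.warn(f"fitted model rejected: {exc}", stacklevel=2)
            spec, converged = None, False
        rsd_vals = rsd_fit(age[:, None])
        return FunctionalZResults(self, spec, rsd_fit, converged, 1,
                                  obs.size, resid, resid / rsd_vals)


class LvefZ(_ZModelBase):
    """Normal model for LVEF with a lower reference limit at Z = -2."""

    def __init__(self, cohort, measure: str = "LVEF",
                 sample_floor: int = DEFAULT_SAMPLE_FLOOR, n_sd: float = 2.0):
        super().__init__(cohort, measure, sample_floor)
        self.n_sd = n_sd

    def fit(self, alpha_normality: float = 0.05,
            alpha_association: float = 0.01) -> LvefZResults:
        obs, _, mask = self._complete_case([])
        mean, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
        if sd == 0:
            warnings.warn(f"{self.measure}: zero variance; reference limit "
                          "equals the mean", stacklevel=2)
            spec = None
            shapiro_p = 1.0
        else:
            shapiro_p = float(stats.shapiro(obs).pvalue)
            if shapiro_p < alpha_normality:
                warnings.warn(
                    f"{self.measure}: Shapiro-Wilk rejects normality "
                    f"(p = {shapiro_p:.4g}); reference limit may be biased",
                    stacklevel=2,
                )
            spec = LvefModel(mean=mean, sd=sd, n_sd=self.n_sd)

        associations = {}
        for cov in ("bsa", "chronological_age", "biological_age"):
            x = self.cohort.covariate(cov)[mask]
            ok = np.isfinite(x)
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                continue
            r, p = stats.pearsonr(x[ok], obs[ok])
            associations[cov] = (float(r), float(p))
            if p <= alpha_association:
                warnings.warn(
                    f"{self.measure}: significant association with {cov} "
                    f"(r = {r:.3f}, p = {p:.3g}); a covariate-free reference "
                    "limit may be inappropriate", stacklevel=2,
                )

        if spec is None:
            # degenerate constant column: limit equals the mean
            resid = obs - mean
            z = np.zeros_like(obs)
            res = LvefZResults(self, None, None, True, 1, obs.size, resid, z,
                               shapiro_p=shapiro_p, normality_ok=True,
                               associations=associations)
            res.mean, res.sd, res.lower_reference_limit = mean, 0.0, mean
            return res
        resid = obs - mean
        return LvefZResults(self, spec, None, True, 1, obs.size, resid,
                            resid / sd, shapiro_p=shapiro_p,
                            normality_ok=shapiro_p >= alpha_normality,
                            associations=associations)


# ---------------------------------------------------------------------------
# convenience wrappers


def fit_structural(cohort, measure, mean_form="additive_age", **kwargs):
    fit_kwargs = {k: kwargs.pop(k) for k in ("max_iter", "xtol", "rsd_floor")
                  if k in kwargs}
    return StructuralZ(cohort, measure, mean_form=mean_form, **kwargs).fit(**fit_kwargs)


def fit_functional(cohort, measure, **kwargs):
    fit_kwargs = {k: kwargs.pop(k) for k in ("rsd_floor",) if k in kwargs}
    return FunctionalZ(cohort, measure, **kwargs).fit(**fit_kwargs)


def fit_lvef(cohort, **kwargs):
    return LvefZ(cohort, **kwargs).fit()


def fit_all(cohort, measures=None, mean_form="additive_age", **kwargs):
    """Fit every (or the given) catalog measure; returns {measure: results}."""
    out = {}
    for m in (measures or cohort.measures):
        family = cohort.family(m)
        if family == "structural":
            out[m] = fit_structural(cohort, m, mean_form=mean_form, **kwargs)
        elif family == "lvef":
            out[m] = fit_lvef(cohort)
        else:
            out[m] = fit_functional(cohort, m)
    return out
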