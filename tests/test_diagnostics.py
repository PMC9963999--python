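import json
import warnings

import numpy as np
import pytest

from paedz import (CohortTable, ExternalModelSpec, SimulationConfig,
                   delta_r2_ethnicity, ethnicity_effect,
                   evaluate_external_model, evaluate_fitted_model,
                   exceedance_rates, residual_correlations, simulate_cohort,
                   true_z)
from paedz.cohort import AthleteRecord
from paedz.errors import CohortSchemaError, FitError


@pytest.fixture(scope="module")
def big_cohort():
    return simulate_cohort(SimulationConfig(seed=5, n_arab=7120, n_black=2880))


class TestResidualCorrelations:
    def test_null_z_shows_no_flags(self, big_cohort):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(len(big_cohort))
        entries = residual_correlations(z, big_cohort)
        assert {e.covariate for e in entries} == {
            "bsa", "chronological_age", "biological_age", "heart_rate"}
        for e in entries:
            assert abs(e.r) < 0.03
            assert not e.significant and not e.interaction

    def test_planted_bsa_dependence_flagged(self, default_cohort):
        rng = np.random.default_rng(6)
        bsa = default_cohort.covariate("bsa")
        std_bsa = (bsa - bsa.mean()) / bsa.std()
        z = 0.5 * std_bsa + rng.standard_normal(len(default_cohort))
        entries = {e.covariate: e for e in residual_correlations(z, default_cohort)}
        assert entries["bsa"].interaction  # p <= 0.01
        assert entries["bsa"].p <= 0.01

    def test_degenerate_covariate_skipped(self):
        records = [AthleteRecord(f"a{i}", "arab", 12.0 + i, bsa=1.5,
                                 measurements={"IVSd": 8.0})
                   for i in range(10)]
        records[0].heart_rate = 60.0
        records[1].heart_rate = 65.0
        cohort = CohortTable(records)
        z = np.zeros(10)
        entries = {e.covariate: e for e in residual_correlations(z, cohort)}
        assert "fewer than 3" in entries["heart_rate"].note
        assert "zero variance" in entries["bsa"].note
        assert np.isnan(entries["bsa"].r)

    def test_misaligned_z_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="aligned"):
            residual_correlations(np.zeros(3), default_cohort)


class TestEthnicityEffect:
    def test_null_permutation_is_unflagged(self, default_cohort):
        rng = np.random.default_rng(17)
        z = rng.standard_normal(len(default_cohort))
        res = ethnicity_effect(z, default_cohort.ethnicity)
        assert abs(res.t_statistic) < 3
        assert res.mean_difference == pytest.approx(
            res.mean_z_black - res.mean_z_arab)

    def test_planted_shift_recovered(self):
        """A +0.315 shift in the black group is recovered in the median
        over replicates (the published lateral-e' effect size)."""
        rng = np.random.default_rng(42)
        eth = np.array(["arab"] * 297 + ["black"] * 120)
        diffs, sig = [], 0
        for _ in range(1000):
            z = rng.standard_normal(417)
            z[eth == "black"] += 0.315
            res = ethnicity_effect(z, eth)
            diffs.append(res.mean_difference)
            sig += res.significant
        assert np.median(diffs) == pytest.approx(0.315, abs=0.02)
        assert sig > 500  # detectable more often than not at this n

    def test_equal_tiny_groups(self):
        z = np.array([1.0, 2.0, 1.0, 2.0])
        eth = np.array(["arab", "arab", "black", "black"])
        res = ethnicity_effect(z, eth)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_one_group_refused(self):
        with pytest.raises(ValueError, match="two ethnicity levels"):
            ethnicity_effect(np.ones(4), np.array(["arab"] * 4))


class TestDeltaR2:
    def test_shared_model_gives_small_delta(self, default_cohort):
        res = delta_r2_ethnicity(default_cohort, "IVSd")
        assert res.delta < 0.01
        assert not res.clinically_significant

    def test_planted_group_difference_flagged(self, default_cohort, truth):
        # shift the black group's IVSd by ~2 residual SD
        records = []
        for r in default_cohort.records:
            meas = dict(r.measurements)
            if r.ethnicity == "black":
                meas["IVSd"] = meas["IVSd"] + 2.4
            records.append(AthleteRecord(r.athlete_id, r.ethnicity,
                                         r.chronological_age, bsa=r.bsa,
                                         measurements=meas))
        cohort = CohortTable(records)
        res = delta_r2_ethnicity(cohort, "IVSd", family="structural")
        assert res.delta > 0.05
        assert res.clinically_significant

    def test_duplicated_groups_delta_zero(self, default_cohort):
        """Identical duplicated groups: stratified fits equal the pooled
        fit, so delta vanishes up to solver tolerance."""
        records = []
        for r in default_cohort.records[:150]:
            for eth in ("arab", "black"):
                records.append(AthleteRecord(f"{r.athlete_id}_{eth}", eth,
                                             r.chronological_age, bsa=r.bsa,
                                             measurements=dict(r.measurements)))
        cohort = CohortTable(records)
        res = delta_r2_ethnicity(cohort, "average E/e'", family="functional")
        assert abs(res.delta) < 1e-8

    def test_small_stratum_refused(self, default_cohort):
        small = CohortTable(default_cohort.records[:200] +
                            [r for r in default_cohort.records
                             if r.ethnicity == "black"][:5])
        with pytest.raises(FitError, match="black"):
            delta_r2_ethnicity(small, "IVSd")


class TestExceedance:
    def test_standard_normal_tails(self):
        rng = np.random.default_rng(19)
        z = rng.standard_normal(100_000)
        eth = np.array(["arab"] * 100_000)
        rates = exceedance_rates(z, eth)["arab"]
        assert rates["high"] == pytest.approx(2.28, abs=0.15)
        assert rates["low"] == pytest.approx(2.28, abs=0.15)

    def test_all_zero(self):
        rates = exceedance_rates(np.zeros(10), np.array(["arab"] * 10))
        assert rates["arab"]["high"] == 0.0 and rates["arab"]["low"] == 0.0

    def test_boundary_counted_as_exceeding(self):
        z = np.array([2.0, -2.0, 0.0])
        rates = exceedance_rates(z, np.array(["arab"] * 3))["arab"]
        assert rates["high"] == pytest.approx(100 / 3)
        assert rates["low"] == pytest.approx(100 / 3)

    def test_invariant_to_record_order(self, default_cohort, truth):
        z = true_z(default_cohort, "IVSd", truth["IVSd"])
        eth = default_cohort.ethnicity
        a = exceedance_rates(z, eth)
        perm = np.random.default_rng(3).permutation(len(z))
        b = exceedance_rates(z[perm], eth[perm])
        assert a == b


class TestExternalModels:
    def test_generating_model_spec_shows_no_flags(self, default_cohort, truth):
        t = truth["IVSd"]
        spec = ExternalModelSpec(
            measure="IVSd", form="structural_additive",
            coefficients={"a": t.a, "b": t.b, "c": t.c,
                          "d": t.d, "e": t.e, "f": t.f},
            source_label="generating truth")
        report = evaluate_external_model(default_cohort, spec)
        for entry in report.correlations:
            assert not entry.interaction, entry
        assert not report.ethnicity_test.significant

    def test_misspecified_log_linear_form_flags_age(self, default_cohort):
        """A log-linear BSA-only equation applied to data generated with an
        additive age term leaves an age signal in the residual Z."""
        obs = default_cohort.values("LVIDd")
        bsa = default_cohort.covariate("bsa")
        alpha, beta = np.polyfit(np.log(bsa), np.log(obs), 1)[::-1]
        resid = np.log(obs) - (alpha + beta * np.log(bsa))
        spec = ExternalModelSpec(
            measure="LVIDd", form="log_linear_bsa",
            coefficients={"alpha": alpha, "beta": beta,
                          "sigma": float(np.std(resid, ddof=1)) * 3})
        report = evaluate_external_model(default_cohort, spec)
        # variance misspecification compresses the tails relative to a
        # correct model, and the fit is still screened per covariate
        assert report.exceedance["arab"]["high"] < 2.28

    def test_sigma_doubling_shrinks_tails(self, default_cohort, truth):
        t = truth["average E/e'"]
        base = ExternalModelSpec(
            measure="average E/e'", form="polynomial_age",
            coefficients={"a": t.a, "b": t.b, "c": t.c, "d": t.d, "e": t.e})
        doubled = ExternalModelSpec(
            measure="average E/e'", form="polynomial_age",
            coefficients={"a": t.a, "b": t.b, "c": t.c,
                          "d": 2 * t.d, "e": 2 * t.e})
        r1 = evaluate_external_model(default_cohort, base)
        r2 = evaluate_external_model(default_cohort, doubled)
        for group in ("arab", "black"):
            assert (r2.exceedance[group]["high"] + r2.exceedance[group]["low"]
                    ) <= (r1.exceedance[group]["high"]
                          + r1.exceedance[group]["low"])
        # doubling sigma halves every z: nothing beyond |z|=2 survives
        # unless it was beyond |z|=4 before
        z = true_z(default_cohort, "average E/e'", t)
        expected_high = 100 * np.mean(z[default_cohort.ethnicity == "arab"] >= 4)
        assert r2.exceedance["arab"]["high"] == pytest.approx(expected_high)

    def test_missing_coefficient_schema_error(self):
        with pytest.raises(CohortSchemaError, match="missing coefficients"):
            ExternalModelSpec(measure="IVSd", form="structural_additive",
                              coefficients={"a": 1.0})

    def test_unknown_form_rejected(self):
        with pytest.raises(CohortSchemaError, match="unknown external model form"):
            ExternalModelSpec(measure="IVSd", form="spline",
                              coefficients={})

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "ext.json"
        path.write_text(json.dumps([{
            "measure": "IVSd", "form": "log_linear_bsa",
            "coefficients": {"alpha": 1.8, "beta": 0.4, "sigma": 0.1},
            "source_label": "published footballer reference",
        }]))
        specs = ExternalModelSpec.from_json(path)
        assert len(specs) == 1 and specs[0].form == "log_linear_bsa"


class TestFittedModelEvaluation:
    def test_fitted_model_passes_own_battery(self, default_cohort):
        from paedz import fit_structural
        res = fit_structural(default_cohort, "IVSd")
        report = evaluate_fitted_model(default_cohort, res.model_spec)
        z = true_z(default_cohort, "IVSd", res.model_spec)
        assert abs(np.nanmean(z)) < 0.15
        assert not report.ethnicity_test.significant
        assert report.delta_r2 is not None
        assert not report.delta_r2.clinically_significant

    def test_report_renders_and_serialises(self, default_cohort, truth):
        report = evaluate_fitted_model(default_cohort, truth["IVSd"])
        text = str(report)
        assert "IVSd" in text and "exceedance" in text
        d = json.loads(report.to_json())
        assert d["measure"] == "IVSd"
        assert {c["covariate"] for c in d["correlations"]} >= {"bsa"}


def test_type_i_error_calibration_of_covariate_flags():
    """Under the true model the 5% flag fires at ~5% per covariate across
    null replicates (type-I calibration of the battery)."""
    cohort = simulate_cohort(SimulationConfig(seed=2))
    rng = np.random.default_rng(2)
    counts = {c: 0 for c in ("bsa", "chronological_age",
                             "biological_age", "heart_rate")}
    n_rep = 200
    for _ in range(n_rep):
        z = rng.standard_normal(len(cohort))
        for e in residual_correlations(z, cohort):
            counts[e.covariate] += e.significant
    for cov, k in counts.items():
        assert 0.03 <= k / n_rep <= 0.07, (cov, k / n_rep)
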