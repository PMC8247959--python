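"""Nonlinear and linear least-squares estimation of the rate constants."""

import itertools

import numpy as np
import pytest

from rnacleave.fitting import (
    ConcSeries,
    PHProfile,
    fit_conc_series,
    fit_ph_profile,
    profile_report,
    report_to_params,
)
from rnacleave.ph_rate_model import (
    Conditions,
    RateParams,
    eq1_rate,
    hydronium_conc,
    speciation_fraction,
)
from rnacleave.synthetic_data import (
    ExperimentDesign,
    NoiseModel,
    gen_conc_series,
    gen_ph_profile,
)

FINE = ExperimentDesign(ph_step=0.25)


def log_objective(params, profile):
    h = 10.0 ** (-profile.pH)
    k = np.array([
        eq1_rate(params, Conditions(pH=float(p), cat_conc=profile.cat_conc))
        for p in profile.pH
    ])
    return float(((np.log10(k) - np.log10(profile.k_obs)) ** 2).sum())


class TestFitPHProfile:
    def test_noise_free_background_recovery(self, background_params):
        prof = gen_ph_profile(background_params, FINE, cat_conc=0.0)
        fit = fit_ph_profile(prof)
        assert fit.converged
        assert set(fit.param_names) == {"kH", "kH2O", "kOH"}
        for name in fit.param_names:
            truth = getattr(background_params, name)
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-4)

    def test_noise_free_catalyst_recovery(self, catalyst_params):
        prof = gen_ph_profile(catalyst_params, FINE, cat_conc=1e-3)
        fit = fit_ph_profile(prof)
        assert fit.converged
        assert set(fit.param_names) == {"kH", "kH2O", "kOH", "kcat", "Ka"}
        # printed-value recovery: kcat 1.6e-3 M^-1 s^-1 and Ka 3e-6 M
        assert fit.estimates["kcat"] == pytest.approx(1.6e-3, rel=1e-4)
        assert fit.estimates["Ka"] == pytest.approx(3e-6, rel=1e-4)
        for name in ("kH", "kH2O", "kOH"):
            truth = getattr(catalyst_params, name)
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-4)

    def test_perturbed_start_converges_to_same_optimum(self, catalyst_params):
        prof = gen_ph_profile(catalyst_params, FINE, cat_conc=1e-3)
        start = {
            n: 2.0 * getattr(catalyst_params, n)
            for n in ("kH", "kH2O", "kOH", "kcat", "Ka")
        }
        fit = fit_ph_profile(prof, start=start)
        assert fit.converged
        assert fit.estimates["kcat"] == pytest.approx(1.6e-3, rel=1e-4)
        assert fit.estimates["Ka"] == pytest.approx(3e-6, rel=1e-4)

    def test_grid_search_oracle(self, catalyst_params):
        """A coarse grid over (kcat, Ka), other constants fixed at truth,
        finds no lower log-residual objective than the fit optimum."""
        prof = gen_ph_profile(catalyst_params, FINE, cat_conc=1e-3)
        fix = {n: getattr(catalyst_params, n) for n in ("kH", "kH2O", "kOH")}
        fit = fit_ph_profile(prof, fix=fix)
        best = log_objective(fit.rate_params(), prof)
        for kcat, Ka in itertools.product(
            np.geomspace(1e-4, 1e-2, 9), np.geomspace(1e-7, 1e-4, 10)
        ):
            trial = catalyst_params.model_copy(
                update={"kcat": float(kcat), "Ka": float(Ka)}
            )
            assert log_objective(trial, prof) >= best - 1e-12

    def test_optimum_beats_truth_on_noisy_data(self, catalyst_params, rng):
        noise = NoiseModel(cv=0.1)
        prof = gen_ph_profile(catalyst_params, FINE, 1e-3, noise, rng)
        fit = fit_ph_profile(prof)
        assert fit.converged
        assert log_objective(fit.rate_params(), prof) <= (
            log_objective(catalyst_params, prof) + 1e-12
        )

    def test_invariant_to_point_order(self, background_params, rng):
        noise = NoiseModel(cv=0.05)
        prof = gen_ph_profile(background_params, FINE, 0.0, noise, rng)
        perm = np.random.default_rng(3).permutation(prof.pH.size)
        shuffled = PHProfile(
            pH=prof.pH[perm], k_obs=prof.k_obs[perm], se=prof.se[perm]
        )
        f1, f2 = fit_ph_profile(prof), fit_ph_profile(shuffled)
        for n in f1.param_names:
            assert f1.estimates[n] == pytest.approx(f2.estimates[n], rel=1e-8)

    def test_invariant_to_unit_rescaling(self, background_params, rng):
        """Scaling k_obs and se together rescales the rate constants and
        leaves dimensionless diagnostics unchanged."""
        noise = NoiseModel(cv=0.05)
        prof = gen_ph_profile(background_params, FINE, 0.0, noise, rng)
        scaled = PHProfile(
            pH=prof.pH, k_obs=60.0 * prof.k_obs, se=60.0 * prof.se
        )
        f1, f2 = fit_ph_profile(prof), fit_ph_profile(scaled)
        for n in ("kH", "kH2O", "kOH"):
            assert f2.estimates[n] == pytest.approx(
                60.0 * f1.estimates[n], rel=1e-6
            )
        assert f2.objective == pytest.approx(f1.objective, rel=1e-6)

    def test_catalytic_constants_excluded_without_catalyst(self, background_params):
        prof = gen_ph_profile(background_params, FINE, cat_conc=0.0)
        fit = fit_ph_profile(prof)
        assert "kcat" not in fit.param_names
        assert "Ka" not in fit.param_names

    def test_unidentifiable_request_rejected(self, background_params):
        prof = gen_ph_profile(background_params, FINE, cat_conc=0.0)
        with pytest.raises(ValueError):
            fit_ph_profile(prof, fix={"kcat": 1e-3})

    def test_too_few_points_rejected(self, background_params):
        prof = gen_ph_profile(background_params, FINE, cat_conc=0.0)
        tiny = PHProfile(pH=prof.pH[:4], k_obs=prof.k_obs[:4], se=prof.se[:4])
        with pytest.raises(ValueError):
            fit_ph_profile(tiny)

    def test_joint_shared_background_fit(self, combined_params):
        bg = combined_params.model_copy(update={"kcat": 0.0, "Ka": 0.0})
        p0 = gen_ph_profile(bg, FINE, cat_conc=0.0)
        p1 = gen_ph_profile(combined_params, FINE, cat_conc=1e-3)
        fit = fit_ph_profile([p0, p1])
        assert fit.converged
        for n in ("kH", "kH2O", "kOH", "kcat", "Ka"):
            assert fit.estimates[n] == pytest.approx(
                getattr(combined_params, n), rel=1e-4
            )

    def test_noisy_replicates_bias_and_coverage(self, combined_params):
        """100 seeded replicates at 10% multiplicative noise: median
        relative bias of every parameter below 5%, and the nominal 1-sigma
        intervals cover truth at a rate consistent with 68%."""
        rng = np.random.default_rng(12345)
        noise = NoiseModel(cv=0.1)
        design = ExperimentDesign()
        names = ("kH", "kH2O", "kOH", "kcat", "Ka")
        bg = combined_params.model_copy(update={"kcat": 0.0, "Ka": 0.0})
        bias = {n: [] for n in names}
        covered = total = 0
        for _ in range(100):
            p0 = gen_ph_profile(bg, design, 0.0, noise, rng)
            p1 = gen_ph_profile(combined_params, design, 1e-3, noise, rng)
            fit = fit_ph_profile([p0, p1])
            assert fit.converged
            for n in names:
                truth = getattr(combined_params, n)
                est, se = fit.estimates[n], fit.standard_errors[n]
                bias[n].append((est - truth) / truth)
                covered += abs(est - truth) <= se
                total += 1
        for n in names:
            assert abs(np.median(bias[n])) < 0.05, n
        assert 0.55 <= covered / total <= 0.80


class TestFitConcSeries:
    def test_exact_line(self):
        c = np.array([0.0, 1e-3, 2e-3, 4e-3, 7e-3])
        a, b = 7.5e-7, 1.5e-3
        series = ConcSeries(cat_conc=c, k_obs=a + b * c, se=np.zeros_like(c))
        fit = fit_conc_series(series)
        assert fit.estimates["intercept"] == pytest.approx(a, rel=1e-10)
        assert fit.estimates["slope"] == pytest.approx(b, rel=1e-10)

    def test_apparent_slope_is_kcat_times_speciation(self, combined_params):
        series = gen_conc_series(combined_params, ExperimentDesign(), pH=7.0)
        fit = fit_conc_series(series)
        frac = speciation_fraction(combined_params, hydronium_conc(7.0))
        assert fit.estimates["slope"] == pytest.approx(
            combined_params.kcat * frac, rel=1e-9
        )

    def test_speciation_correction_restores_intrinsic_kcat(self, combined_params):
        series = gen_conc_series(combined_params, ExperimentDesign(), pH=7.0)
        fit = fit_conc_series(
            series, speciation_correction=True, Ka=combined_params.Ka
        )
        assert fit.meta["slope_intrinsic"] == pytest.approx(
            combined_params.kcat, rel=1e-9
        )

    def test_noisy_slope_within_printed_uncertainty(self, combined_params, rng):
        """A 10%-noise series gives a slope consistent with the published
        apparent catalytic constant (1.7 +/- 2) x 10^-3 M^-1 s^-1."""
        noise = NoiseModel(cv=0.1)
        series = gen_conc_series(
            combined_params, ExperimentDesign(), 7.0, noise, rng
        )
        fit = fit_conc_series(series)
        assert abs(fit.estimates["slope"] - 1.7e-3) < 2e-3

    def test_too_few_points(self):
        series = ConcSeries(
            cat_conc=np.array([0.0, 1e-3]),
            k_obs=np.array([1e-6, 2e-6]),
            se=np.zeros(2),
        )
        with pytest.raises(ValueError):
            fit_conc_series(series)

    def test_correction_requires_ka(self, combined_params):
        series = gen_conc_series(combined_params, ExperimentDesign(), pH=7.0)
        with pytest.raises(ValueError):
            fit_conc_series(series, speciation_correction=True)


class TestProfileReport:
    def test_table_in_scaled_units(self, catalyst_params):
        prof = gen_ph_profile(catalyst_params, FINE, cat_conc=1e-3)
        fit = fit_ph_profile(prof)
        report = profile_report(fit, prof)
        table = report["parameters"]
        assert table["kH"]["value"] == pytest.approx(3.0, rel=1e-3)
        assert table["kH2O"]["value"] == pytest.approx(1.0, rel=1e-3)
        assert table["kOH"]["value"] == pytest.approx(0.07, rel=1e-3)
        assert table["kcat"]["value"] == pytest.approx(1.6, rel=1e-3)
        assert table["Ka"]["value"] == pytest.approx(3.0, rel=1e-3)
        for token in ("3", "0.07", "1.6"):
            assert token in report["text"]

    def test_catalyst_free_entries_marked_na(self, background_params):
        prof = gen_ph_profile(background_params, FINE, cat_conc=0.0)
        fit = fit_ph_profile(prof)
        report = profile_report(fit, prof)
        assert report["parameters"]["kcat"] == "n.a."
        assert report["parameters"]["Ka"] == "n.a."
        assert "n.a." in report["text"]

    def test_round_trip_to_params(self, catalyst_params):
        prof = gen_ph_profile(catalyst_params, FINE, cat_conc=1e-3)
        fit = fit_ph_profile(prof)
        report = profile_report(fit, prof)
        restored = report_to_params(report)
        for n in ("kH", "kH2O", "kOH", "kcat", "Ka"):
            assert getattr(restored, n) == pytest.approx(
                fit.estimates[n], rel=1e-12
            )

    def test_predictions_and_acceleration(self, catalyst_params):
        prof = gen_ph_profile(catalyst_params, FINE, cat_conc=1e-3)
        fit = fit_ph_profile(prof)
        report = profile_report(fit, prof)
        assert len(report["predictions"]) == prof.pH.size
        row = report["predictions"][0]
        assert row["k_pred"] == pytest.approx(row["k_obs"], rel=1e-3)
        assert all(r["fold_acceleration"] >= 1.0 for r in report["predictions"])
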