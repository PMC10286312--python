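"""Likelihood, calibration, profile-likelihood and validation checks."""

import math

import numpy as np
import pandas as pd
import pytest

from tkreceptor import (
    ErrorModel,
    ExposureScenario,
    FitResult,
    TKDataset,
    TKParameters,
    calibrate,
    generate_tk_dataset,
    negative_log_likelihood,
    profile_likelihood,
    validate,
)
from tkreceptor.inference import PROFILE_CUTOFF_95, profile_scan
from tkreceptor.model import simulate
from tkreceptor.synthetic import standard_templates


def toy_dataset(ref_params, times=(1.0, 2.0, 4.0), values=None):
    """Single-treatment 3-point dataset on the kinetic-experiment design."""
    scenario = ExposureScenario.uptake_elimination(0.2, 2.0, 8.0)
    if values is None:
        values = simulate(ref_params, scenario, list(times)).c_total
    df = pd.DataFrame(
        {
            "time_d": times,
            "treatment": "t1",
            "replicate": 0,
            "c_total_umol_kg": values,
        }
    )
    return TKDataset(df, {"t1": scenario})


from conftest import small_design


class TestNegativeLogLikelihood:
    def test_hand_computed_three_point_nll(self, ref_params):
        # independent Gaussian residuals on log concentrations with the
        # residual SD profiled out: NLL = n/2 * (log(2 pi SSR/n) + 1)
        times = (1.0, 2.0, 4.0)
        scenario = ExposureScenario.uptake_elimination(0.2, 2.0, 8.0)
        model = simulate(ref_params, scenario, list(times)).c_total
        obs = model * np.array([1.1, 0.9, 1.05])
        data = toy_dataset(ref_params, times, obs)

        r = np.log(obs) - np.log(model)
        ssr = float(np.sum(r * r))
        expected = 1.5 * (math.log(2 * math.pi * ssr / 3) + 1)
        got = negative_log_likelihood(ref_params, data)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_residuals_hit_sd_floor(self, ref_params):
        data = toy_dataset(ref_params)
        em = ErrorModel()
        floor = 1.5 * (math.log(2 * math.pi * em.sigma_floor**2) + 1)
        assert negative_log_likelihood(ref_params, data, em) == pytest.approx(floor)

    def test_any_perturbation_increases_nll(self, ref_params):
        data = toy_dataset(ref_params)
        base = negative_log_likelihood(ref_params, data)
        for name in ("k_u", "k_e", "B_max"):
            bumped = ref_params.replace(**{name: getattr(ref_params, name) * 1.1})
            assert negative_log_likelihood(bumped, data) > base

    def test_agrees_with_naive_loop_oracle(self, ref_params):
        # point-by-point reimplementation: one simulation per observation
        rng = np.random.default_rng(11)
        ds = small_design(cv=0.3, seed=5, replicates=1)
        for _ in range(3):
            params = TKParameters(
                k_u=rng.uniform(5, 20),
                k_e=rng.uniform(2, 8),
                k_on=rng.uniform(10, 200),
                B_max=rng.uniform(5, 50),
            )
            em = ErrorModel()
            sq = 0.0
            for _, row in ds.observations.iterrows():
                traj = simulate(params, ds.scenarios[row.treatment], [row.time_d])
                r = math.log(max(row.c_total_umol_kg, em.floor)) - math.log(
                    max(traj.c_total[0], em.floor)
                )
                sq += r * r
            n = ds.n_obs
            sigma = max(math.sqrt(sq / n), em.sigma_floor)
            expected = 0.5 * n * (math.log(2 * math.pi * sigma**2) + 1)
            # batched and per-point simulation differ by solver step
            # placement, so agreement is to solver tolerance only
            assert negative_log_likelihood(params, ds, em) == pytest.approx(
                expected, rel=1e-6
            )


class TestCalibrate:
    @pytest.fixture(scope="class")
    @staticmethod
    def noiseless_fit():
        ds = small_design(cv=0.0, seed=None)
        return calibrate(ds, seed=0, n_starts=6), ds

    def test_recovers_generating_parameters(self, noiseless_fit):
        fit, _ = noiseless_fit
        assert fit.best_fit.k_u == pytest.approx(10.6, rel=0.01)
        assert fit.best_fit.k_e == pytest.approx(5.2, rel=0.01)
        assert fit.best_fit.B_max == pytest.approx(25.0, rel=0.01)
        assert fit.r_squared > 0.999

    def test_instantaneous_binding_flagged_at_bound(self, noiseless_fit):
        # data generated with binding at the search cap: the association
        # rate must be reported as boundary-limited, not as an interior CI
        fit, ds = noiseless_fit
        assert "k_on" in fit.boundary_params
        prof = profile_likelihood(fit, ds, "k_on")
        assert prof.upper_at_bound
        assert prof.ci_95[1] == pytest.approx(200.0)

    def test_degenerate_designs_rejected(self, ref_params):
        single = toy_dataset(ref_params, times=(2.0,))
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(single, n_starts=2)

    def test_uptake_elimination_correlation_is_positive(self):
        # joint-confidence geometry: because steady-state levels pin the
        # ratio k_u/k_e, the two rates trade off against each other -- a
        # positively correlated, narrow ellipse.  Checked via the Fisher
        # information (Gauss-Newton J^T J of the log-residuals) on the
        # full calibration design, evaluated at the generating truth.
        from tkreceptor import GPULEX_THIACLOPRID, calibration_design
        from tkreceptor.inference import _residuals

        ds = calibration_design(GPULEX_THIACLOPRID, cv=0.0)
        best = GPULEX_THIACLOPRID
        em = ErrorModel()
        names = ["k_u", "k_e", "B_max"]
        x0 = np.log([getattr(best, n) for n in names])

        def res(x):
            p = best.replace(**{n: math.exp(v) for n, v in zip(names, x)})
            return _residuals(p, ds, em)

        h = 1e-4
        cols = [
            (res(x0 + np.eye(3)[i] * h) - res(x0 - np.eye(3)[i] * h)) / (2 * h)
            for i in range(3)
        ]
        jac = np.column_stack(cols)
        cov = np.linalg.inv(jac.T @ jac)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        assert corr[0, 1] > 0.3
        # k_u-k_e is the dominant trade-off among the identified parameters
        assert corr[0, 1] > abs(corr[0, 2]) and corr[0, 1] > abs(corr[1, 2])


class TestProfileLikelihood:
    def test_quadratic_likelihood_gives_wald_interval(self):
        # for a Gaussian (quadratic) NLL the profile interval must equal
        # MLE +/- 1.96 SE; reoptimization over the second parameter is a
        # closed-form quadratic minimization
        mle, se = 4.0, 0.5

        def reoptimize(value):
            return 0.5 * ((value - mle) / se) ** 2  # nuisance already profiled

        grid, nll, ci, lo_b, hi_b = profile_scan(
            reoptimize, mle, 0.0, bounds=(0.01, 100.0)
        )
        half = se * math.sqrt(2 * PROFILE_CUTOFF_95)  # = 1.96 SE
        assert ci[0] == pytest.approx(mle - half, rel=1e-3)
        assert ci[1] == pytest.approx(mle + half, rel=1e-3)
        assert not lo_b and not hi_b

    def test_profile_deviation_is_zero_at_best_fit(self, ref_params):
        ds = small_design(cv=0.1, seed=21)
        fit = calibrate(ds, seed=0, n_starts=4)
        prof = profile_likelihood(fit, ds, "k_u")
        i = np.argmin(np.abs(prof.grid - fit.best_fit.k_u))
        assert prof.nll[i] <= fit.nll + 1e-6
        assert prof.ci_95[0] < fit.best_fit.k_u < prof.ci_95[1]

    def test_interval_shrinks_with_noise(self):
        widths = []
        for cv in (0.2, 0.1, 0.05):
            ds = small_design(cv=cv, seed=13)
            fit = calibrate(ds, seed=0, n_starts=4)
            prof = profile_likelihood(fit, ds, "k_u")
            widths.append(prof.ci_95[1] - prof.ci_95[0])
        assert widths[0] > widths[1] > widths[2]

    def test_fixed_parameter_cannot_be_profiled(self, ref_params):
        ds = small_design(cv=0.0, seed=None)
        fit = calibrate(ds, seed=0, n_starts=2)
        with pytest.raises(ValueError, match="fixed"):
            profile_likelihood(fit, ds, "k_off")


class TestValidate:
    def _fit_from(self, params) -> FitResult:
        return FitResult(
            best_fit=params, nll=0.0, r_squared=1.0,
            bounds={}, fixed={"k_off": 0.0}, boundary_params=[],
        )

    def test_perfect_model_scores_r2_of_one(self, ref_params):
        ds = generate_tk_dataset(
            ref_params, standard_templates()["III"], role="validation"
        )
        report = validate(self._fit_from(ref_params), ds)
        assert report.r_squared == pytest.approx(1.0, abs=1e-9)
        assert all(
            r == pytest.approx(1.0, abs=1e-9)
            for r in report.per_treatment_r2.values()
        )

    def test_pulsed_exposure_plateaus_at_receptor_capacity(self, ref_params):
        # after each 2 d + 3 d pulse the prediction returns to the same
        # elimination-resistant level fms*B_max: the receptor pool is
        # already saturated by the first pulse
        ds = generate_tk_dataset(
            ref_params, standard_templates()["IV"], role="validation"
        )
        report = validate(self._fit_from(ref_params), ds)
        table = report.observed_vs_predicted
        ends = table[
            (table.treatment == "IV-50ugL") & table.time_d.isin([5.0, 10.0, 15.0])
        ]
        assert len(ends) > 0
        np.testing.assert_allclose(ends["c_total_predicted"], 0.25, rtol=1e-3)

    def test_times_beyond_scenario_span_rejected(self, ref_params):
        scenario = ExposureScenario.uptake_elimination(0.2, 2.0, 2.0)
        df = pd.DataFrame(
            {
                "time_d": [1.0, 99.0],
                "treatment": "t1",
                "replicate": 0,
                "c_total_umol_kg": [0.1, 0.2],
            }
        )
        with pytest.raises(ValueError, match="span"):
            TKDataset(df, {"t1": scenario})
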