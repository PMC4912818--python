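"""Least-squares recovery of (m_S, k_d) and the maintenance report."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retentostat.estimate import (
    FitError,
    ObservationSet,
    RetentostatMaintenanceEstimator,
    bootstrap_uncertainty,
    derive_rates,
    fit_retentostat,
    kd_from_dead_biomass_accumulation,
    maintenance_report,
)
from retentostat.pirt import PirtParameters
from retentostat.simulate import ReactorConfig
from retentostat.synthetic import NoiseModel, generate_retentostat_observations


@pytest.fixture(scope="module")
def exact_obs(study_config, fitted_params):
    obs, truth = generate_retentostat_observations(
        study_config, fitted_params, k_d=4.7e-4, noise=NoiseModel.exact()
    )
    return obs, truth


@pytest.fixture(scope="module")
def exact_fit(exact_obs, study_config):
    obs, _ = exact_obs
    return fit_retentostat(obs, study_config)


class TestObservationSet:
    def test_viable_biomass_is_product(self):
        obs = ObservationSet(
            times=np.arange(0.0, 600.0, 100.0),
            dry_weight=np.full(6, 10.0),
            viability=np.full(6, 0.85),
        )
        np.testing.assert_allclose(obs.viable_biomass, 8.5)

    @pytest.mark.parametrize(
        "times, dw, viab",
        [
            ([0, 1, 1], [1, 1, 1], [1, 1, 1]),          # non-increasing times
            ([0, 1, 2], [1, -1, 1], [1, 1, 1]),          # negative dry weight
            ([0, 1, 2], [1, 1, 1], [1, 1.2, 1]),         # viability > 1
        ],
    )
    def test_invalid_inputs_rejected(self, times, dw, viab):
        with pytest.raises(ValueError):
            ObservationSet(
                times=np.array(times, float),
                dry_weight=np.array(dw, float),
                viability=np.array(viab, float),
            )

    def test_short_series_not_fit_feasible(self, study_config):
        obs = ObservationSet(
            times=np.array([0.0, 10.0, 20.0, 30.0]),
            dry_weight=np.full(4, 9.0),
            viability=np.full(4, 1.0),
        )
        assert not obs.fit_feasible()
        with pytest.raises(FitError):
            fit_retentostat(obs, study_config)


class TestNoiselessRecovery:
    def test_study_truth_recovered_to_01_percent(self, exact_fit):
        assert abs(exact_fit.m_s - 0.00703) / 0.00703 < 1e-3
        assert abs(exact_fit.k_d - 4.7e-4) / 4.7e-4 < 1e-3

    def test_no_death_constant_viability_pins_kd_at_zero(self, study_config):
        params = PirtParameters(y_xs_max=0.5, m_s=0.009)
        obs, _ = generate_retentostat_observations(
            study_config, params, k_d=0.0, noise=NoiseModel.exact()
        )
        np.testing.assert_allclose(obs.viability, 1.0)
        fit = fit_retentostat(obs, study_config)
        assert fit.k_d == pytest.approx(0.0, abs=1e-7)
        assert fit.m_s == pytest.approx(0.009, rel=1e-4)

    @given(
        m_s=st.floats(0.004, 0.02),
        k_d=st.floats(0.0, 2e-3),
    )
    @settings(deadline=None, derandomize=True, max_examples=10)
    def test_randomized_truths_self_consistency(self, study_config, m_s, k_d):
        params = PirtParameters(y_xs_max=0.5, m_s=m_s)
        obs, _ = generate_retentostat_observations(
            study_config, params, k_d=k_d, noise=NoiseModel.exact()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_retentostat(obs, study_config)
        assert fit.m_s == pytest.approx(m_s, rel=1e-3)
        assert fit.k_d == pytest.approx(k_d, rel=1e-3, abs=1e-7)

    def test_objective_no_better_than_truth_artifacts(self, exact_obs, study_config):
        """On noiseless data the optimum cannot beat the generating truth
        by more than numerical tolerance (both SSEs are ~0)."""
        obs, truth = exact_obs
        fit = fit_retentostat(obs, study_config)
        assert fit.sse <= 1e-8

    def test_estimator_sklearn_protocol(self, exact_obs, study_config):
        obs, _ = exact_obs
        est = RetentostatMaintenanceEstimator(config=study_config)
        params = est.get_params()
        assert "y_xs_max" in params
        est.set_params(y_xs_max=0.5)
        est.fit(obs.to_frame())  # DataFrame input path
        assert est.m_s_ == pytest.approx(0.00703, rel=1e-3)
        pred = est.predict(np.array([0.0, 100.0, 480.0]))
        assert pred["c_x_total_gL"].iloc[-1] > pred["c_x_total_gL"].iloc[0]


class TestNoisyRecovery:
    def test_ms_within_10_percent_in_most_replicates(self, study_config, fitted_params):
        """At the declared noise model (5 % dry-weight CV, binomial
        viability counting), m_S lands within ±10 % of truth in the
        vast majority of replicate datasets."""
        hits = 0
        n_rep = 30
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for seed in range(n_rep):
                obs, _ = generate_retentostat_observations(
                    study_config, fitted_params, k_d=4.7e-4,
                    noise=NoiseModel(seed=seed),
                )
                fit = fit_retentostat(obs, study_config)
                hits += abs(fit.m_s - 0.00703) / 0.00703 <= 0.10
        assert hits >= int(0.9 * n_rep)

    def test_unit_system_invariance(self, study_config, fitted_params, tmp_path):
        """Declaring the dry-weight unit as mg/L and converting yields the
        same estimates as the native g/L table."""
        from retentostat.io import read_observations

        obs, _ = generate_retentostat_observations(
            study_config, fitted_params, k_d=4.7e-4, noise=NoiseModel(seed=7)
        )
        df = obs.to_frame()
        path_g = tmp_path / "obs_g.tsv"
        df.to_csv(path_g, sep="\t", index=False)
        df_mg = df.rename(columns={"dw_gL": "dw_mgL"})
        df_mg["dw_mgL"] *= 1000.0
        path_mg = tmp_path / "obs_mg.tsv"
        df_mg.to_csv(path_mg, sep="\t", index=False)

        fit_g = fit_retentostat(read_observations(path_g), study_config)
        fit_mg = fit_retentostat(
            read_observations(path_mg, dw_unit="mg_per_L"), study_config
        )
        assert fit_mg.m_s == pytest.approx(fit_g.m_s, rel=1e-9)
        assert fit_mg.k_d == pytest.approx(fit_g.k_d, rel=1e-9, abs=1e-12)


class TestDerivedQuantities:
    def test_terminal_qs_identity(self, exact_fit):
        # long-run q_S = m_S + k_d / Y
        expected = exact_fit.m_s + exact_fit.k_d / exact_fit.y_xs_max
        assert exact_fit.asymptotic_q_s == pytest.approx(expected)
        rates = derive_rates(exact_fit)
        assert rates.attrs["terminal_q_s_g_per_gx_h"] == pytest.approx(expected)
        # terminal q_s in mmol lands in the experimentally observed range
        assert 0.035 < rates.attrs["terminal_q_s_mmol_per_gx_h"] < 0.05

    def test_terminal_mu_is_kd(self, exact_fit):
        rates = derive_rates(exact_fit)
        assert rates.attrs["terminal_mu_per_h"] == exact_fit.k_d

    def test_qs_series_matches_feed_over_viable_biomass(self, exact_fit, study_config):
        traj = exact_fit.trajectory
        d = study_config.dilution_rate
        np.testing.assert_allclose(traj.q_s, d * traj.c_s_in / traj.c_x_v, rtol=1e-12)

    def test_maintenance_report_values(self, exact_fit):
        rep = maintenance_report(exact_fit, anaerobic_reference_matp=1.0)
        assert rep["m_s_mmol_per_gx_h"] == pytest.approx(0.039, abs=5e-4)
        assert rep["m_atp_mmol_per_gx_h"] == pytest.approx(0.624, abs=5e-3)
        # aerobic maintenance ATP is ~35-40 % below the anaerobic reference
        assert rep["percent_difference_vs_anaerobic"] == pytest.approx(-37.6, abs=1.0)

    def test_zero_maintenance_gives_zero_matp(self):
        from retentostat.pirt import ms_to_matp

        assert ms_to_matp(0.0, "g/gX/h", "respiratory") == 0.0

    def test_kd_slope_diagnostic_close_to_joint_fit(self, exact_obs):
        obs, truth = exact_obs
        kd = kd_from_dead_biomass_accumulation(obs)
        assert kd == pytest.approx(truth["k_d"], rel=0.05)


class TestBootstrap:
    def test_noiseless_interval_is_narrow_and_deterministic(
        self, exact_obs, exact_fit, study_config
    ):
        obs, _ = exact_obs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            b1 = bootstrap_uncertainty(obs, study_config, exact_fit,
                                       n_boot=100, seed=11)
            b2 = bootstrap_uncertainty(obs, study_config, exact_fit,
                                       n_boot=100, seed=11)
        assert b1["valid"]
        assert b1 == b2  # same seed, identical intervals
        width = b1["m_s"]["upper"] - b1["m_s"]["lower"]
        assert width < 1e-6

    def test_noisy_interval_covers_truth(self, study_config, fitted_params):
        obs, _ = generate_retentostat_observations(
            study_config, fitted_params, k_d=4.7e-4, noise=NoiseModel(seed=3)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_retentostat(obs, study_config)
            b = bootstrap_uncertainty(obs, study_config, fit, n_boot=100, seed=5)
        assert b["valid"]
        assert b["m_s"]["lower"] <= 0.00703 * 1.05
        assert b["m_s"]["upper"] >= 0.00703 * 0.95

    def test_too_few_resamples_rejected(self, exact_obs, exact_fit, study_config):
        obs, _ = exact_obs
        with pytest.raises(ValueError):
            bootstrap_uncertainty(obs, study_config, exact_fit, n_boot=10)
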