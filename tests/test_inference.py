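"""Decoding, pseudo-residuals, occupancy and equilibrium curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import divehmm as dh
from divehmm import likelihood as lk
from divehmm.inference import (
    equilibrium_distribution,
    pseudo_residuals,
    smoothing_probabilities,
    state_occupancy,
    ts_state_table,
)

from conftest import random_small_instance, tiny_params, tiny_spec
from oracles import brute_force_viterbi, softmax_tpm, stationary


class TestViterbi:
    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(12):
            spec, params, rec, _ = random_small_instance(rng)
            got = lk.viterbi_path(rec, params, spec)
            want, _ = brute_force_viterbi(rec, params, spec)
            np.testing.assert_array_equal(got, want)

    def test_matches_exhaustive_argmax_with_covariates(self, rng):
        for _ in range(6):
            spec, params, rec, _ = random_small_instance(rng, design="full")
            got = lk.viterbi_path(rec, params, spec)
            want, _ = brute_force_viterbi(rec, params, spec)
            np.testing.assert_array_equal(got, want)

    def test_pinned_records_always_decode_to_known_state(self, female_records,
                                                         female_scenario):
        rec, _ = female_records
        path = lk.viterbi_path(rec, female_scenario.params, female_scenario.spec)
        assert (path[(rec["record_type"] == "haulout").to_numpy()] == 0).all()
        assert (path[(rec["record_type"] == "surface").to_numpy()] == 1).all()

    def test_best_path_likelihood_below_forward(self, rng):
        for _ in range(8):
            spec, params, rec, _ = random_small_instance(rng)
            _, best = brute_force_viterbi(rec, params, spec)
            ll = lk.forward_loglik(rec, params, spec)
            assert best <= ll + 1e-9

    def test_high_accuracy_on_separated_states(self, female_scenario):
        rec, states = dh.simulate_sequence(female_scenario, 10_000, seed=31)
        path = lk.viterbi_path(rec, female_scenario.params, female_scenario.spec)
        assert (path == states).mean() >= 0.99

    def test_smoothing_probabilities_normalised(self, female_records,
                                                female_scenario):
        rec, states = female_records
        gamma = smoothing_probabilities(rec, female_scenario.params,
                                        female_scenario.spec)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert gamma[np.arange(len(states)), states].mean() > 0.95


class TestOccupancy:
    def test_degenerate_single_state(self):
        spec = tiny_spec(1)
        out = state_occupancy(np.zeros(100, dtype=int), spec, n_boot=20)
        assert out.loc[0, "proportion"] == 1.0
        assert (out.loc[1:, "proportion"] == 0.0).all()

    def test_two_identical_individuals_have_tight_interval(self):
        spec = tiny_spec(1)
        decoded = np.tile(np.array([0, 1, 2, 2]), 50)
        ids = np.repeat([0, 1], 100)
        out = state_occupancy(decoded, spec, individual_ids=ids, n_boot=50)
        np.testing.assert_allclose(out["lower95"], out["proportion"], atol=1e-12)
        np.testing.assert_allclose(out["upper95"], out["proportion"], atol=1e-12)

    def test_single_individual_flagged_as_block_bootstrap(self):
        spec = tiny_spec(1)
        out = state_occupancy(np.zeros(60, dtype=int), spec, n_boot=10)
        assert (out["interval"] == "within-individual block bootstrap").all()

    def test_decoded_occupancy_near_generating_stationary(self, female_scenario):
        rec, states = dh.simulate_sequence(female_scenario, 20_000, seed=32)
        path = lk.viterbi_path(rec, female_scenario.params, female_scenario.spec)
        occ = np.bincount(path, minlength=6) / path.size
        # benthic occupancy close to the generating long-run value (0.09)
        assert abs(occ[5] - 0.09) < 0.03


class TestPseudoResiduals:
    def test_single_state_residual_is_marginal_cdf(self):
        spec = tiny_spec(1)
        params = tiny_params(spec)
        scen = dh.GeneratingScenario(spec=spec, params=params)
        rec, states = dh.simulate_sequence(scen, 200, seed=33)
        resid = pseudo_residuals(rec, params, spec)
        dive = rec["record_type"] == "dive"
        from divehmm.params import gamma_shape_rate

        kz, rz = gamma_shape_rate(params.depth_mean[0], params.depth_sd[0])
        want = stats.gamma.cdf(rec.loc[dive, "hunting_depth_m"], kz, scale=1 / rz)
        np.testing.assert_allclose(resid.loc[dive, "depth"], want, atol=1e-10)

    def test_non_dive_residual_uses_only_duration(self, female_records,
                                                  female_scenario):
        rec, _ = female_records
        resid = pseudo_residuals(rec, female_scenario.params, female_scenario.spec)
        nondive = rec["record_type"] != "dive"
        assert resid.loc[nondive, ["depth", "prop", "salinity", "benthic"]].isna().all().all()
        assert resid.loc[nondive, "duration"].notna().all()

    def test_missing_salinity_gives_missing_residual(self, female_scenario):
        from dataclasses import replace

        scen = replace(female_scenario, salinity_missing_rate=0.5)
        rec, _ = dh.simulate_sequence(scen, 400, seed=34)
        resid = pseudo_residuals(rec, scen.params, scen.spec)
        dive = rec["record_type"] == "dive"
        missing = dive & rec["salinity_psu"].isna()
        assert resid.loc[missing, "salinity"].isna().all()
        assert resid.loc[dive & ~missing.to_numpy(), "salinity"].notna().all()


class TestEquilibrium:
    def test_homogeneous_matches_eigen_stationary(self, female_scenario):
        params, spec = female_scenario.params, female_scenario.spec
        curve = equilibrium_distribution((params, spec), hour_grid=[0.0],
                                         week_grid=[15.0])
        P = dh.transition_matrix_from_logits(params.tpm_coefs[:, 0], 6)
        np.testing.assert_allclose(curve.probs[0, 0], stationary(P), atol=1e-10)

    def test_zero_coefficients_give_uniform_everywhere(self):
        spec = tiny_spec(2, design="full")
        params = tiny_params(spec)
        params.tpm_coefs = np.zeros_like(params.tpm_coefs)
        curve = equilibrium_distribution((params, spec),
                                         hour_grid=np.arange(0, 24, 1.0),
                                         week_grid=(7, 15, 24))
        np.testing.assert_allclose(curve.probs, 0.25, atol=1e-12)

    def test_probabilities_sum_to_one_and_periodic(self, rng):
        spec = tiny_spec(2, design="full")
        params = tiny_params(spec, rng=rng)
        params.tpm_coefs = params.tpm_coefs + rng.normal(0, 0.3,
                                                         params.tpm_coefs.shape)
        hours = np.arange(0, 24, 0.5)
        curve = equilibrium_distribution((params, spec), hour_grid=hours,
                                         week_grid=(7.0,))
        np.testing.assert_allclose(curve.probs.sum(axis=2), 1.0, atol=1e-10)
        ext = equilibrium_distribution((params, spec), hour_grid=hours + 24.0,
                                       week_grid=(7.0,))
        np.testing.assert_allclose(curve.probs, ext.probs, atol=1e-10)

    def test_ci_bounds_bracket_estimate_within_unit_interval(self, rng):
        spec = tiny_spec(1, design="intercept")
        params = tiny_params(spec, rng=rng)
        cov = np.eye(params.tpm_coefs.size) * 0.5  # wide: forces clipping
        curve = equilibrium_distribution((params, spec), hour_grid=[0.0],
                                         week_grid=[15.0], cov=cov)
        assert (curve.lower >= 0).all() and (curve.upper <= 1).all()
        assert (curve.lower <= curve.probs).all()
        assert (curve.upper >= curve.probs).all()

    def test_to_frame_is_tidy(self):
        spec = tiny_spec(1)
        params = tiny_params(spec)
        curve = equilibrium_distribution((params, spec), hour_grid=[0.0, 12.0],
                                         week_grid=[7.0])
        df = curve.to_frame()
        assert set(df.columns) >= {"week", "hour", "state", "probability"}
        assert len(df) == 2 * 3


class TestTsTable:
    def test_empty_without_temperature(self, caplog):
        spec = tiny_spec(1)
        rec = pd.DataFrame(
            [dict(record_type="dive", duration_s=100.0, hunting_depth_m=50.0,
                  prop_hunting=0.5, benthic=0.0, salinity_psu=34.4)]
        )
        with caplog.at_level("WARNING"):
            out = ts_state_table(rec, np.array([2]), spec)
        assert out.empty
        assert "temperature" in caplog.text.lower()

    def test_rows_join_one_to_one_with_dives(self):
        spec = tiny_spec(2)
        rec = pd.DataFrame(
            [
                dict(record_type="haulout", duration_s=1000.0),
                dict(record_type="dive", duration_s=600.0, hunting_depth_m=100.0,
                     prop_hunting=0.4, benthic=0.0, salinity_psu=34.3,
                     temperature_C=-1.5),
                dict(record_type="dive", duration_s=700.0, hunting_depth_m=350.0,
                     prop_hunting=0.4, benthic=1.0, salinity_psu=34.6,
                     temperature_C=np.nan),
            ]
        )
        out = ts_state_table(rec, np.array([0, 2, 3]), spec)
        assert len(out) == 1
        assert out.iloc[0]["state"] == "dive1"
        assert out.iloc[0]["salinity_psu"] == 34.3
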