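"""Emission densities, transition matrices and the forward recursion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import divehmm as dh
from divehmm import likelihood as lk
from divehmm.params import HmmParams, beta_ab, gamma_shape_rate

from conftest import random_small_instance, tiny_params, tiny_spec
from oracles import brute_force_loglik, emission_logpdf


def dive_row(spec, params, state=2, **over):
    d = state - 2
    row = dict(
        record_type="dive",
        duration_s=params.duration_mean[state],
        hunting_depth_m=params.depth_mean[d],
        prop_hunting=params.hunt_mean[d],
        benthic=1.0,
        salinity_psu=params.salinity_mean[d],
        local_hour=12.0,
        week_of_year=15.0,
    )
    row.update(over)
    return row


class TestEmissionDensity:
    def test_known_state_constraint_gives_neg_inf(self):
        spec = tiny_spec(2)
        params = tiny_params(spec)
        row = dict(record_type="haulout", duration_s=3600.0,
                   local_hour=0.0, week_of_year=10.0)
        assert lk.emission_logdensity(row, 2, params, spec) == -np.inf
        assert np.isfinite(lk.emission_logdensity(row, 0, params, spec))
        # dive records likewise never occupy a non-diving state
        drow = dive_row(spec, params)
        assert lk.emission_logdensity(drow, 0, params, spec) == -np.inf

    def test_matches_sum_of_scipy_densities(self, rng):
        spec = tiny_spec(3)
        params = tiny_params(spec, rng=rng)
        for state in (2, 3, 4):
            row = dive_row(spec, params, state=state)
            got = lk.emission_logdensity(row, state, params, spec)
            want = emission_logpdf(row, state, params, spec)
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_salinity_term_omitted_exactly(self):
        spec = tiny_spec(1)
        params = tiny_params(spec)
        full = dive_row(spec, params)
        nosal = dive_row(spec, params, salinity_psu=np.nan)
        diff = lk.emission_logdensity(full, 2, params, spec) - lk.emission_logdensity(
            nosal, 2, params, spec
        )
        want = stats.norm.logpdf(
            params.salinity_mean[0], params.salinity_mean[0], params.salinity_sd[0]
        )
        assert diff == pytest.approx(want, abs=1e-10)

    def test_missing_benthic_term_omitted(self):
        spec = tiny_spec(1)
        params = tiny_params(spec)
        noben = dive_row(spec, params, benthic=np.nan)
        got = lk.emission_logdensity(noben, 2, params, spec)
        withben = lk.emission_logdensity(dive_row(spec, params, benthic=1.0), 2,
                                         params, spec)
        assert got == pytest.approx(withben - np.log(params.benthic_p[0]), abs=1e-10)

    @pytest.mark.parametrize("family", ["duration", "depth", "prop", "salinity"])
    def test_densities_integrate_to_one(self, family):
        """Numeric quadrature over each emission family's support."""
        spec = tiny_spec(1)
        params = tiny_params(spec)
        if family == "duration":
            k, r = gamma_shape_rate(params.duration_mean[2], params.duration_sd[2])
            f = lambda x: stats.gamma.pdf(x, k, scale=1 / r)
            lo, hi = 0, np.inf
        elif family == "depth":
            k, r = gamma_shape_rate(params.depth_mean[0], params.depth_sd[0])
            f = lambda x: stats.gamma.pdf(x, k, scale=1 / r)
            lo, hi = 0, np.inf
        elif family == "prop":
            a, b = beta_ab(params.hunt_mean[0], params.hunt_precision[0])
            f = lambda x: stats.beta.pdf(x, a, b)
            lo, hi = 0, 1
        else:
            mu, sd = params.salinity_mean[0], params.salinity_sd[0]
            f = lambda x: stats.norm.pdf(x, mu, sd)
            lo, hi = mu - 12 * sd, mu + 12 * sd  # quad misses a narrow bump on R
        val, _ = integrate.quad(f, lo, hi)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestForward:
    def test_single_record_is_log_mixture(self, rng):
        spec, params, rec, _ = random_small_instance(rng, T=1)
        ll = lk.forward_loglik(rec, params, spec)
        assert ll == pytest.approx(brute_force_loglik(rec, params, spec), abs=1e-9)

    def test_matches_path_enumeration_homogeneous(self, rng):
        for _ in range(10):
            spec, params, rec, _ = random_small_instance(rng)
            ll = lk.forward_loglik(rec, params, spec)
            want = brute_force_loglik(rec, params, spec)
            assert ll == pytest.approx(want, abs=1e-8)

    def test_matches_path_enumeration_with_covariates(self, rng):
        for _ in range(5):
            spec, params, rec, _ = random_small_instance(rng, design="full")
            ll = lk.forward_loglik(rec, params, spec)
            want = brute_force_loglik(rec, params, spec)
            assert ll == pytest.approx(want, abs=1e-8)

    def test_known_state_record_constrains_paths(self, rng):
        """Inserting pinned records equals the constrained path sum."""
        found = False
        for _ in range(20):
            spec, params, rec, states = random_small_instance(rng, T=6)
            if (rec["record_type"] != "dive").any():
                found = True
                ll = lk.forward_loglik(rec, params, spec)
                want = brute_force_loglik(rec, params, spec)
                assert ll == pytest.approx(want, abs=1e-8)
        assert found

    def test_label_switching_symmetry(self, rng):
        spec = tiny_spec(3)
        params = tiny_params(spec, rng=rng)
        scen = dh.GeneratingScenario(spec=spec, params=params)
        rec, _ = dh.simulate_sequence(scen, 200, seed=3)
        ll = lk.forward_loglik(rec, params, spec)
        permuted = params.permute_states(np.array([0, 1, 4, 2, 3]))
        assert lk.forward_loglik(rec, permuted, spec) == pytest.approx(ll, abs=1e-8)

    def test_pooled_additivity(self, rng):
        spec = tiny_spec(2)
        params = tiny_params(spec, rng=rng)
        scen = dh.GeneratingScenario(spec=spec, params=params)
        rec, _ = dh.simulate_sequence(scen, 120, seed=4)
        single = lk.forward_loglik(rec, params, spec)
        assert lk.pooled_loglik([rec, rec], params, spec) == pytest.approx(
            2 * single, rel=1e-12
        )
        # one table with two individuals == sum of separate evaluations
        rec2 = rec.copy()
        rec2["individual_id"] = "other"
        both = pd.concat([rec, rec2], ignore_index=True)
        assert lk.forward_loglik(both, params, spec) == pytest.approx(
            2 * single, rel=1e-12
        )

    def test_gradient_matches_finite_differences(self, rng):
        spec = tiny_spec(2, design="full")
        params = tiny_params(spec, rng=rng)
        scen = dh.GeneratingScenario(spec=spec, params=params,
                                     salinity_missing_rate=0.2)
        rec, _ = dh.simulate_sequence(scen, 150, seed=5)
        data = lk.pack_records(rec, spec)
        ll, grad = lk.core_loglik_and_grad(data, params, spec)
        w = params.to_working()
        for i in rng.choice(w.size, size=12, replace=False):
            h = 1e-6 * max(1, abs(w[i]))
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd = (
                lk.core_loglik(data, HmmParams.from_working(wp, spec), spec)
                - lk.core_loglik(data, HmmParams.from_working(wm, spec), spec)
            ) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=5e-5, rel=5e-5)


class TestTransitionMatrix:
    def test_uniform_when_coefficients_zero(self):
        spec = tiny_spec(2, design="full")
        params = tiny_params(spec)
        params.tpm_coefs = np.zeros_like(params.tpm_coefs)
        P = lk.transition_matrix(13.0, 20.0, params, spec)
        np.testing.assert_allclose(P, 0.25, atol=1e-14)

    @given(st.floats(0, 24, allow_nan=False), st.floats(5, 25, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_periodic_in_hour(self, hour, week):
        spec = tiny_spec(2, design="full")
        params = tiny_params(spec)
        params.tpm_coefs = params.tpm_coefs + 0.3
        P1 = lk.transition_matrix(hour, week, params, spec)
        P2 = lk.transition_matrix((hour + 24.0) % 24.0, week, params, spec)
        np.testing.assert_allclose(P1, P2, atol=1e-10)
        np.testing.assert_allclose(P1.sum(axis=1), 1.0, atol=1e-12)

    def test_continuous_in_week(self):
        spec = tiny_spec(2, design="full")
        params = tiny_params(spec)
        params.tpm_coefs = params.tpm_coefs + 0.2
        P1 = lk.transition_matrix(6.0, 15.0, params, spec)
        P2 = lk.transition_matrix(6.0, 15.0 + 1e-7, params, spec)
        assert np.abs(P1 - P2).max() < 1e-6


class TestErrors:
    def test_all_impossible_record_names_position(self):
        spec = tiny_spec(1)
        params = tiny_params(spec)
        rec = pd.DataFrame(
            [
                dict(record_type="haulout", duration_s=100.0, local_hour=0.0,
                     week_of_year=10.0),
            ]
        )
        # force an impossible row by zero-probability duration? use bad spec:
        # a dive record with no dive state is impossible only when D=0, which
        # the spec forbids; instead check the validation of corrupt streams.
        bad = pd.DataFrame([dict(record_type="dive", duration_s=600.0,
                                 hunting_depth_m=-5.0, prop_hunting=0.5,
                                 benthic=0.0, salinity_psu=34.5,
                                 local_hour=0.0, week_of_year=10.0)])
        with pytest.raises(ValueError, match="hunting_depth"):
            lk.pack_records(bad, spec)

    def test_unknown_record_type_rejected(self):
        spec = tiny_spec(1)
        rec = pd.DataFrame([dict(record_type="cruise", duration_s=10.0)])
        with pytest.raises(ValueError, match="cruise"):
            lk.pack_records(rec, spec)

    def test_empty_sequence_rejected(self):
        spec = tiny_spec(1)
        with pytest.raises(ValueError, match="empty"):
            lk.pack_records(pd.DataFrame(columns=["record_type", "duration_s"]), spec)
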