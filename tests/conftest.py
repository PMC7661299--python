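import numpy as np
import pandas as pd
import pytest

import divehmm as dh
from divehmm.params import HmmParams, coefs_from_matrix
from divehmm.spec import HmmSpec


@pytest.fixture(scope="session")
def female_scenario():
    return dh.reference_scenario("F")


@pytest.fixture(scope="session")
def male_scenario():
    return dh.reference_scenario("M")


@pytest.fixture(scope="session")
def female_records(female_scenario):
    """A moderate simulated female sequence shared across read-only tests."""
    return dh.simulate_sequence(female_scenario, 3000, seed=11)


def tiny_spec(n_dive=1, design="intercept", initial="stationary"):
    names = ("haulout", "surface") + tuple(f"dive{i+1}" for i in range(n_dive))
    return HmmSpec(state_names=names, covariate_design=design, initial=initial)


def tiny_params(spec, rng=None, tpm=None):
    """Well-separated parameters for a small model, optionally jittered."""
    D = spec.n_dive_states
    N = spec.n_states
    base = dict(
        duration_mean=np.concatenate(
            [[9000.0, 2000.0], np.linspace(120.0, 1100.0, D)]
        ),
        duration_sd=np.concatenate([[4000.0, 900.0], np.linspace(40.0, 300.0, D)]),
        depth_mean=np.linspace(10.0, 400.0, D),
        depth_sd=np.linspace(3.0, 45.0, D),
        hunt_mean=np.linspace(0.52, 0.42, D),
        hunt_precision=np.full(D, 30.0),
        benthic_p=np.linspace(0.01, 0.9, D) if D > 1 else np.array([0.3]),
        salinity_mean=np.linspace(34.2, 34.6, D),
        salinity_sd=np.full(D, 0.04),
    )
    if tpm is None:
        occ = np.full(N, 1.0 / N)
        tpm = dh.persistence_matrix(occ, 0.8)
    K = spec.n_design
    coefs = np.zeros((N * (N - 1), K))
    coefs[:, :1] = coefs_from_matrix(tpm)
    params = HmmParams(tpm_coefs=coefs, **base)
    if rng is not None:
        w = params.to_working() + rng.normal(0, 0.05, params.to_working().size)
        params = HmmParams.from_working(w, spec)
    return params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_small_instance(rng, N=None, T=None, design="intercept"):
    """A random tiny model + sequence for path-enumeration oracles."""
    N = N or int(rng.integers(3, 4))
    T = T or int(rng.integers(2, 7))
    spec = tiny_spec(N - 2, design=design)
    params = tiny_params(spec, rng=rng)
    scen = dh.GeneratingScenario(spec=spec, params=params)
    rec, states = dh.simulate_sequence(scen, T, seed=int(rng.integers(2**31 - 1)))
    return spec, params, rec, states
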