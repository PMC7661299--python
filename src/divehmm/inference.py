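"""Decoding, model diagnostics and covariate-dependent equilibrium curves.

The equilibrium (stationary) distribution at covariate value z is the
probability vector delta solving delta * Gamma(z) = delta; plotted over a
(week x hour) grid it shows when in the diel and seasonal cycle a seal is
expected to occupy each behavioural state.  Its pointwise 95% confidence
bands come from the delta method: the gradient of delta with respect to the
working transition coefficients (by central finite differences) propagated
through the fitted covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import likelihood as lk
from .params import (
    HmmParams,
    beta_ab,
    gamma_shape_rate,
    stationary_distribution,
    transition_matrix_from_logits,
)
from .spec import HmmSpec

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# decoding


def viterbi(records, fitted) -> np.ndarray:
    """Most probable state path for a sequence under a fitted model."""
    return lk.viterbi_path(records, fitted.params, fitted.spec)


def smoothing_probabilities(
    records, params: HmmParams, spec: HmmSpec
) -> np.ndarray:
    """(T, N) posterior state probabilities given all observations."""
    data = records if isinstance(records, lk.StreamData) else lk.pack_records(records, spec)
    logb = lk.emission_table(data, params, spec, core_only=True)
    eta, homogeneous, deltas = lk._prepare_eval(data, params, spec)
    _, _, filt = lk._forward_filter_kernel(
        logb, eta, homogeneous, deltas, data.seg_starts
    )
    N = spec.n_states
    if homogeneous:
        Gamma_all = None
        Gamma0 = transition_matrix_from_logits(eta[0], N)
    else:
        Gamma_all = transition_matrix_from_logits(eta, N)
    gamma = np.empty_like(filt)
    for s, e in data.segment_bounds():
        bw = np.ones(N)
        gamma[e - 1] = filt[e - 1]
        for t in range(e - 2, s - 1, -1):
            G = Gamma0 if Gamma_all is None else Gamma_all[t + 1]
            m = logb[t + 1].max()
            w = np.exp(logb[t + 1] - m)
            bw = G @ (w * bw)
            tot = bw.sum()
            if tot > 0:
                bw = bw / tot
            g = filt[t] * bw
            gamma[t] = g / g.sum()
    return gamma


def decode_states(fitted) -> pd.DataFrame:
    """Viterbi path with the local posterior probability of each decoded state."""
    data = fitted.model.data
    path = lk.viterbi_path(data, fitted.params, fitted.spec)
    gamma = smoothing_probabilities(data, fitted.params, fitted.spec)
    return pd.DataFrame(
        {
            "state_index": path,
            "state": [fitted.spec.state_names[i] for i in path],
            "prob_decoded": gamma[np.arange(len(path)), path],
        }
    )


# ---------------------------------------------------------------------------
# occupancy


def state_occupancy(
    decoded: np.ndarray,
    spec: HmmSpec,
    individual_ids: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
    n_blocks: int = 50,
) -> pd.DataFrame:
    """Per-state occupancy proportions with bootstrap intervals.

    The resampling unit is the individual; with a single individual the
    sequence is cut into ``n_blocks`` contiguous blocks instead and the
    interval is flagged as a within-individual block bootstrap.
    """
    decoded = np.asarray(decoded)
    N = spec.n_states
    T = decoded.size
    if individual_ids is None:
        individual_ids = np.zeros(T, dtype=int)
    individual_ids = np.asarray(individual_ids)
    props = np.bincount(decoded, minlength=N) / T

    uniq = pd.unique(individual_ids)
    rng = np.random.default_rng(seed)
    if len(uniq) > 1:
        groups = [decoded[individual_ids == u] for u in uniq]
        method = "individual bootstrap"
    else:
        groups = np.array_split(decoded, min(n_blocks, T))
        method = "within-individual block bootstrap"
        log.warning("single individual: occupancy interval uses %s", method)
    boot = np.empty((n_boot, N))
    for b in range(n_boot):
        pick = rng.integers(0, len(groups), size=len(groups))
        sample = np.concatenate([groups[i] for i in pick])
        boot[b] = np.bincount(sample, minlength=N) / sample.size
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "state": spec.state_names,
            "proportion": props,
            "lower95": lo,
            "upper95": hi,
            "interval": method,
        }
    )


# ---------------------------------------------------------------------------
# pseudo-residuals


def pseudo_residuals(
    records, params: HmmParams, spec: HmmSpec, seed: int = 0
) -> pd.DataFrame:
    """One-step-ahead uniform pseudo-residuals per record and stream.

    The residual of stream x at time t is the forecast conditional CDF
    sum_j P(S_t = j | x_(1:t-1), type_t) F_j(x_t); under the true model the
    continuous-stream residuals are Uniform(0, 1).  The discrete
    bathymetry-contact stream uses a randomised PIT (seeded).  Missing
    streams yield NaN.
    """
    data = records if isinstance(records, lk.StreamData) else lk.pack_records(records, spec)
    logb = lk.emission_table(data, params, spec, core_only=True)
    eta, homogeneous, deltas = lk._prepare_eval(data, params, spec)
    _, pred, _ = lk._forward_filter_kernel(
        logb, eta, homogeneous, deltas, data.seg_starts
    )
    T, N = pred.shape
    allowed = spec.allowed_state_mask()[data.type_code]  # (T, N)
    w = np.where(allowed, pred, 0.0)
    w = w / w.sum(axis=1, keepdims=True)

    out = pd.DataFrame(
        index=np.arange(T),
        columns=["duration", "depth", "prop", "benthic", "salinity"],
        dtype=float,
    )
    # duration: all states, gamma per state
    k, r = gamma_shape_rate(params.duration_mean, params.duration_sd)
    Fdur = sps.gamma.cdf(data.dur[:, None], k[None, :], scale=1.0 / r[None, :])
    out["duration"] = (w * Fdur).sum(axis=1)

    dive = data.type_code == 2
    if dive.any():
        wd = w[dive][:, 2:]
        wd = wd / wd.sum(axis=1, keepdims=True)
        kz, rz = gamma_shape_rate(params.depth_mean, params.depth_sd)
        Fz = sps.gamma.cdf(data.depth[dive, None], kz[None, :], scale=1.0 / rz[None, :])
        out.loc[dive, "depth"] = (wd * Fz).sum(axis=1)
        a, b = beta_ab(params.hunt_mean, params.hunt_precision)
        Fp = sps.beta.cdf(data.prop[dive, None], a[None, :], b[None, :])
        out.loc[dive, "prop"] = (wd * Fp).sum(axis=1)
        sal_ok = dive & ~data.sal_miss
        if sal_ok.any():
            ws = w[sal_ok][:, 2:]
            ws = ws / ws.sum(axis=1, keepdims=True)
            Fs = sps.norm.cdf(
                data.sal[sal_ok, None],
                params.salinity_mean[None, :],
                params.salinity_sd[None, :],
            )
            out.loc[sal_ok, "salinity"] = (ws * Fs).sum(axis=1)
        ben_ok = dive & ~data.benthic_miss
        if ben_ok.any():
            rng = np.random.default_rng(seed)
            wb = w[ben_ok][:, 2:]
            wb = wb / wb.sum(axis=1, keepdims=True)
            y = data.benthic[ben_ok][:, None]
            p = params.benthic_p[None, :]
            F_below = np.where(y > 0.5, 1.0 - p, 0.0)  # F(y-)
            mass = np.where(y > 0.5, p, 1.0 - p)
            u = rng.random(int(ben_ok.sum()))[:, None]
            out.loc[ben_ok, "benthic"] = (wb * (F_below + u * mass)).sum(axis=1)
    if data.index is not None:
        out.index = data.index
    return out


# ---------------------------------------------------------------------------
# posterior predictive check


def posterior_predictive_check(
    fitted, n_sims: int = 100, seed: int = 0, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)
) -> pd.DataFrame:
    """Simulate from the fitted model and compare stream summaries.

    Each replicate simulates a dataset of the observed length from the
    fitted parameters; for every stream summary (mean, sd and quantiles of
    each dive stream, plus the benthic rate) the observed value is compared
    with the central 95% envelope across replicates.
    """
    from .simulate import GeneratingScenario, simulate_sequence

    model = fitted.model
    obs = model.records
    scen = GeneratingScenario(
        spec=fitted.spec,
        params=fitted.params,
        start_time=obs["start_time"].iloc[0]
        if "start_time" in obs
        else pd.Timestamp("2011-02-15T00:00:00Z"),
        lon=float(obs["lon"].iloc[0]) if "lon" in obs else -40.0,
    )
    rng = np.random.default_rng(seed)
    rows = {}

    def summarise(df):
        dive = df[df["record_type"] == "dive"]
        s = {}
        for col, name in (
            ("duration_s", "duration"),
            ("hunting_depth_m", "depth"),
            ("prop_hunting", "prop"),
            ("salinity_psu", "salinity"),
        ):
            x = (df if name == "duration" else dive)[col].dropna().to_numpy()
            s[f"{name}_mean"] = x.mean()
            s[f"{name}_sd"] = x.std()
            for q in quantiles:
                s[f"{name}_q{int(q * 100):02d}"] = np.quantile(x, q)
        s["benthic_rate"] = dive["benthic"].dropna().mean()
        return s

    obs_summary = summarise(obs)
    sims = []
    for b in range(n_sims):
        sim, _ = simulate_sequence(scen, len(obs), int(rng.integers(2**31 - 1)))
        sims.append(summarise(sim))
    sim_df = pd.DataFrame(sims)
    lo = sim_df.quantile(0.025)
    hi = sim_df.quantile(0.975)
    out = pd.DataFrame(
        {
            "observed": pd.Series(obs_summary),
            "sim_lower": lo,
            "sim_upper": hi,
        }
    )
    out["inside"] = (out["observed"] >= out["sim_lower"]) & (
        out["observed"] <= out["sim_upper"]
    )
    return out


# ---------------------------------------------------------------------------
# equilibrium distribution


@dataclass
class EquilibriumCurve:
    """State probabilities over an (hour x week) covariate grid with 95% CIs."""

    hours: np.ndarray  # (H,)
    weeks: np.ndarray  # (W,)
    probs: np.ndarray  # (W, H, N)
    lower: np.ndarray  # (W, H, N), NaN when no covariance available
    upper: np.ndarray
    state_names: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for wi, wk in enumerate(self.weeks):
            for hi, h in enumerate(self.hours):
                for si, name in enumerate(self.state_names):
                    rows.append(
                        {
                            "week": wk,
                            "hour": h,
                            "state": name,
                            "probability": self.probs[wi, hi, si],
                            "lower95": self.lower[wi, hi, si],
                            "upper95": self.upper[wi, hi, si],
                        }
                    )
        return pd.DataFrame(rows)


def equilibrium_distribution(
    fitted,
    hour_grid=None,
    week_grid=(7, 15, 24),
    cov: np.ndarray | None = None,
    rel_step: float = 1e-5,
) -> EquilibriumCurve:
    """Equilibrium state probabilities over a covariate grid, with CIs.

    At each grid point the stationary vector of the transition matrix is
    solved; 95% intervals use the delta method on the probability scale and
    are clipped to [0, 1].  ``fitted`` may be a results object (its
    transition-coefficient covariance is used) or an (params, spec) tuple
    (point estimates only).
    """
    if isinstance(fitted, tuple):
        params, spec = fitted
        tpm_cov = cov
    else:
        params, spec = fitted.params, fitted.spec
        tpm_cov = cov if cov is not None else fitted.tpm_cov()
    hours = np.arange(0.0, 24.0, 0.25) if hour_grid is None else np.asarray(hour_grid, dtype=float)
    weeks = np.asarray(week_grid, dtype=float)
    N = spec.n_states
    H, W = hours.size, weeks.size
    probs = np.empty((W, H, N))
    lower = np.full((W, H, N), np.nan)
    upper = np.full((W, H, N), np.nan)
    B = params.tpm_coefs
    flatB = B.ravel()
    nB = flatB.size

    def delta_at(flat_b, x):
        eta = x @ flat_b.reshape(B.shape).T
        P = transition_matrix_from_logits(eta, N)
        return stationary_distribution(P)

    for wi, wk in enumerate(weeks):
        for hi, h in enumerate(hours):
            x = spec.design_row(h, wk)
            try:
                d = delta_at(flatB, x)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"reducible transition matrix at hour={h}, week={wk}: {err}"
                ) from err
            probs[wi, hi] = d
            if tpm_cov is not None:
                G = np.empty((nB, N))  # d delta / d B_k
                for kk in range(nB):
                    hstep = rel_step * max(1.0, abs(flatB[kk]))
                    bp = flatB.copy()
                    bp[kk] += hstep
                    bm = flatB.copy()
                    bm[kk] -= hstep
                    G[kk] = (delta_at(bp, x) - delta_at(bm, x)) / (2 * hstep)
                var = np.einsum("ki,kl,li->i", G, tpm_cov, G)
                sd = np.sqrt(np.clip(var, 0.0, None))
                lower[wi, hi] = np.clip(d - 1.96 * sd, 0.0, 1.0)
                upper[wi, hi] = np.clip(d + 1.96 * sd, 0.0, 1.0)
    # bounds must bracket the estimate even after clipping
    lower = np.minimum(lower, probs)
    upper = np.maximum(upper, probs)
    return EquilibriumCurve(hours, weeks, probs, lower, upper, spec.state_names)


# ---------------------------------------------------------------------------
# temperature-salinity table


def ts_state_table(records: pd.DataFrame, decoded, spec: HmmSpec) -> pd.DataFrame:
    """Per-dive (temperature, salinity, state) rows for TS-diagram plotting."""
    decoded = np.asarray(decoded)
    df = records.copy().reset_index(drop=True)
    df["state_index"] = decoded
    df["state"] = [spec.state_names[i] for i in decoded]
    dive = df["record_type"] == "dive"
    if "temperature_C" not in df:
        log.warning("no temperature data; TS table is empty")
        return pd.DataFrame(columns=["temperature_C", "salinity_psu", "state"])
    ok = dive & df["temperature_C"].notna() & df["salinity_psu"].notna()
    if not ok.any():
        log.warning("no dives with both temperature and salinity; TS table is empty")
    return df.loc[ok, ["temperature_C", "salinity_psu", "state"]].reset_index(
        drop=True
    )
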