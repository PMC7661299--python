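"""Forward algorithm, emission densities and Viterbi decoding.

The observation unit is one behavioural record (haulout, surface or dive).
Record types constrain the state space: haulout/surface records are pinned to
their known state, dive records may occupy any dive state.  Given the state,
the five data streams are conditionally independent; their joint emission
log-density is the sum of the active streams' terms.  Salinity (and the
bathymetry-contact indicator) may be missing, in which case that stream's
term is omitted from the likelihood.

Because pinned records admit exactly one state, the duration densities of the
two non-diving states factor out of the path sum; the forward recursion here
therefore works with a (T, N) table in which pinned records contribute a unit
emission weight in their own state.  The pinned-state gamma terms are added
back by the model layer (they are maximised separately, which is exact).

The transition probability at step t (from the state of record t-1 to the
state of record t) is the multinomial-logit matrix evaluated at record t's
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import betaln, gammaln

from .params import (
    HmmParams,
    beta_ab,
    gamma_shape_rate,
    stationary_distribution,
    transition_matrix_from_logits,
)
from .spec import RECORD_TYPES, HmmSpec

_LOG2PI = np.log(2.0 * np.pi)
NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# data packing


@dataclass
class StreamData:
    """Numeric arrays for one or more behavioural sequences.

    ``seg_starts`` marks the first record of each individual's sequence;
    the forward recursion restarts its initial distribution there.
    """

    type_code: np.ndarray  # (T,) 0=haulout 1=surface 2=dive
    dur: np.ndarray  # (T,) seconds
    log_dur: np.ndarray
    depth: np.ndarray  # NaN for non-dive
    log_depth: np.ndarray
    prop: np.ndarray
    log_prop: np.ndarray
    log_1mprop: np.ndarray
    benthic: np.ndarray  # 0/1, NaN = missing
    benthic_miss: np.ndarray  # bool
    sal: np.ndarray
    sal_miss: np.ndarray  # bool
    X: np.ndarray  # (T, K) transition design rows
    seg_starts: np.ndarray  # (n_seg,) int
    index: pd.Index | None = None

    @property
    def n_records(self) -> int:
        return self.type_code.size

    @property
    def n_segments(self) -> int:
        return self.seg_starts.size

    def segment_bounds(self) -> list[tuple[int, int]]:
        ends = np.append(self.seg_starts[1:], self.n_records)
        return [(int(s), int(e)) for s, e in zip(self.seg_starts, ends)]


_TYPE_TO_CODE = {t: i for i, t in enumerate(RECORD_TYPES)}


def pack_records(records: pd.DataFrame, spec: HmmSpec) -> StreamData:
    """Turn a tidy records table into the numeric arrays the kernels use.

    Required columns: ``record_type``, ``duration_s``; for dive rows also
    ``hunting_depth_m``, ``prop_hunting``, ``benthic`` and optionally
    ``salinity_psu`` (NaN = missing).  ``local_hour`` and ``week_of_year``
    are required unless the design is intercept-only.  Rows must be
    time-ordered within each individual; an ``individual_id`` column splits
    the table into independent sequences.
    """
    if "record_type" not in records or "duration_s" not in records:
        raise ValueError("records need 'record_type' and 'duration_s' columns")
    T = len(records)
    if T == 0:
        raise ValueError("empty records table")
    type_code = records["record_type"].map(_TYPE_TO_CODE)
    if type_code.isna().any():
        bad = records.loc[type_code.isna(), "record_type"].unique()
        raise ValueError(f"unknown record types: {bad}")
    type_code = type_code.to_numpy(dtype=np.int8)
    dur = records["duration_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(dur)) or np.any(dur <= 0):
        raise ValueError("duration_s must be positive and finite")
    dive = type_code == 2

    def _col(name, default=np.nan):
        if name in records:
            return records[name].to_numpy(dtype=float)
        return np.full(T, default)

    depth = _col("hunting_depth_m")
    prop = _col("prop_hunting")
    benthic = _col("benthic")
    sal = _col("salinity_psu")
    if dive.any():
        if np.any(~np.isfinite(depth[dive])) or np.any(depth[dive] <= 0):
            raise ValueError("dive records need positive hunting_depth_m")
        pd_ = prop[dive]
        if np.any(~np.isfinite(pd_)) or np.any(pd_ <= 0) or np.any(pd_ >= 1):
            raise ValueError("dive prop_hunting must lie strictly in (0, 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_dur = np.log(dur)
        log_depth = np.log(depth)
        log_prop = np.log(prop)
        log_1mprop = np.log1p(-prop)
    sal_miss = ~np.isfinite(sal) | ~dive
    benthic_miss = ~np.isfinite(benthic) | ~dive
    if spec.covariate_design == "intercept":
        X = np.ones((T, 1))
    else:
        if "local_hour" not in records or "week_of_year" not in records:
            raise ValueError(
                "covariate-dependent designs need 'local_hour' and "
                "'week_of_year' columns"
            )
        X = spec.design_row(
            records["local_hour"].to_numpy(dtype=float),
            records["week_of_year"].to_numpy(dtype=float),
        )
    if "individual_id" in records:
        ids = records["individual_id"].to_numpy()
        starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    else:
        starts = np.array([0])
    return StreamData(
        type_code=type_code,
        dur=dur,
        log_dur=log_dur,
        depth=np.nan_to_num(depth),
        log_depth=np.nan_to_num(log_depth),
        prop=np.nan_to_num(prop),
        log_prop=np.nan_to_num(log_prop),
        log_1mprop=np.nan_to_num(log_1mprop),
        benthic=np.nan_to_num(benthic),
        benthic_miss=benthic_miss,
        sal=np.nan_to_num(sal),
        sal_miss=sal_miss,
        X=np.ascontiguousarray(X, dtype=float),
        seg_starts=starts,
        index=records.index,
    )


# ---------------------------------------------------------------------------
# emission log-densities


def _gamma_terms(mean, sd):
    shape, rate = gamma_shape_rate(mean, sd)
    const = shape * np.log(rate) - gammaln(shape)
    return shape, rate, const


def emission_table(
    data: StreamData, params: HmmParams, spec: HmmSpec, *, core_only: bool = True
) -> np.ndarray:
    """(T, N) log emission densities with the known-state mask applied.

    With ``core_only`` (the default used inside the likelihood), pinned
    records get log-weight 0 in their own state — their gamma duration terms
    are handled separately.  With ``core_only=False`` the pinned records'
    duration densities are included, giving the full emission log-density.
    """
    T, N, D = data.n_records, spec.n_states, spec.n_dive_states
    logb = np.full((T, N), NEG_INF)
    dive = data.type_code == 2

    # pinned non-dive records
    for code, state in ((0, 0), (1, 1)):
        rows = data.type_code == code
        if not rows.any():
            continue
        if core_only:
            logb[rows, state] = 0.0
        else:
            k, r, c = _gamma_terms(
                params.duration_mean[state], params.duration_sd[state]
            )
            logb[rows, state] = (
                (k - 1.0) * data.log_dur[rows] - r * data.dur[rows] + c
            )

    if dive.any() and D > 0:
        dm, dsd = params.duration_mean[2:], params.duration_sd[2:]
        kd, rd, cd = _gamma_terms(dm, dsd)  # (D,)
        kz, rz, cz = _gamma_terms(params.depth_mean, params.depth_sd)
        a, b = beta_ab(params.hunt_mean, params.hunt_precision)
        cbeta = -betaln(a, b)
        logp = np.log(params.benthic_p)
        log1mp = np.log1p(-params.benthic_p)
        smu, ssd = params.salinity_mean, params.salinity_sd
        csal = -np.log(ssd) - 0.5 * _LOG2PI

        ld = data.log_dur[dive, None]
        d = data.dur[dive, None]
        lz = data.log_depth[dive, None]
        z = data.depth[dive, None]
        lp = data.log_prop[dive, None]
        l1p = data.log_1mprop[dive, None]
        y = data.benthic[dive, None]
        ymiss = data.benthic_miss[dive, None]
        s = data.sal[dive, None]
        smiss = data.sal_miss[dive, None]

        core = (
            (kd - 1.0) * ld - rd * d + cd
            + (kz - 1.0) * lz - rz * z + cz
            + (a - 1.0) * lp + (b - 1.0) * l1p + cbeta
        )
        bern = np.where(ymiss, 0.0, y * logp + (1.0 - y) * log1mp)
        saln = np.where(smiss, 0.0, -0.5 * ((s - smu) / ssd) ** 2 + csal)
        logb[np.flatnonzero(dive)[:, None], np.arange(2, N)[None, :]] = (
            core + bern + saln
        )
    return logb


def emission_logdensity(
    record: pd.Series | dict, state: int, params: HmmParams, spec: HmmSpec
) -> float:
    """Full emission log-density of one record in one state.

    Returns ``-inf`` when the record type excludes the state (the known-state
    constraint); missing salinity or bathymetry-contact terms are omitted.
    """
    df = pd.DataFrame([dict(record)])
    data = pack_records(df, spec)
    logb = emission_table(data, params, spec, core_only=False)
    return float(logb[0, state])


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _softmax_row(eta_row, N, out):
    """Fill out (N, N) from one off-diagonal logit row (diagonal reference)."""
    r = 0
    for i in range(N):
        m = 0.0
        for j in range(N):
            if i == j:
                continue
            v = eta_row[r + (j if j < i else j - 1)]
            if v > m:
                m = v
        denom = np.exp(-m)
        rr = r
        for j in range(N):
            if i == j:
                continue
            out[i, j] = np.exp(eta_row[rr] - m)
            denom += out[i, j]
            rr += 1
        for j in range(N):
            if i == j:
                out[i, j] = np.exp(-m) / denom
            else:
                out[i, j] = out[i, j] / denom
        r += N - 1


@njit(cache=True)
def _forward_kernel(logb, eta, homogeneous, deltas, seg_starts):
    """Scaled forward recursion; returns total log-likelihood.

    deltas: (n_seg, N) initial distributions per segment.
    Returns -inf if any step has zero total mass.
    """
    T, N = logb.shape
    Gamma = np.empty((N, N))
    if homogeneous:
        _softmax_row(eta[0], N, Gamma)
    phi = np.empty(N)
    new = np.empty(N)
    ll = 0.0
    seg = -1
    for t in range(T):
        new_seg = seg + 1 < seg_starts.size and seg_starts[seg + 1] == t
        if t == 0 or new_seg:
            seg += 1
            for j in range(N):
                new[j] = deltas[seg, j]
        else:
            if not homogeneous:
                _softmax_row(eta[t], N, Gamma)
            for j in range(N):
                acc = 0.0
                for i in range(N):
                    acc += phi[i] * Gamma[i, j]
                new[j] = acc
        m = NEG_INF
        for j in range(N):
            if logb[t, j] > m:
                m = logb[t, j]
        if m == NEG_INF:
            return NEG_INF
        c = 0.0
        for j in range(N):
            phi[j] = new[j] * np.exp(logb[t, j] - m)
            c += phi[j]
        if c <= 0.0 or not np.isfinite(c):
            return NEG_INF
        ll += np.log(c) + m
        for j in range(N):
            phi[j] /= c
    return ll


@njit(cache=True)
def _forward_filter_kernel(logb, eta, homogeneous, deltas, seg_starts):
    """Forward pass also returning one-step-ahead and filtered state probs."""
    T, N = logb.shape
    Gamma = np.empty((N, N))
    if homogeneous:
        _softmax_row(eta[0], N, Gamma)
    pred = np.empty((T, N))
    filt = np.empty((T, N))
    phi = np.empty(N)
    ll = 0.0
    seg = -1
    for t in range(T):
        new_seg = seg + 1 < seg_starts.size and seg_starts[seg + 1] == t
        if t == 0 or new_seg:
            seg += 1
            for j in range(N):
                pred[t, j] = deltas[seg, j]
        else:
            if not homogeneous:
                _softmax_row(eta[t], N, Gamma)
            for j in range(N):
                acc = 0.0
                for i in range(N):
                    acc += phi[i] * Gamma[i, j]
                pred[t, j] = acc
        m = NEG_INF
        for j in range(N):
            if logb[t, j] > m:
                m = logb[t, j]
        c = 0.0
        for j in range(N):
            filt[t, j] = pred[t, j] * np.exp(logb[t, j] - m)
            c += filt[t, j]
        ll += np.log(c) + m
        for j in range(N):
            filt[t, j] /= c
            phi[j] = filt[t, j]
    return ll, pred, filt


@njit(cache=True)
def _viterbi_kernel(logb, eta, homogeneous, log_deltas, seg_starts):
    """Most probable state path; ties broken toward the lower state index."""
    T, N = logb.shape
    Gamma = np.empty((N, N))
    logGamma = np.empty((N, N))
    if homogeneous:
        _softmax_row(eta[0], N, Gamma)
        for i in range(N):
            for j in range(N):
                logGamma[i, j] = np.log(Gamma[i, j])
    score = np.empty((T, N))
    back = np.zeros((T, N), dtype=np.int64)
    seg = -1
    bounds = np.empty((seg_starts.size, 2), dtype=np.int64)
    for t in range(T):
        new_seg = seg + 1 < seg_starts.size and seg_starts[seg + 1] == t
        if t == 0 or new_seg:
            if seg >= 0:
                bounds[seg, 1] = t
            seg += 1
            bounds[seg, 0] = t
            for j in range(N):
                score[t, j] = log_deltas[seg, j] + logb[t, j]
        else:
            if not homogeneous:
                _softmax_row(eta[t], N, Gamma)
                for i in range(N):
                    for j in range(N):
                        logGamma[i, j] = np.log(Gamma[i, j])
            for j in range(N):
                best = NEG_INF
                arg = 0
                for i in range(N):
                    v = score[t - 1, i] + logGamma[i, j]
                    if v > best:  # strict: first (lowest) index wins ties
                        best = v
                        arg = i
                score[t, j] = best + logb[t, j]
                back[t, j] = arg
    bounds[seg, 1] = T
    path = np.empty(T, dtype=np.int64)
    for s in range(seg_starts.size):
        t0, t1 = bounds[s, 0], bounds[s, 1]
        best = NEG_INF
        arg = 0
        for j in range(N):
            if score[t1 - 1, j] > best:
                best = score[t1 - 1, j]
                arg = j
        path[t1 - 1] = arg
        for t in range(t1 - 1, t0, -1):
            path[t - 1] = back[t, path[t]]
    return path


@njit(cache=True)
def _forward_backward_kernel(
    logb, eta, X, homogeneous, deltas, seg_starts,
    type_code, log_dur, dur, log_depth, depth,
    log_prop, log_1mprop, benthic, benthic_miss, sal, sal_miss,
):
    """Scaled forward-backward pass with analytic gradient accumulators.

    Returns (ll, stats, dB, gamma0) where
      stats[d] = posterior-weighted sufficient statistics of dive state d:
        [sum g, sum g*log dur, sum g*dur, sum g*log z, sum g*z,
         sum g*log p, sum g*log(1-p), sum g (benthic obs), sum g*y,
         sum g (sal obs), sum g*s, sum g*s^2]
      dB = d ll / d tpm_coefs, shape (N*(N-1), K)  (transition part only)
      gamma0[seg] = smoothed state probabilities of each segment's first
        record (the initial-distribution term chains through these).
    """
    T, N = logb.shape
    K = X.shape[1]
    D = N - 2
    M = N * (N - 1)
    n_seg = seg_starts.size
    Gamma = np.empty((N, N))
    if homogeneous:
        _softmax_row(eta[0], N, Gamma)

    filt = np.empty((T, N))
    cs = np.empty(T)
    ms = np.empty(T)
    ll = 0.0
    seg = -1
    seg_of = np.empty(T, dtype=np.int64)
    phi = np.empty(N)
    new = np.empty(N)
    for t in range(T):
        new_seg = seg + 1 < n_seg and seg_starts[seg + 1] == t
        if t == 0 or new_seg:
            seg += 1
            for j in range(N):
                new[j] = deltas[seg, j]
        else:
            if not homogeneous:
                _softmax_row(eta[t], N, Gamma)
            for j in range(N):
                acc = 0.0
                for i in range(N):
                    acc += phi[i] * Gamma[i, j]
                new[j] = acc
        seg_of[t] = seg
        m = NEG_INF
        for j in range(N):
            if logb[t, j] > m:
                m = logb[t, j]
        ms[t] = m
        c = 0.0
        for j in range(N):
            phi[j] = new[j] * np.exp(logb[t, j] - m)
            c += phi[j]
        cs[t] = c
        ll += np.log(c) + m
        for j in range(N):
            phi[j] /= c
            filt[t, j] = phi[j]

    stats = np.zeros((D, 12))
    dB = np.zeros((M, K))
    gamma0 = np.zeros((n_seg, N))
    bw = np.empty(N)
    v = np.empty(N)
    gam = np.empty(N)
    xi_row = np.empty(N)
    for t in range(T - 1, -1, -1):
        first = t == seg_starts[seg_of[t]]
        last = t == T - 1 or (seg_of[t + 1] != seg_of[t])
        if last:
            for j in range(N):
                bw[j] = 1.0
        # smoothed probs of record t with current bw = beta_hat_t
        for j in range(N):
            gam[j] = filt[t, j] * bw[j]
        if type_code[t] == 2:
            for d in range(D):
                g = gam[2 + d]
                stats[d, 0] += g
                stats[d, 1] += g * log_dur[t]
                stats[d, 2] += g * dur[t]
                stats[d, 3] += g * log_depth[t]
                stats[d, 4] += g * depth[t]
                stats[d, 5] += g * log_prop[t]
                stats[d, 6] += g * log_1mprop[t]
                if not benthic_miss[t]:
                    stats[d, 7] += g
                    stats[d, 8] += g * benthic[t]
                if not sal_miss[t]:
                    stats[d, 9] += g
                    stats[d, 10] += g * sal[t]
                    stats[d, 11] += g * sal[t] * sal[t]
        if first:
            for j in range(N):
                gamma0[seg_of[t], j] = gam[j]
            continue
        # transition step t-1 -> t and backward update
        if not homogeneous:
            _softmax_row(eta[t], N, Gamma)
        for j in range(N):
            v[j] = np.exp(logb[t, j] - ms[t]) * bw[j]
        cell = 0
        for i in range(N):
            gprev = 0.0
            for j in range(N):
                xi_row[j] = filt[t - 1, i] * Gamma[i, j] * v[j] / cs[t]
                gprev += xi_row[j]
            for j in range(N):
                if i == j:
                    continue
                de = xi_row[j] - gprev * Gamma[i, j]
                for k in range(K):
                    dB[cell, k] += de * X[t, k]
                cell += 1
        for i in range(N):
            acc = 0.0
            for j in range(N):
                acc += Gamma[i, j] * v[j]
            bw[i] = acc / cs[t]
    return ll, stats, dB, gamma0


# ---------------------------------------------------------------------------
# python-level API


def _prepare_eval(data: StreamData, params: HmmParams, spec: HmmSpec):
    homogeneous = spec.covariate_design == "intercept"
    if homogeneous:
        eta = np.ascontiguousarray(params.tpm_coefs[:, 0])[None, :]
    else:
        eta = data.X @ params.tpm_coefs.T  # (T, N(N-1))
        eta = np.ascontiguousarray(eta)
    deltas = np.empty((data.n_segments, spec.n_states))
    for s, start in enumerate(data.seg_starts):
        deltas[s] = initial_distribution(
            params, spec, eta[0] if homogeneous else eta[start]
        )
    return eta, homogeneous, deltas


def initial_distribution(
    params: HmmParams, spec: HmmSpec, eta_row: np.ndarray
) -> np.ndarray:
    """Initial state distribution under the spec's rule."""
    N = spec.n_states
    if spec.initial == "uniform":
        return np.full(N, 1.0 / N)
    if spec.initial == "estimated":
        z = np.concatenate([[0.0], params.init_logits])
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()
    P = transition_matrix_from_logits(eta_row, N)
    return stationary_distribution(P)


def core_loglik_and_grad(
    data: StreamData, params: HmmParams, spec: HmmSpec
) -> tuple[float, np.ndarray]:
    """Core log-likelihood and its analytic gradient on the working scale.

    The gradient covers every working-vector entry; the pinned-state
    duration entries (profiled out of the core likelihood) are zero.  The
    stationary-initial term is chained through the smoothed first-record
    probabilities with a central finite difference on the small
    logits-to-stationary map.
    """
    from scipy.special import psi as _psi

    N, D, K = spec.n_states, spec.n_dive_states, spec.n_design
    M = N * (N - 1)
    logb = emission_table(data, params, spec, core_only=True)
    eta, homogeneous, deltas = _prepare_eval(data, params, spec)
    ll, stats, dB, gamma0 = _forward_backward_kernel(
        logb, eta, data.X, homogeneous, deltas, data.seg_starts,
        data.type_code, data.log_dur, data.dur, data.log_depth, data.depth,
        data.log_prop, data.log_1mprop, data.benthic, data.benthic_miss,
        data.sal, data.sal_miss,
    )
    size = 2 * N + 7 * D + M * K + (N - 1 if spec.initial == "estimated" else 0)
    grad = np.zeros(size)
    o = {
        "dur_mean": 0, "dur_sd": N, "depth_mean": 2 * N, "depth_sd": 2 * N + D,
        "hunt_mean": 2 * N + 2 * D, "hunt_prec": 2 * N + 3 * D,
        "benthic": 2 * N + 4 * D, "sal_mean": 2 * N + 5 * D,
        "sal_sd": 2 * N + 6 * D, "B": 2 * N + 7 * D,
    }
    for d in range(D):
        E0, E1, E2, Ez1, Ez2, Ep, E1p, S0b, Sy, S0s, Ss, Ss2 = stats[d]
        # duration gamma
        m, s = params.duration_mean[2 + d], params.duration_sd[2 + d]
        k, r = gamma_shape_rate(m, s)
        dk = E0 * (np.log(r) - _psi(k)) + E1
        dr = E0 * k / r - E2
        grad[o["dur_mean"] + 2 + d] = 2 * k * dk + r * dr
        grad[o["dur_sd"] + 2 + d] = -2 * k * dk - 2 * r * dr
        # depth gamma
        mz, sz = params.depth_mean[d], params.depth_sd[d]
        kz, rz = gamma_shape_rate(mz, sz)
        dkz = E0 * (np.log(rz) - _psi(kz)) + Ez1
        drz = E0 * kz / rz - Ez2
        grad[o["depth_mean"] + d] = 2 * kz * dkz + rz * drz
        grad[o["depth_sd"] + d] = -2 * kz * dkz - 2 * rz * drz
        # hunting-proportion beta (mean/precision)
        mu, phi = params.hunt_mean[d], params.hunt_precision[d]
        a, b = mu * phi, (1 - mu) * phi
        da = Ep + E0 * (_psi(phi) - _psi(a))
        db = E1p + E0 * (_psi(phi) - _psi(b))
        grad[o["hunt_mean"] + d] = mu * (1 - mu) * phi * (da - db)
        grad[o["hunt_prec"] + d] = phi * (mu * da + (1 - mu) * db)
        # benthic Bernoulli (logit scale)
        grad[o["benthic"] + d] = Sy - S0b * params.benthic_p[d]
        # salinity normal
        smu, ssd = params.salinity_mean[d], params.salinity_sd[d]
        grad[o["sal_mean"] + d] = (Ss - S0s * smu) / ssd**2
        grad[o["sal_sd"] + d] = (Ss2 - 2 * smu * Ss + smu**2 * S0s) / ssd**2 - S0s
    dB_total = dB
    if spec.initial == "stationary":
        # chain d ll / d delta0 through the logits of each segment's first row
        for sidx, start in enumerate(data.seg_starts):
            row = eta[0] if homogeneous else eta[start]
            delta = deltas[sidx]
            gd = np.where(delta > 0, gamma0[sidx] / np.maximum(delta, 1e-300), 0.0)
            deta = np.empty(M)
            for mcell in range(M):
                h = 1e-6 * max(1.0, abs(row[mcell]))
                rp = row.copy(); rp[mcell] += h
                rm = row.copy(); rm[mcell] -= h
                dp = stationary_distribution(transition_matrix_from_logits(rp, N))
                dm = stationary_distribution(transition_matrix_from_logits(rm, N))
                deta[mcell] = gd @ (dp - dm) / (2 * h)
            x = data.X[0] if homogeneous else data.X[start]
            dB_total = dB_total + deta[:, None] * x[None, :]
    elif spec.initial == "estimated":
        off = o["B"] + M * K
        for sidx in range(deltas.shape[0]):
            grad[off : off + N - 1] += gamma0[sidx][1:] - deltas[sidx][1:]
    grad[o["B"] : o["B"] + M * K] = dB_total.ravel()
    return float(ll), grad


def core_loglik(data: StreamData, params: HmmParams, spec: HmmSpec) -> float:
    """Forward log-likelihood excluding the pinned-state duration terms."""
    logb = emission_table(data, params, spec, core_only=True)
    eta, homogeneous, deltas = _prepare_eval(data, params, spec)
    return float(
        _forward_kernel(logb, eta, homogeneous, deltas, data.seg_starts)
    )


def pinned_duration_loglik(
    data: StreamData, params: HmmParams, spec: HmmSpec
) -> float:
    """Gamma log-likelihood of the pinned haulout/surface durations."""
    total = 0.0
    for code, state in ((0, 0), (1, 1)):
        rows = data.type_code == code
        if not rows.any():
            continue
        k, r, c = _gamma_terms(
            params.duration_mean[state], params.duration_sd[state]
        )
        total += float(
            np.sum((k - 1.0) * data.log_dur[rows] - r * data.dur[rows] + c)
        )
    return total


def forward_loglik(
    records: pd.DataFrame | StreamData, params: HmmParams, spec: HmmSpec
) -> float:
    """Full forward log-likelihood of one or more behavioural sequences.

    Multiple individuals (an ``individual_id`` column) contribute
    independent sequences, each restarting the initial distribution; the
    result is the pooled log-likelihood.
    """
    data = records if isinstance(records, StreamData) else pack_records(records, spec)
    logb = emission_table(data, params, spec, core_only=True)
    bad = np.flatnonzero(np.all(np.isinf(logb) & (logb < 0), axis=1))
    if bad.size:
        raise ValueError(
            f"record {bad[0]} has zero emission density in every admissible state"
        )
    eta, homogeneous, deltas = _prepare_eval(data, params, spec)
    core = float(_forward_kernel(logb, eta, homogeneous, deltas, data.seg_starts))
    return core + pinned_duration_loglik(data, params, spec)


def pooled_loglik(
    sequences, params: HmmParams, spec: HmmSpec
) -> float:
    """Sum of forward log-likelihoods over per-individual sequences."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    return float(sum(forward_loglik(s, params, spec) for s in seqs))


def forward_filter(
    records: pd.DataFrame | StreamData, params: HmmParams, spec: HmmSpec
):
    """Log-likelihood plus one-step-ahead and filtered state probabilities."""
    data = records if isinstance(records, StreamData) else pack_records(records, spec)
    logb = emission_table(data, params, spec, core_only=True)
    eta, homogeneous, deltas = _prepare_eval(data, params, spec)
    ll, pred, filt = _forward_filter_kernel(
        logb, eta, homogeneous, deltas, data.seg_starts
    )
    return float(ll) + pinned_duration_loglik(data, params, spec), pred, filt


def viterbi_path(
    records: pd.DataFrame | StreamData, params: HmmParams, spec: HmmSpec
) -> np.ndarray:
    """Jointly most probable state index per record (per individual)."""
    data = records if isinstance(records, StreamData) else pack_records(records, spec)
    logb = emission_table(data, params, spec, core_only=True)
    eta, homogeneous, deltas = _prepare_eval(data, params, spec)
    with np.errstate(divide="ignore"):
        log_deltas = np.log(deltas)
    return np.asarray(
        _viterbi_kernel(logb, eta, homogeneous, log_deltas, data.seg_starts)
    )


def transition_matrix(
    hour, week, params: HmmParams, spec: HmmSpec
) -> np.ndarray:
    """N x N row-stochastic transition matrix at given covariates."""
    x = spec.design_row(hour, week)
    eta = x @ params.tpm_coefs.T
    return transition_matrix_from_logits(eta, spec.n_states)
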