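"""Independent brute-force oracles used by the tests.

Everything here is computed from first principles with scipy/numpy only:
emission densities via scipy.stats, transition probabilities via an explicit
softmax, likelihoods by enumerating every admissible state path.  None of it
reuses the package's recursion code.
"""

import itertools

import numpy as np
from scipy import linalg, stats


def design_row(spec, hour, week):
    c = np.cos(2 * np.pi * hour / 24)
    s = np.sin(2 * np.pi * hour / 24)
    w = (week - spec.week_center) / spec.week_scale
    if spec.covariate_design == "full":
        return np.array([1.0, c, s, w, c * w, s * w])
    if spec.covariate_design == "no_interaction":
        return np.array([1.0, c, s, w])
    return np.array([1.0])


def softmax_tpm(spec, params, hour, week):
    N = spec.n_states
    x = design_row(spec, hour, week)
    eta = params.tpm_coefs @ x
    P = np.zeros((N, N))
    r = 0
    for i in range(N):
        ex = {}
        for j in range(N):
            if i == j:
                continue
            ex[j] = np.exp(eta[r])
            r += 1
        denom = 1.0 + sum(ex.values())
        for j in range(N):
            P[i, j] = (1.0 if i == j else ex[j]) / denom
    return P


def stationary(P):
    vals, vecs = linalg.eig(P.T)
    k = np.argmin(np.abs(vals - 1.0))
    v = np.real(vecs[:, k])
    return v / v.sum()


def emission_logpdf(row, state, params, spec):
    """Full per-record log emission density via scipy.stats."""
    N = spec.n_states
    rtype = row["record_type"]
    allowed = {"haulout": [0], "surface": [1], "dive": list(range(2, N))}[rtype]
    if state not in allowed:
        return -np.inf

    def gamma_lp(x, mean, sd):
        shape = (mean / sd) ** 2
        return stats.gamma.logpdf(x, shape, scale=mean / shape)

    lp = gamma_lp(row["duration_s"], params.duration_mean[state],
                  params.duration_sd[state])
    if state >= 2:
        d = state - 2
        lp += gamma_lp(row["hunting_depth_m"], params.depth_mean[d],
                       params.depth_sd[d])
        a = params.hunt_mean[d] * params.hunt_precision[d]
        b = (1 - params.hunt_mean[d]) * params.hunt_precision[d]
        lp += stats.beta.logpdf(row["prop_hunting"], a, b)
        if np.isfinite(row["benthic"]):
            lp += stats.bernoulli.logpmf(int(row["benthic"]), params.benthic_p[d])
        if np.isfinite(row["salinity_psu"]):
            lp += stats.norm.logpdf(row["salinity_psu"], params.salinity_mean[d],
                                    params.salinity_sd[d])
    return float(lp)


def _path_components(records, params, spec):
    N = spec.n_states
    T = len(records)
    logb = np.array(
        [
            [emission_logpdf(records.iloc[t], j, params, spec) for j in range(N)]
            for t in range(T)
        ]
    )
    tpms = [
        softmax_tpm(spec, params, records.iloc[t]["local_hour"],
                    records.iloc[t]["week_of_year"])
        for t in range(T)
    ]
    if spec.initial == "uniform":
        delta = np.full(N, 1.0 / N)
    elif spec.initial == "estimated":
        z = np.concatenate([[0.0], params.init_logits])
        delta = np.exp(z - z.max())
        delta /= delta.sum()
    else:
        delta = stationary(tpms[0])
    return logb, tpms, delta


def path_logweight(path, logb, tpms, delta):
    lw = np.log(delta[path[0]]) + logb[0, path[0]]
    for t in range(1, len(path)):
        lw += np.log(tpms[t][path[t - 1], path[t]]) + logb[t, path[t]]
    return lw


def brute_force_loglik(records, params, spec):
    """Log-likelihood by summation over every state path."""
    N, T = spec.n_states, len(records)
    logb, tpms, delta = _path_components(records, params, spec)
    weights = [
        path_logweight(p, logb, tpms, delta)
        for p in itertools.product(range(N), repeat=T)
    ]
    weights = np.array(weights)
    m = weights.max()
    return float(m + np.log(np.exp(weights - m).sum()))


def brute_force_viterbi(records, params, spec):
    """Most probable path by exhaustive argmax (first-best on ties)."""
    N, T = spec.n_states, len(records)
    logb, tpms, delta = _path_components(records, params, spec)
    best, best_path = -np.inf, None
    for p in itertools.product(range(N), repeat=T):
        lw = path_logweight(p, logb, tpms, delta)
        if lw > best:
            best = lw
            best_path = p
    return np.array(best_path), best
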