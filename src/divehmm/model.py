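"""Model and results objects for the semi-supervised dive HMM.

:class:`DiveHMM` wraps a prepared behavioural-records table together with an
:class:`~divehmm.spec.HmmSpec`; :meth:`DiveHMM.fit` maximises the pooled
forward log-likelihood by quasi-Newton search on the unconstrained working
scale from multiple starting values, and returns a :class:`DiveHMMResults`
carrying the estimates, their covariance (inverse numeric Hessian of the
negative log-likelihood), information criteria and per-start provenance.

Because haulout and surface records are pinned to their known states, the
gamma duration parameters of those two states factor out of the path sum and
are maximised in closed form (Newton iteration on the gamma shape); the
numerical search runs over the remaining parameters.  The two maximisations
jointly attain the full MLE exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import polygamma, psi

from . import likelihood as lk
from .params import HmmParams
from .spec import HmmSpec

__all__ = ["DiveHMM", "DiveHMMResults", "gamma_mle", "multi_start_initializer"]


def gamma_mle(x: np.ndarray, tol: float = 1e-12, maxiter: int = 100):
    """Maximum-likelihood (mean, sd) of a gamma sample.

    Solves log(k) - psi(k) = log(mean) - mean(log x) by Newton iteration
    (the profile likelihood in the shape k), then sd = mean / sqrt(k).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("gamma_mle needs a non-empty positive sample")
    m = x.mean()
    s = np.log(m) - np.mean(np.log(x))
    if s <= 0:  # degenerate (constant sample): near-infinite shape
        return float(m), float(m * 1e-6)
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(maxiter):
        f = np.log(k) - psi(k) - s
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < tol * k:
            k = k_new
            break
        k = k_new
    return float(m), float(m / np.sqrt(k))


def _moment_start(
    spec: HmmSpec, data: lk.StreamData, rng: np.random.Generator, jitter: float
) -> HmmParams:
    """Moment-based starting values: dive streams binned by depth quantile.

    Dive records are split into as many equal-count bins as there are dive
    states, ordered by hunting depth; each bin's sample moments seed one
    state.  ``jitter`` is the log/logit-scale sd of multiplicative noise
    (0 for the deterministic first start).
    """
    N, D = spec.n_states, spec.n_dive_states
    dive = data.type_code == 2
    dz = data.depth[dive]
    dd = data.dur[dive]
    dp = data.prop[dive]
    dy = np.where(data.benthic_miss[dive], np.nan, data.benthic[dive])
    ds = np.where(data.sal_miss[dive], np.nan, data.sal[dive])
    if dz.size < 4 * D:
        raise ValueError("too few dive records to initialise the dive states")
    order = np.argsort(dz)
    bins = np.array_split(order, D)

    def _clip_sd(v, lo):
        return max(float(v), lo)

    dur_mean = np.empty(N)
    dur_sd = np.empty(N)
    for code, st in ((0, 0), (1, 1)):
        rows = data.type_code == code
        if rows.any():
            dur_mean[st] = data.dur[rows].mean()
            dur_sd[st] = _clip_sd(data.dur[rows].std(), 1.0)
        else:  # type absent: harmless placeholder, profiled out anyway
            dur_mean[st], dur_sd[st] = 3600.0, 1800.0
    depth_mean = np.empty(D)
    depth_sd = np.empty(D)
    hunt_mean = np.empty(D)
    hunt_prec = np.empty(D)
    benthic_p = np.empty(D)
    sal_mean = np.empty(D)
    sal_sd = np.empty(D)
    for k, idx in enumerate(bins):
        depth_mean[k] = dz[idx].mean()
        depth_sd[k] = _clip_sd(dz[idx].std(), 0.05 * depth_mean[k] + 0.5)
        dur_mean[2 + k] = dd[idx].mean()
        dur_sd[2 + k] = _clip_sd(dd[idx].std(), 1.0)
        mu = float(np.clip(dp[idx].mean(), 0.02, 0.98))
        var = float(dp[idx].var())
        hunt_mean[k] = mu
        hunt_prec[k] = np.clip(mu * (1 - mu) / max(var, 1e-6) - 1.0, 2.0, 200.0)
        y = dy[idx]
        y = y[np.isfinite(y)]
        benthic_p[k] = np.clip(y.mean() if y.size else 0.5, 0.02, 0.98)
        s = ds[idx]
        s = s[np.isfinite(s)]
        if s.size:
            sal_mean[k] = s.mean()
            sal_sd[k] = _clip_sd(s.std(), 0.01)
        else:
            sal_mean[k], sal_sd[k] = 34.5, 0.2
    # transition intercepts: moderate persistence (self-transition ~ 0.9)
    eta0 = np.log((0.1 / max(N - 1, 1)) / 0.9)
    B = np.zeros((N * (N - 1), spec.n_design))
    B[:, 0] = eta0
    if jitter > 0:
        z = lambda shape: rng.normal(0.0, jitter, size=shape)  # noqa: E731
        dur_mean = dur_mean * np.exp(z(N))
        dur_sd = dur_sd * np.exp(z(N))
        depth_mean = np.sort(depth_mean * np.exp(z(D)))
        depth_sd = depth_sd * np.exp(z(D))
        hunt_mean = 1 / (1 + np.exp(-(np.log(hunt_mean / (1 - hunt_mean)) + z(D))))
        hunt_prec = hunt_prec * np.exp(z(D))
        benthic_p = 1 / (1 + np.exp(-(np.log(benthic_p / (1 - benthic_p)) + z(D))))
        sal_mean = sal_mean + 0.05 * z(D)
        sal_sd = sal_sd * np.exp(z(D))
        B[:, 0] = B[:, 0] + z(N * (N - 1))
        if spec.n_design > 1:
            B[:, 1:] = 0.1 * z((N * (N - 1), spec.n_design - 1))
    init = np.zeros(N - 1) if spec.initial == "estimated" else None
    return HmmParams(
        duration_mean=dur_mean,
        duration_sd=dur_sd,
        depth_mean=depth_mean,
        depth_sd=depth_sd,
        hunt_mean=hunt_mean,
        hunt_precision=hunt_prec,
        benthic_p=benthic_p,
        salinity_mean=sal_mean,
        salinity_sd=sal_sd,
        tpm_coefs=B,
        init_logits=init,
    )


def multi_start_initializer(
    spec: HmmSpec, data: lk.StreamData, start_id: int, seed: int
) -> np.ndarray:
    """Deterministic working-scale starting vector for one start.

    Start 0 uses the raw depth-quantile moment construction; later starts
    jitter it with reproducible noise.  Depth means are sorted so start
    values are always ordered across dive states.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(start_id)]))
    jitter = 0.0 if start_id == 0 else 0.35
    return _moment_start(spec, data, rng, jitter).to_working()


@dataclass
class _StartResult:
    start_id: int
    converged: bool
    loglik: float
    n_iter: int
    message: str


class DiveHMM:
    """Semi-supervised multivariate HMM for behavioural dive records.

    Parameters
    ----------
    records
        Tidy table with one row per behavioural record, time-ordered within
        individual: columns ``record_type``, ``duration_s``, dive rows also
        ``hunting_depth_m``, ``prop_hunting``, ``benthic``, ``salinity_psu``
        (NaN = missing), and — unless the design is intercept-only —
        ``local_hour`` and ``week_of_year``.
    spec
        Model skeleton (state names, covariate design, initial rule).
    """

    def __init__(self, records: pd.DataFrame, spec: HmmSpec):
        self.records = records.reset_index(drop=True)
        self.spec = spec
        self.data = lk.pack_records(self.records, spec)
        # indices of the pinned-state duration entries in the working vector
        N = spec.n_states
        self._fixed_idx = np.array([0, 1, N, N + 1])
        size = self._working_size()
        self._free_idx = np.setdiff1d(np.arange(size), self._fixed_idx)

    @classmethod
    def from_csv(cls, path, spec: HmmSpec, **read_kwargs) -> "DiveHMM":
        return cls(pd.read_csv(path, **read_kwargs), spec)

    # -- sizes -------------------------------------------------------------
    def _working_size(self) -> int:
        s = self.spec
        n = 2 * s.n_states + 7 * s.n_dive_states + s.n_states * (s.n_states - 1) * s.n_design
        if s.initial == "estimated":
            n += s.n_states - 1
        return n

    @property
    def n_obs(self) -> int:
        return self.data.n_records

    @property
    def k_params(self) -> int:
        return self._working_size()

    # -- likelihood --------------------------------------------------------
    def loglik(self, params: HmmParams) -> float:
        return lk.forward_loglik(self.data, params, self.spec)

    def _core_nll_free(self, w_free: np.ndarray, w_template: np.ndarray) -> float:
        w = w_template.copy()
        w[self._free_idx] = w_free
        params = HmmParams.from_working(w, self.spec)
        ll = lk.core_loglik(self.data, params, self.spec)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def _core_nll_grad_free(self, w_free: np.ndarray, w_template: np.ndarray):
        w = w_template.copy()
        w[self._free_idx] = w_free
        params = HmmParams.from_working(w, self.spec)
        ll, grad = lk.core_loglik_and_grad(self.data, params, self.spec)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(w_free)
        return -ll, -grad[self._free_idx]

    def _pinned_mle(self) -> dict[int, tuple[float, float]]:
        out = {}
        for code, st in ((0, 0), (1, 1)):
            rows = self.data.type_code == code
            if rows.any():
                out[st] = gamma_mle(self.data.dur[rows])
        return out

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        start_params: HmmParams | None = None,
        maxiter: int = 2000,
        ftol: float = 1e-8,
        gtol: float = 1e-5,
        canonical: bool = True,
    ) -> "DiveHMMResults":
        """Maximise the likelihood from ``n_starts`` starting values.

        With ``start_params`` given, that single start is used instead of the
        multi-start schedule.  Dive states of the returned fit are relabelled
        in increasing order of mean hunting depth unless ``canonical=False``.
        """
        spec = self.spec
        pinned = self._pinned_mle()
        starts: list[np.ndarray]
        if start_params is not None:
            starts = [start_params.to_working()]
        else:
            starts = [
                multi_start_initializer(spec, self.data, sid, seed)
                for sid in range(n_starts)
            ]
        results: list[_StartResult] = []
        best = None
        best_w = None
        t0 = time.perf_counter()
        for sid, w0 in enumerate(starts):
            res = minimize(
                self._core_nll_grad_free,
                w0[self._free_idx],
                args=(w0,),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                         "ftol": ftol, "gtol": gtol},
            )
            ll = -res.fun
            results.append(
                _StartResult(sid, bool(res.success), float(ll),
                             int(res.nit), str(res.message))
            )
            if res.success and (best is None or ll > best):
                best = ll
                best_w = w0.copy()
                best_w[self._free_idx] = res.x
        if best is None:
            diag = "; ".join(
                f"start {r.start_id}: {r.message} (ll={r.loglik:.2f})"
                for r in results
            )
            raise RuntimeError(f"no start converged: {diag}")
        params = HmmParams.from_working(best_w, spec)
        # exact closed-form update of the pinned-state duration gammas
        for st, (m, sd) in pinned.items():
            params.duration_mean[st] = m
            params.duration_sd[st] = sd
        if canonical:
            params = params.permute_states(params.canonical_order())
        loglik = lk.forward_loglik(self.data, params, spec)
        return DiveHMMResults(
            model=self,
            params=params,
            loglik=loglik,
            start_results=results,
            seed=seed,
            fit_seconds=time.perf_counter() - t0,
        )

    def simulate(self, params: HmmParams, n_records: int, seed: int, **kw):
        """Simulate a behavioural sequence from given parameters (see
        :func:`divehmm.simulate.simulate_sequence`)."""
        from .simulate import GeneratingScenario, simulate_sequence

        scen = GeneratingScenario(spec=self.spec, params=params, **kw)
        return simulate_sequence(scen, n_records, seed)


@dataclass
class DiveHMMResults:
    """A converged dive-HMM fit.

    Carries natural-scale parameters (dive states in canonical depth order),
    the maximised log-likelihood, information criteria, multi-start
    provenance, and — computed lazily — the covariance of the working
    parameters from the inverse numeric Hessian.
    """

    model: DiveHMM
    params: HmmParams
    loglik: float
    start_results: list
    seed: int
    fit_seconds: float = float("nan")
    _cov: np.ndarray | None = field(default=None, repr=False)
    _cov_failed: bool = field(default=False, repr=False)

    # -- information criteria ---------------------------------------------
    @property
    def spec(self) -> HmmSpec:
        return self.model.spec

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_params * np.log(self.n_obs)

    @property
    def working_params(self) -> np.ndarray:
        return self.params.to_working()

    @property
    def converged_starts(self) -> int:
        return sum(r.converged for r in self.start_results)

    def start_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start_id": r.start_id,
                    "converged": r.converged,
                    "loglik": r.loglik,
                    "n_iter": r.n_iter,
                }
                for r in self.start_results
            ]
        )

    # -- covariance --------------------------------------------------------
    @property
    def cov_params(self) -> np.ndarray | None:
        """Covariance of the working parameters (inverse numeric Hessian).

        ``None`` when the Hessian is not invertible.  Block-diagonal between
        the pinned-state gamma blocks and the jointly-estimated block, which
        is exact because the likelihood factorises there.
        """
        if self._cov is None and not self._cov_failed:
            self._compute_cov()
        return self._cov

    def _compute_cov(self) -> None:
        model = self.model
        w = self.params.to_working()
        n = w.size
        H = np.zeros((n, n))
        free = model._free_idx
        Hfree = _numeric_hessian(
            lambda wf: model._core_nll_free(wf, w), w[free]
        )
        H[np.ix_(free, free)] = Hfree
        for code, st in ((0, 0), (1, 1)):
            rows = model.data.type_code == code
            if not rows.any():
                H[st, st] = H[model.spec.n_states + st, model.spec.n_states + st] = np.inf
                continue
            x = model.data.dur[rows]
            idx = np.array([st, model.spec.n_states + st])

            def nll(v, x=x):
                m, sd = np.exp(v)
                from .params import gamma_shape_rate  # local, tiny

                k, r = gamma_shape_rate(m, sd)
                from scipy.special import gammaln

                return -float(
                    np.sum((k - 1) * np.log(x) - r * x + k * np.log(r) - gammaln(k))
                )

            H[np.ix_(idx, idx)] = _numeric_hessian(nll, w[idx])
        try:
            cov = np.linalg.inv(H)
            cov = 0.5 * (cov + cov.T)
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError("non-finite covariance")
            self._cov = cov
        except np.linalg.LinAlgError:
            self._cov_failed = True
            self._cov = None

    def tpm_cov(self) -> np.ndarray | None:
        """Covariance sub-block of the transition coefficients (flattened)."""
        cov = self.cov_params
        if cov is None:
            return None
        s = self.spec
        off = 2 * s.n_states + 7 * s.n_dive_states
        k = s.n_states * (s.n_states - 1) * s.n_design
        return cov[off : off + k, off : off + k]

    # -- decoding & diagnostics (delegating to inference) ------------------
    def decode(self) -> pd.DataFrame:
        from .inference import decode_states

        return decode_states(self)

    def viterbi(self) -> np.ndarray:
        return lk.viterbi_path(self.model.data, self.params, self.spec)

    def state_occupancy(self, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
        from .inference import state_occupancy

        decoded = self.viterbi()
        ids = (
            self.model.records["individual_id"].to_numpy()
            if "individual_id" in self.model.records
            else np.zeros(self.n_obs, dtype=int)
        )
        return state_occupancy(
            decoded, self.spec, individual_ids=ids, n_boot=n_boot, seed=seed
        )

    def pseudo_residuals(self) -> pd.DataFrame:
        from .inference import pseudo_residuals

        return pseudo_residuals(self.model.records, self.params, self.spec)

    def equilibrium(self, hours=None, weeks=(7, 15, 24)):
        from .inference import equilibrium_distribution

        return equilibrium_distribution(self, hour_grid=hours, week_grid=weeks)

    def posterior_predictive(self, n_sims: int = 100, seed: int = 0):
        from .inference import posterior_predictive_check

        return posterior_predictive_check(self, n_sims=n_sims, seed=seed)

    def simulate(self, n_records: int, seed: int, **kw) -> pd.DataFrame:
        records, _ = self.model.simulate(self.params, n_records, seed, **kw)
        return records

    # -- reporting ---------------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        """Tidy per-state emission-parameter table."""
        s = self.spec
        p = self.params
        rows = []
        for i, name in enumerate(s.state_names):
            row = {
                "state": name,
                "duration_mean_s": p.duration_mean[i],
                "duration_sd_s": p.duration_sd[i],
            }
            if i >= 2:
                d = i - 2
                row.update(
                    hunting_depth_mean_m=p.depth_mean[d],
                    hunting_depth_sd_m=p.depth_sd[d],
                    hunt_prop_mean=p.hunt_mean[d],
                    hunt_prop_precision=p.hunt_precision[d],
                    benthic_p=p.benthic_p[d],
                    salinity_mean_psu=p.salinity_mean[d],
                    salinity_sd_psu=p.salinity_sd[d],
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("state")

    def summary(self) -> str:
        s = self.spec
        lines = [
            "Semi-supervised multivariate dive HMM",
            "=" * 52,
            f"states: {', '.join(s.state_names)}",
            f"records: {self.n_obs}   parameters: {self.k_params}",
            f"log-likelihood: {self.loglik:.3f}",
            f"AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"starts converged: {self.converged_starts}/{len(self.start_results)}",
            "",
            "State-dependent distributions",
            "-" * 52,
            self.params_frame().to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            f"transition design: {s.covariate_design} "
            f"({s.n_design} columns per off-diagonal cell)",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        import json

        d = {
            "spec": {
                "state_names": list(self.spec.state_names),
                "covariate_design": self.spec.covariate_design,
                "initial": self.spec.initial,
            },
            "params": self.params.to_dict(self.spec),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "starts": self.start_table().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with step rel_step * max(1, |x_i|)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H
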