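"""Parameter containers and the working-scale bijection.

Natural-scale parameters live in :class:`HmmParams`.  Optimisation happens on
an unconstrained *working* vector: positive parameters are logged,
probabilities logit-transformed, transition coefficients and normal means kept
raw.  ``params_to_working`` / ``working_to_params`` form an exact bijection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .spec import HmmSpec

_LOGIT_EPS = 1e-12


def _logit(p):
    p = np.clip(np.asarray(p, dtype=float), _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def gamma_shape_rate(mean, sd):
    """(mean, sd) -> (shape, rate) for the gamma family."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape, rate


def beta_ab(mean, precision):
    """(mean, precision) -> (a, b): a = mu*phi, b = (1-mu)*phi."""
    mean = np.asarray(mean, dtype=float)
    precision = np.asarray(precision, dtype=float)
    return mean * precision, (1.0 - mean) * precision


@dataclass
class HmmParams:
    """All estimable parameters of a dive HMM, on the natural scale.

    Emission families per state: behaviour duration is gamma for every state;
    dive states additionally carry a gamma hunting depth, a beta
    hunting-time proportion (mean/precision parameterisation), a Bernoulli
    bathymetry-contact probability, and a normal salinity at hunting depth.

    ``tpm_coefs`` holds the multinomial-logit transition coefficients, one
    row per off-diagonal cell (row-major over (i, j), j != i), one column per
    design-row entry.
    """

    duration_mean: np.ndarray  # (N,) seconds
    duration_sd: np.ndarray  # (N,)
    depth_mean: np.ndarray  # (n_dive,) metres
    depth_sd: np.ndarray
    hunt_mean: np.ndarray  # (n_dive,) in (0,1)
    hunt_precision: np.ndarray  # (n_dive,) > 0
    benthic_p: np.ndarray  # (n_dive,) in (0,1)
    salinity_mean: np.ndarray  # (n_dive,) psu
    salinity_sd: np.ndarray
    tpm_coefs: np.ndarray  # (N*(N-1), K)
    init_logits: np.ndarray | None = None  # (N-1,), only if initial='estimated'

    def __post_init__(self) -> None:
        for name in (
            "duration_mean",
            "duration_sd",
            "depth_mean",
            "depth_sd",
            "hunt_mean",
            "hunt_precision",
            "benthic_p",
            "salinity_mean",
            "salinity_sd",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.tpm_coefs = np.atleast_2d(np.asarray(self.tpm_coefs, dtype=float))
        if self.init_logits is not None:
            self.init_logits = np.asarray(self.init_logits, dtype=float)

    # -- structure ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.duration_mean)

    @property
    def n_dive_states(self) -> int:
        return len(self.depth_mean)

    def validate(self, spec: HmmSpec | None = None) -> None:
        N, D = self.n_states, self.n_dive_states
        if spec is not None:
            if N != spec.n_states or D != spec.n_dive_states:
                raise ValueError("parameter shapes do not match the spec")
            if self.tpm_coefs.shape != (N * (N - 1), spec.n_design):
                raise ValueError(
                    f"tpm_coefs must have shape {(N * (N - 1), spec.n_design)}, "
                    f"got {self.tpm_coefs.shape}"
                )
            if spec.initial == "estimated" and self.init_logits is None:
                raise ValueError("initial='estimated' requires init_logits")
        if N != D + 2:
            raise ValueError("expected exactly two non-dive states")
        for name in ("duration_mean", "duration_sd", "depth_mean", "depth_sd",
                     "hunt_precision", "salinity_sd"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive and finite")
        for name in ("hunt_mean", "benthic_p"):
            v = getattr(self, name)
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if not np.all(np.isfinite(self.salinity_mean)):
            raise ValueError("salinity_mean must be finite")
        if not np.all(np.isfinite(self.tpm_coefs)):
            raise ValueError("tpm_coefs must be finite")

    # -- working-scale bijection ------------------------------------------
    def to_working(self) -> np.ndarray:
        parts = [
            np.log(self.duration_mean),
            np.log(self.duration_sd),
            np.log(self.depth_mean),
            np.log(self.depth_sd),
            _logit(self.hunt_mean),
            np.log(self.hunt_precision),
            _logit(self.benthic_p),
            self.salinity_mean,
            np.log(self.salinity_sd),
            self.tpm_coefs.ravel(),
        ]
        if self.init_logits is not None:
            parts.append(self.init_logits)
        return np.concatenate(parts)

    @classmethod
    def from_working(
        cls, w: np.ndarray, spec: HmmSpec
    ) -> "HmmParams":
        N, D, K = spec.n_states, spec.n_dive_states, spec.n_design
        sizes = [N, N, D, D, D, D, D, D, D, N * (N - 1) * K]
        if spec.initial == "estimated":
            sizes.append(N - 1)
        w = np.asarray(w, dtype=float)
        if w.size != sum(sizes):
            raise ValueError(f"working vector length {w.size} != {sum(sizes)}")
        chunks = np.split(w, np.cumsum(sizes)[:-1])
        return cls(
            duration_mean=np.exp(chunks[0]),
            duration_sd=np.exp(chunks[1]),
            depth_mean=np.exp(chunks[2]),
            depth_sd=np.exp(chunks[3]),
            hunt_mean=_expit(chunks[4]),
            hunt_precision=np.exp(chunks[5]),
            benthic_p=_expit(chunks[6]),
            salinity_mean=chunks[7].copy(),
            salinity_sd=np.exp(chunks[8]),
            tpm_coefs=chunks[9].reshape(N * (N - 1), K),
            init_logits=chunks[10].copy() if spec.initial == "estimated" else None,
        )

    def working_size(self, spec: HmmSpec) -> int:
        return self.to_working().size

    # -- relabelling -------------------------------------------------------
    def permute_states(self, perm: np.ndarray) -> "HmmParams":
        """Relabel states by permutation ``perm`` (new index i <- old perm[i]).

        The two known states must map to themselves.
        """
        perm = np.asarray(perm, dtype=int)
        N = self.n_states
        if perm[0] != 0 or perm[1] != 1:
            raise ValueError("known states cannot be relabelled")
        dive_perm = perm[2:] - 2
        B = coef_matrix_from_rows(self.tpm_coefs, N)  # (N, N, K)
        Bp = B[np.ix_(perm, perm)]
        init = None
        if self.init_logits is not None:
            full = np.concatenate([[0.0], self.init_logits])
            init = (full[perm] - full[perm][0])[1:]
        return replace(
            self,
            duration_mean=self.duration_mean[perm],
            duration_sd=self.duration_sd[perm],
            depth_mean=self.depth_mean[dive_perm],
            depth_sd=self.depth_sd[dive_perm],
            hunt_mean=self.hunt_mean[dive_perm],
            hunt_precision=self.hunt_precision[dive_perm],
            benthic_p=self.benthic_p[dive_perm],
            salinity_mean=self.salinity_mean[dive_perm],
            salinity_sd=self.salinity_sd[dive_perm],
            tpm_coefs=coef_rows_from_matrix(Bp),
            init_logits=init,
        )

    def canonical_order(self) -> np.ndarray:
        """Permutation putting dive states in increasing mean hunting depth."""
        order = np.argsort(self.depth_mean, kind="stable")
        return np.concatenate([[0, 1], order + 2])

    # -- serialisation -----------------------------------------------------
    def to_dict(self, spec: HmmSpec | None = None) -> dict:
        names = list(spec.state_names) if spec is not None else None
        out = {
            "state_names": names,
            "duration": {"mean_s": self.duration_mean.tolist(),
                         "sd_s": self.duration_sd.tolist()},
            "hunting_depth": {"mean_m": self.depth_mean.tolist(),
                              "sd_m": self.depth_sd.tolist()},
            "hunting_proportion": {"mean": self.hunt_mean.tolist(),
                                   "precision": self.hunt_precision.tolist()},
            "benthic_probability": self.benthic_p.tolist(),
            "salinity": {"mean_psu": self.salinity_mean.tolist(),
                         "sd_psu": self.salinity_sd.tolist()},
            "transition_coefficients": self.tpm_coefs.tolist(),
        }
        if self.init_logits is not None:
            out["initial_logits"] = self.init_logits.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        return cls(
            duration_mean=d["duration"]["mean_s"],
            duration_sd=d["duration"]["sd_s"],
            depth_mean=d["hunting_depth"]["mean_m"],
            depth_sd=d["hunting_depth"]["sd_m"],
            hunt_mean=d["hunting_proportion"]["mean"],
            hunt_precision=d["hunting_proportion"]["precision"],
            benthic_p=d["benthic_probability"],
            salinity_mean=d["salinity"]["mean_psu"],
            salinity_sd=d["salinity"]["sd_psu"],
            tpm_coefs=d["transition_coefficients"],
            init_logits=d.get("initial_logits"),
        )

    def to_yaml(self, path, spec: HmmSpec | None = None) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(spec), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "HmmParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path, spec: HmmSpec | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(spec), fh, indent=1)


# ---------------------------------------------------------------------------
# transition-coefficient helpers


def coef_matrix_from_rows(rows: np.ndarray, n_states: int) -> np.ndarray:
    """(N*(N-1), K) row-major off-diagonal layout -> (N, N, K) with zero diag."""
    rows = np.atleast_2d(rows)
    K = rows.shape[1]
    out = np.zeros((n_states, n_states, K))
    r = 0
    for i in range(n_states):
        for j in range(n_states):
            if i == j:
                continue
            out[i, j] = rows[r]
            r += 1
    return out


def coef_rows_from_matrix(mat: np.ndarray) -> np.ndarray:
    N = mat.shape[0]
    rows = [mat[i, j] for i in range(N) for j in range(N) if i != j]
    return np.array(rows)


def coefs_from_matrix(P: np.ndarray) -> np.ndarray:
    """Intercept-only coefficients reproducing a fixed row-stochastic matrix.

    eta_ij = log(P_ij / P_ii) is exact for the diagonal-reference multinomial
    logit; use with an 'intercept' covariate design.
    """
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    if P.shape != (N, N):
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("rows of the transition matrix must sum to 1")
    if np.any(np.diag(P) <= 0):
        raise ValueError("diagonal-reference logit needs P_ii > 0")
    rows = []
    for i in range(N):
        for j in range(N):
            if i != j:
                # a zero cell maps to the most negative finite logit
                rows.append([np.log(max(P[i, j], 1e-300) / P[i, i])])
    return np.array(rows)


def transition_matrix_from_logits(eta: np.ndarray, n_states: int) -> np.ndarray:
    """Row-stochastic matrix/matrices from off-diagonal logits.

    ``eta`` has shape (N*(N-1),) or (T, N*(N-1)); returns (N, N) or (T, N, N).
    Diagonal is the reference category: P_ii = 1 / (1 + sum_j exp(eta_ij)).
    """
    eta = np.asarray(eta, dtype=float)
    single = eta.ndim == 1
    eta = np.atleast_2d(eta)
    if not np.all(np.isfinite(eta)):
        bad = np.argwhere(~np.isfinite(eta))
        raise FloatingPointError(
            f"non-finite transition logit at (record, cell) {tuple(bad[0])}"
        )
    T = eta.shape[0]
    N = n_states
    full = np.zeros((T, N, N))
    r = 0
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            full[:, i, j] = eta[:, r]
            r += 1
    m = np.maximum(full.max(axis=2), 0.0)  # (T, N)
    ex = np.exp(full - m[:, :, None])
    diag = np.exp(-m)  # exp(0 - m)
    idx = np.arange(N)
    ex[:, idx, idx] = diag
    P = ex / ex.sum(axis=2, keepdims=True)
    return P[0] if single else P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution delta with delta P = delta, sum(delta) = 1."""
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    A = np.vstack([P.T - np.eye(N), np.ones(N)])
    b = np.zeros(N + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(delta < -1e-8):
        raise np.linalg.LinAlgError("transition matrix appears reducible")
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


def persistence_matrix(occupancy: np.ndarray, self_prob: float = 0.8) -> np.ndarray:
    """Homogeneous matrix with fixed self-transition probability.

    Off-diagonal mass (1 - self_prob) in each row is spread proportionally to
    the target occupancy of the destination states, giving realistic
    persistence with long-run occupancy close to ``occupancy``.
    """
    pi = np.asarray(occupancy, dtype=float)
    pi = pi / pi.sum()
    N = len(pi)
    P = np.zeros((N, N))
    for i in range(N):
        w = pi.copy()
        w[i] = 0.0
        P[i] = (1.0 - self_prob) * w / w.sum()
        P[i, i] = self_prob
    return P
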