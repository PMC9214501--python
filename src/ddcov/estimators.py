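"""Connectivity estimators: covariance family, differential covariance, and
dynamical differential covariance (DDC).

Every estimator maps a recording to a square matrix whose entry ``(i, j)``
encodes the influence of node j on node i (row = target, column = source).

The covariance family (Cov, P, L1/L2-regularized P) is symmetric and blind to
direction. Differential covariance Δc = <dx/dt, x> and its partialled version
Δp are directed second-order statistics. The DDC family reads the estimate
off an assumed dynamical system: if dx/dt = W R(x), then time-averaging the
outer product with the state gives <dx/dt, x> = W <R(x), x>, so

    ΔR = <dx/dt, x> <R(x), x>^{-1}

is the least-squares estimate of W (ΔL for R = identity). A leaky variant ΔD
handles τ dx/dt = −x + W R(x).

Derivative/state pairing
------------------------
The derivative is the symmetric difference quotient at time t. For Δc/Δp the
companion state sample is the one at the same t (the stencil center). The DDC
estimators instead pair the derivative with the state one step earlier (the
trailing stencil edge): for stochastic dynamics the backward noise increment
inside the stencil is part of x_t, and pairing with x_t would correlate noise
and regressor, biasing the least-squares solution by Q P^{-1}/2 — an O(1)
distortion that does not vanish with more data. The trailing state predates
every increment in the stencil, restoring the unbiasedness that holds for the
exact equations; on smooth data the shift costs only O(dt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .timeseries import (
    SpikeTrains,
    TimeSeries,
    interior,
    numerical_derivative,
    time_average_outer,
    trailing,
    zscore,
)

__all__ = [
    "ConnectivityEstimate",
    "ResponseFunction",
    "ESTIMATOR_NAMES",
    "cov_estimator",
    "precision_estimator",
    "regularized_precision",
    "delta_c",
    "delta_p",
    "ddc_linear",
    "ddc_linear_from_arrays",
    "ddc_linear_segmented",
    "ddc_nonlinear",
    "ddc_nonlinear_from_arrays",
    "ddc_leaky",
    "ddc_leaky_from_arrays",
    "relu_threshold_scan",
    "cspk",
    "get_estimator",
    "write_estimate",
    "read_estimate",
]

ESTIMATOR_NAMES = (
    "Cov", "P", "L1reg", "L2reg", "Dc", "Dp",
    "DDC_L", "DDC_R", "DDC_ReLU", "DDC_D", "Cspk",
)


@dataclass(frozen=True)
class ConnectivityEstimate:
    """Square estimate matrix; entry (i, j) is the influence j -> i."""

    matrix: np.ndarray
    estimator: str
    params: dict = field(default_factory=dict)
    node_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError(f"estimate must be square, got shape {M.shape}")
        object.__setattr__(self, "matrix", M)
        if not self.node_ids:
            object.__setattr__(
                self, "node_ids", tuple(f"n{i}" for i in range(M.shape[0])))

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ResponseFunction:
    """Elementwise monotone response R(x) used by the nonlinear estimators.

    kinds: ``identity``; ``relu`` — max(x, θ); ``sigmoid`` — the centered
    logistic 1/(1+e^{−αx}) − 1/2; ``custom`` — a user callable.
    """

    kind: str = "identity"
    theta: float = 0.0
    alpha: float = 1.0
    fn: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "identity":
            return np.asarray(x, float)
        if self.kind == "relu":
            return np.maximum(x, self.theta)
        if self.kind == "sigmoid":
            return 1.0 / (1.0 + np.exp(-self.alpha * np.asarray(x, float))) - 0.5
        if self.kind == "custom":
            if self.fn is None:
                raise ValueError("custom ResponseFunction needs fn")
            return self.fn(np.asarray(x, float))
        raise ValueError(f"unknown response kind {self.kind!r}")


# ---------------------------------------------------------------------------
# linear-algebra helpers
# ---------------------------------------------------------------------------

_COND_CAP = 1e12


def _right_divide(A: np.ndarray, B: np.ndarray, pseudoinverse: bool,
                  what: str) -> np.ndarray:
    """A @ B^{-1}, by direct solve unless the pseudoinverse is requested."""
    if pseudoinverse:
        return A @ np.linalg.pinv(B)
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > _COND_CAP:
        raise np.linalg.LinAlgError(
            f"{what} is rank deficient or ill-conditioned (cond={cond:.2e}); "
            "its inverse is not unique — opt in to the Moore-Penrose "
            "pseudoinverse with pseudoinverse=True"
        )
    return np.linalg.solve(B.T, A.T).T


def _prep(ts: TimeSeries, standardize: bool) -> TimeSeries:
    return zscore(ts) if standardize else ts


# ---------------------------------------------------------------------------
# covariance family
# ---------------------------------------------------------------------------

def cov_estimator(ts: TimeSeries, standardize: bool = True) -> ConnectivityEstimate:
    """Sample covariance <x, x> of the z-scored recording (i.e. correlation)."""
    z = _prep(ts, standardize)
    C = time_average_outer(z, z)
    C = (C + C.T) / 2.0
    return ConnectivityEstimate(C, "Cov", {"standardize": standardize}, ts.node_ids)


def precision_estimator(ts: TimeSeries, pseudoinverse: bool = False,
                        standardize: bool = True) -> ConnectivityEstimate:
    """Partial covariance P = Cov^{-1}."""
    C = cov_estimator(ts, standardize).matrix
    P = _right_divide(np.eye(C.shape[0]), C, pseudoinverse, "covariance matrix")
    P = (P + P.T) / 2.0
    return ConnectivityEstimate(P, "P", {"pseudoinverse": pseudoinverse}, ts.node_ids)


def regularized_precision(ts: TimeSeries, penalty: str, lam: float,
                          max_iter: int = 200) -> ConnectivityEstimate:
    """Penalized inverse-covariance estimate.

    ``L1`` solves the graphical-lasso objective (penalized Gaussian maximum
    likelihood with an L1 penalty of weight λ on the off-diagonal precision
    entries); ``L2`` inverts the ridge-shrunk covariance (Cov + λI) and, for
    λ > 0, rescales the result to a unit diagonal. λ = 0 reduces to the plain
    precision matrix for both penalties.
    """
    if lam < 0:
        raise ValueError("penalty weight lambda must be nonnegative")
    if penalty not in ("L1", "L2"):
        raise ValueError(f"penalty must be 'L1' or 'L2', got {penalty!r}")
    name = "L1reg" if penalty == "L1" else "L2reg"
    if lam == 0:
        P = precision_estimator(ts).matrix
        return ConnectivityEstimate(P, name, {"lambda": 0.0}, ts.node_ids)
    C = cov_estimator(ts).matrix
    if penalty == "L1":
        from sklearn.covariance import graphical_lasso

        _, P = graphical_lasso(C, alpha=lam, max_iter=max_iter)
    else:
        P = np.linalg.inv(C + lam * np.eye(C.shape[0]))
        d = np.sqrt(np.diag(P))
        P = P / np.outer(d, d)
    P = (P + P.T) / 2.0
    return ConnectivityEstimate(P, name, {"lambda": lam}, ts.node_ids)


# ---------------------------------------------------------------------------
# differential covariance
# ---------------------------------------------------------------------------

def delta_c(ts: TimeSeries, standardize: bool = True) -> ConnectivityEstimate:
    """Differential covariance Δc = <dx/dt, x> on aligned interior samples."""
    z = _prep(ts, standardize)
    dC = time_average_outer(numerical_derivative(z), interior(z))
    return ConnectivityEstimate(dC, "Dc", {"standardize": standardize}, ts.node_ids)


def delta_p(ts: TimeSeries, standardize: bool = True) -> ConnectivityEstimate:
    """Partial differential covariance.

    Elementwise for i ≠ j: Δp_ij = Δc_ij − Cov_jK Cov_KK^{-1} Δc_iK^T with K
    all nodes except i and j; the diagonal is copied from Δc.
    """
    z = _prep(ts, standardize)
    dc = delta_c(z, standardize=False).matrix
    C = cov_estimator(z, standardize=False).matrix
    n = ts.n_nodes
    dp = dc.copy()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            K = [k for k in range(n) if k != i and k != j]
            if not K:
                continue  # 2-node system: empty conditioning set, Δp = Δc
            CKK = C[np.ix_(K, K)]
            try:
                w = np.linalg.solve(CKK, dc[i, K])
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"conditioning covariance Cov_KK is singular for pair "
                    f"(i={ts.node_ids[i]}, j={ts.node_ids[j]})"
                ) from None
            dp[i, j] = dc[i, j] - C[j, K] @ w
    return ConnectivityEstimate(dp, "Dp", {"standardize": standardize}, ts.node_ids)


# ---------------------------------------------------------------------------
# DDC family
# ---------------------------------------------------------------------------

def _ddc_arrays(ts: TimeSeries, standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    """(derivative, trailing state) sample arrays for the DDC estimators."""
    z = _prep(ts, standardize)
    return numerical_derivative(z).values, trailing(z).values


def ddc_linear_from_arrays(dx: np.ndarray, x: np.ndarray,
                           pseudoinverse: bool = False) -> np.ndarray:
    """ΔL = <dx/dt, x><x, x>^{-1} from raw, already-paired sample arrays.

    This is the least-squares solution of (dx/dt)_t = W x_t: identical to a
    row-wise ordinary regression of each derivative node on all state nodes.
    """
    A = time_average_outer(dx, x)
    B = time_average_outer(x, x)
    return _right_divide(A, B, pseudoinverse, "state covariance <x,x>")


def ddc_linear(ts: TimeSeries, pseudoinverse: bool = False,
               standardize: bool = True) -> ConnectivityEstimate:
    """Linear DDC estimator ΔL."""
    dx, x = _ddc_arrays(ts, standardize)
    W = ddc_linear_from_arrays(dx, x, pseudoinverse)
    return ConnectivityEstimate(W, "DDC_L", {"pseudoinverse": pseudoinverse},
                                ts.node_ids)


def ddc_linear_segmented(segments: Sequence[TimeSeries], pseudoinverse: bool = False,
                         standardize: bool = True) -> ConnectivityEstimate:
    """ΔL pooled over contiguous segments (cross-products never span a gap).

    Standardization statistics are taken over the concatenation of all
    segments so every segment lives on a common scale.
    """
    segs = [s for s in segments if s.n_time >= 3]
    if not segs:
        raise ValueError("no segment long enough for a derivative (need >= 3 samples)")
    if standardize:
        pooled = np.concatenate([s.values for s in segs], axis=1)
        mean = pooled.mean(axis=1, keepdims=True)
        sd = pooled.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance node across pooled segments")
        segs = [s.with_values((s.values - mean) / sd) for s in segs]
    n = segs[0].n_nodes
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    total = 0
    for s in segs:
        dx = numerical_derivative(s).values
        x = trailing(s).values
        A += dx @ x.T
        B += x @ x.T
        total += x.shape[1]
    W = _right_divide(A / total, B / total, pseudoinverse, "state covariance <x,x>")
    return ConnectivityEstimate(W, "DDC_L", {"segments": len(segs)},
                                segs[0].node_ids)


def ddc_nonlinear_from_arrays(dx: np.ndarray, x: np.ndarray, Rx: np.ndarray,
                              pseudoinverse: bool = False,
                              center_response: bool = True) -> np.ndarray:
    """ΔR = <dx/dt, x><R(x), x>^{-1} from raw, already-paired arrays."""
    if center_response:
        Rx = Rx - Rx.mean(axis=1, keepdims=True)
    A = time_average_outer(dx, x)
    B = time_average_outer(Rx, x)
    try:
        return _right_divide(A, B, pseudoinverse, "<R(x),x>")
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "<R(x),x> was rank deficient and thus noninvertible; consider the "
            "pseudoinverse option or a different response threshold"
        ) from None


def ddc_nonlinear(ts: TimeSeries, R: ResponseFunction,
                  pseudoinverse: bool = False,
                  standardize: bool = True,
                  center_response: bool = True) -> ConnectivityEstimate:
    """Nonlinear DDC estimator ΔR for an elementwise response R.

    R is applied to the z-scored state; R(x) is mean-centered over time before
    the outer product so that constant shifts of the response are irrelevant.
    """
    dx, x = _ddc_arrays(ts, standardize)
    W = ddc_nonlinear_from_arrays(dx, x, R(x), pseudoinverse, center_response)
    name = "DDC_ReLU" if R.kind == "relu" else "DDC_R"
    params = {"kind": R.kind, "theta": R.theta, "alpha": R.alpha}
    return ConnectivityEstimate(W, name, params, ts.node_ids)


def ddc_leaky_from_arrays(dx: np.ndarray, x: np.ndarray, Rx: np.ndarray,
                          tau: float, pseudoinverse: bool = False,
                          center_response: bool = True) -> np.ndarray:
    """ΔD = (τ <dx/dt, x> + <x, x>) <R(x), x>^{-1} from raw paired arrays."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if center_response:
        Rx = Rx - Rx.mean(axis=1, keepdims=True)
    A = tau * time_average_outer(dx, x) + time_average_outer(x, x)
    B = time_average_outer(Rx, x)
    return _right_divide(A, B, pseudoinverse, "<R(x),x>")


def ddc_leaky(ts: TimeSeries, R: ResponseFunction, tau: float,
              pseudoinverse: bool = False, standardize: bool = True,
              center_response: bool = True) -> ConnectivityEstimate:
    """Leaky DDC estimator ΔD for systems τ dx/dt = −x + W R(x)."""
    dx, x = _ddc_arrays(ts, standardize)
    W = ddc_leaky_from_arrays(dx, x, R(x), tau, pseudoinverse, center_response)
    return ConnectivityEstimate(W, "DDC_D", {"tau": tau, "kind": R.kind},
                                ts.node_ids)


def relu_threshold_scan(ts: TimeSeries, truth, criterion: str = "error",
                        n_grid: int = 19, pseudoinverse: bool = False,
                        lower_triangle_only: bool = False):
    """Select the ReLU threshold θ on a percentile grid of the z-scored data.

    θ candidates are the 5th…95th percentiles of the pooled z-scored samples
    (``n_grid`` evenly spaced percentile steps). The best θ minimizes the
    normalized estimation error against ``truth`` (criterion ``'error'``) or
    maximizes the ROC AUC against the binarized truth (``'auc'``); ties break
    toward smaller θ. Returns ``(theta, ConnectivityEstimate)``.
    """
    from .evaluate import normalized_error, roc_auc  # local import, avoids cycle

    if criterion not in ("error", "auc"):
        raise ValueError("criterion must be 'error' or 'auc'")
    if truth is None:
        raise ValueError(f"criterion {criterion!r} requires a ground-truth graph")
    W_true = truth.W if hasattr(truth, "W") else np.asarray(truth, float)
    z = zscore(ts)
    pct = np.linspace(5.0, 95.0, n_grid)
    thetas = np.percentile(z.values, pct)
    best = None
    for theta in thetas:
        est = ddc_nonlinear(z, ResponseFunction("relu", theta=float(theta)),
                            pseudoinverse=pseudoinverse, standardize=False)
        if criterion == "error":
            score = normalized_error(est.matrix, W_true,
                                     lower_triangle_only=lower_triangle_only)
        else:
            score = -roc_auc(est.matrix, (W_true != 0).astype(int)).auc
        if best is None or score < best[0] - 1e-12:
            best = (score, float(theta), est)
    _, theta, est = best
    return theta, est


# ---------------------------------------------------------------------------
# spike-train cross-correlogram
# ---------------------------------------------------------------------------

def cspk(spikes: SpikeTrains, dt: float = 5e-4, tau_window: float = 0.1,
         min_rate: float = 0.1) -> ConnectivityEstimate:
    """Spike-train cross-correlogram connectivity.

    Spike trains are binned at ``dt`` and mean-centered; the Pearson-scaled
    cross-correlogram g_ij(t) is averaged over the causal window
    t ∈ [−τ, 0], so Cspk(i, j) integrates the correlation of i's present with
    j's recent past — influence j -> i. Pairs involving a neuron firing below
    ``min_rate`` Hz are set to zero.
    """
    if tau_window <= 0:
        raise ValueError("tau_window must be positive")
    n = spikes.n_neurons
    n_bins = int(round(spikes.duration / dt))
    binned = np.zeros((n, n_bins))
    for i, train in enumerate(spikes.spike_times):
        idx = np.minimum((train / dt).astype(int), n_bins - 1)
        np.add.at(binned[i], idx, 1.0)
    rates = spikes.rates()
    ok = rates >= min_rate
    centered = binned - binned.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    L = int(round(tau_window / dt))
    M = np.zeros((n, n))
    for i in range(n):
        if not ok[i]:
            continue
        for j in range(n):
            if i == j or not ok[j]:
                continue
            acc = 0.0
            # g_ij(-s) = sum_t x_i(t) x_j(t-s), s = 0..L  (j's past vs i's present)
            for s in range(L + 1):
                if s == 0:
                    acc += float(centered[i] @ centered[j])
                else:
                    acc += float(centered[i, s:] @ centered[j, :-s])
            denom = n_bins * sd[i] * sd[j]
            if denom > 0:
                M[i, j] = acc * dt / (tau_window * denom)
    return ConnectivityEstimate(M, "Cspk", {"dt": dt, "tau_window": tau_window,
                                            "min_rate": min_rate})


# ---------------------------------------------------------------------------
# registry and estimate I/O
# ---------------------------------------------------------------------------

def get_estimator(name: str, **params) -> Callable[[TimeSeries], ConnectivityEstimate]:
    """Resolve an estimator name into a ``TimeSeries -> ConnectivityEstimate``
    callable with the given parameters bound."""
    def _relu(ts):
        theta = params.get("theta")
        if theta is None:
            raise ValueError(
                "DDC_ReLU needs an explicit theta, or run relu_threshold_scan "
                "against a ground-truth graph to select one"
            )
        return ddc_nonlinear(ts, ResponseFunction("relu", theta=theta),
                             pseudoinverse=params.get("pseudoinverse", False))

    table: dict[str, Callable[[TimeSeries], ConnectivityEstimate]] = {
        "Cov": lambda ts: cov_estimator(ts),
        "P": lambda ts: precision_estimator(ts, params.get("pseudoinverse", False)),
        "L1reg": lambda ts: regularized_precision(ts, "L1", params.get("lam", 0.1)),
        "L2reg": lambda ts: regularized_precision(ts, "L2", params.get("lam", 0.1)),
        "Dc": lambda ts: delta_c(ts),
        "Dp": lambda ts: delta_p(ts),
        "DDC_L": lambda ts: ddc_linear(ts, params.get("pseudoinverse", False)),
        "DDC_R": lambda ts: ddc_nonlinear(
            ts, ResponseFunction(params.get("kind", "sigmoid"),
                                 theta=params.get("theta", 0.0),
                                 alpha=params.get("alpha", 1.0)),
            params.get("pseudoinverse", False)),
        "DDC_ReLU": _relu,
        "DDC_D": lambda ts: ddc_leaky(
            ts, ResponseFunction(params.get("kind", "relu"),
                                 theta=params.get("theta", 0.0)),
            tau=params.get("tau", 1.0),
            pseudoinverse=params.get("pseudoinverse", False)),
    }
    if name not in table:
        raise ValueError(
            f"unknown estimator {name!r}; valid names: {', '.join(ESTIMATOR_NAMES)}"
        )
    return table[name]


def write_estimate(est: ConnectivityEstimate, path: str | Path) -> None:
    """Write the matrix as CSV with node-id headers plus a JSON sidecar of the
    estimator name and parameters."""
    import json

    path = Path(path)
    lines = ["," + ",".join(est.node_ids)]
    for node_id, row in zip(est.node_ids, est.matrix):
        lines.append(node_id + "," + ",".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"estimator": est.estimator,
         "params": {k: v for k, v in est.params.items()
                    if isinstance(v, (int, float, str, bool))}},
        indent=2), encoding="utf-8")


def read_estimate(path: str | Path) -> ConnectivityEstimate:
    import json

    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    header = lines[0].split(",")[1:]
    rows = []
    ids = []
    for ln in lines[1:]:
        fields = ln.split(",")
        ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    sidecar = path.with_suffix(path.suffix + ".json")
    estimator, params = "unknown", {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        estimator = meta.get("estimator", estimator)
        params = meta.get("params", {})
    if header != ids:
        warnings.warn("row and column labels differ; using row labels")
    return ConnectivityEstimate(np.array(rows), estimator, params, tuple(ids))
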