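"""Ground-truth networks and the dynamical models used to validate estimators.

Six generative models, all integrated with fixed-step Euler (Euler–Maruyama
for the stochastic ones), matching the simplest scheme a practitioner would
use at the stated step sizes:

* a linear stochastic network dx/dt = W x + D u (Ornstein–Uhlenbeck),
* a sigmoid-coupled stochastic network dx/dt = W R(x) + u,
* the Rössler chaotic oscillator,
* a two-state system with a mid-run switch of the noise structure,
* a network of leaky integrate-and-fire neurons with double-exponential
  synapses,
* a reduced Wong–Wang (dynamic mean-field) model of regional brain activity.

All stochastic simulators are deterministic given (config, seed). The
analytic steady-state covariance of the linear models is available through
:func:`lyapunov_steady_cov`, the law-of-large-numbers bridge used throughout
the test-suite as an oracle for the sample covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .timeseries import SpikeTrains, TimeSeries

try:  # optional JIT acceleration for the integration loops
    from numba import njit
except ImportError:  # pragma: no cover - numba is normally available
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco

__all__ = [
    "NetworkGraph",
    "LinearSimConfig",
    "SigmoidSimConfig",
    "RosslerConfig",
    "TwoStateConfig",
    "LIFConfig",
    "WongWangConfig",
    "motif_graph",
    "er_graph",
    "degree_preserving_randomize",
    "lyapunov_steady_cov",
    "simulate_linear",
    "simulate_sigmoid",
    "simulate_rossler",
    "simulate_two_state",
    "simulate_lif",
    "simulate_wong_wang",
    "split_active_quiet",
    "ActivityPartition",
    "wong_wang_transfer",
    "wong_wang_dmri_preset",
    "TWO_STATE_D2",
]

_DIVERGENCE_LIMIT = 1e6

#: Correlated noise-mixing matrix of the second state of the two-state system.
TWO_STATE_D2 = np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])


# ---------------------------------------------------------------------------
# ground-truth graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkGraph:
    """Directed weighted ground truth; entry ``W[i, j]`` is the weight of j -> i."""

    W: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got shape {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValueError("W contains non-finite entries")
        object.__setattr__(self, "W", W)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def binary(self, include_diagonal: bool = False) -> np.ndarray:
        """0/1 adjacency of the off-diagonal (optionally full) support."""
        B = (self.W != 0).astype(int)
        if not include_diagonal:
            np.fill_diagonal(B, 0)
        return B


def motif_graph(kind: str, strength: float = -0.5) -> NetworkGraph:
    """Three-node chain (1->2->3) or confounder (1->2, 1->3) motif.

    Diagonal entries are −1 (leaky self-dynamics); true edges carry the given
    uniform (inhibitory, by default) strength.
    """
    W = -np.eye(3)
    if kind == "chain":
        W[1, 0] = strength
        W[2, 1] = strength
    elif kind == "confounder":
        W[1, 0] = strength
        W[2, 0] = strength
    else:
        raise ValueError(f"unknown motif kind {kind!r}; expected 'chain' or 'confounder'")
    return NetworkGraph(W, metadata={"motif": kind, "strength": strength})


def er_graph(n: int, sparsity: float, strength: float, seed: int = 0,
             diagonal: float = 0.0) -> NetworkGraph:
    """Directed Erdős–Rényi graph: each ordered off-diagonal pair carries an
    edge of uniform ``strength`` independently with probability ``sparsity``."""
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < sparsity
    np.fill_diagonal(mask, False)
    W = np.where(mask, strength, 0.0)
    np.fill_diagonal(W, diagonal)
    return NetworkGraph(W, metadata={"sparsity": sparsity, "strength": strength,
                                     "seed": seed})


def degree_preserving_randomize(g: NetworkGraph, n_swaps: int, seed: int = 0) -> NetworkGraph:
    """Rewire by repeated directed double-edge swaps, preserving every node's
    in- and out-degree; self-loops and duplicate edges are rejected.

    Weights on the rewired graph reuse the most common nonzero weight of the
    input (the generators here use uniform strengths).
    """
    import networkx as nx

    B = g.binary()
    n = g.n_nodes
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(*np.nonzero(B.T)))  # W[i,j]: j->i, so transpose
    if n_swaps <= 0:
        return NetworkGraph(g.W.copy(), metadata=dict(g.metadata, randomized=0))
    off = g.W[~np.eye(n, dtype=bool)]
    weights = off[off != 0]
    weight = float(np.median(weights)) if weights.size else 0.0
    try:
        nx.directed_edge_swap(G, nswap=n_swaps, max_tries=max(100 * n_swaps, 1000),
                              seed=seed)
    except nx.NetworkXError as exc:
        warnings.warn(f"degree-preserving swap not possible ({exc}); returning input")
        return NetworkGraph(g.W.copy(), metadata=dict(g.metadata, randomized=0))
    W = np.zeros_like(g.W)
    for u, v in G.edges:
        W[v, u] = weight
    W[np.diag_indices(n)] = np.diag(g.W)
    return NetworkGraph(W, metadata=dict(g.metadata, randomized=n_swaps, seed=seed))


# ---------------------------------------------------------------------------
# analytic steady-state covariance
# ---------------------------------------------------------------------------

def lyapunov_steady_cov(W: np.ndarray, D: Optional[np.ndarray] = None,
                        Q: Optional[np.ndarray] = None) -> np.ndarray:
    """Stationary covariance P of dx = W x dt + D dβ, Var(dβ) = Q dt.

    Solves the Lyapunov equation ``W P + P Wᵀ + D Q Dᵀ = 0``. Requires W
    stable (all eigenvalue real parts negative).
    """
    from scipy.linalg import solve_continuous_lyapunov

    W = np.asarray(W, float)
    n = W.shape[0]
    D = np.eye(n) if D is None else np.asarray(D, float)
    Q = np.eye(n) if Q is None else np.asarray(Q, float)
    if np.max(np.linalg.eigvals(W).real) >= 0:
        raise ValueError("W is not stable (an eigenvalue has nonnegative real part)")
    P = solve_continuous_lyapunov(W, -D @ Q @ D.T)
    return (P + P.T) / 2.0


# ---------------------------------------------------------------------------
# stochastic linear / sigmoid networks
# ---------------------------------------------------------------------------

@dataclass
class LinearSimConfig:
    """Linear SDE dx/dt = W x + D u with white drive noise of sd ``sigma``
    (spectral density σ²) and additive observational noise of sd ``sigma_obs``."""

    W: np.ndarray
    sigma: float = 1.0
    sigma_obs: float = 0.0
    D: Optional[np.ndarray] = None
    dt: float = 0.01
    duration: float = 1000.0
    seed: int = 0
    x0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.D is not None:
            self.D = np.asarray(self.D, float)
            if self.D.shape != self.W.shape:
                raise ValueError("D must match W in shape")


@dataclass
class SigmoidSimConfig:
    """Nonlinear SDE dx/dt = W R(x) + u with the centered sigmoid
    R(x) = 1/(1+e^{−αx}) − 1/2."""

    W: np.ndarray
    alpha: float = 1.0
    sigma: float = 1.0
    dt: float = 1e-4
    output_rate: float = 100.0
    duration: float = 1000.0
    seed: int = 0
    downsample: str = "pre"  # decimate before estimation ('pre') or keep full ('none')

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.downsample not in ("pre", "none"):
            raise ValueError("downsample must be 'pre' or 'none'")


@njit(cache=True)
def _linear_loop(A, noise, x0, decim, n_rec):  # pragma: no cover - jitted
    n = x0.shape[0]
    out = np.empty((n_rec, n))
    x = x0.copy()
    r = 0
    for k in range(noise.shape[0]):
        if k % decim == 0 and r < n_rec:
            out[r] = x
            r += 1
        x = A @ x + noise[k]
    return out


@njit(cache=True)
def _sigmoid_loop(W, alpha, noise, dt, x0, decim, n_rec):  # pragma: no cover
    n = x0.shape[0]
    out = np.empty((n_rec, n))
    x = x0.copy()
    r = 0
    for k in range(noise.shape[0]):
        if k % decim == 0 and r < n_rec:
            out[r] = x
            r += 1
        R = 1.0 / (1.0 + np.exp(-alpha * x)) - 0.5
        x = x + dt * (W @ R) + noise[k]
    return out


def _check_stability_warn(W: np.ndarray) -> None:
    if np.max(np.linalg.eigvals(W).real) >= 0:
        warnings.warn("spectral abscissa of W is nonnegative; trajectory may diverge")


def _check_divergence(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)) or np.max(np.abs(X)) > _DIVERGENCE_LIMIT:
        raise FloatingPointError(
            "trajectory diverged (|x| > 1e6); use a smaller dt or a stable W"
        )


def simulate_linear(cfg: LinearSimConfig, return_drive: bool = False):
    """Euler–Maruyama integration of the linear SDE.

    The per-step state update is ``x += dt·W x + D·(σ√dt·z)``; the Brownian
    increment dβ = σ√dt·z is independent of the state it is added to.

    With ``return_drive=True`` also returns the noise-derivative series
    dβ/dt (shape-matched to the state series, sample k paired with the state
    *before* the k-th update), used to measure the size of the stochastic
    term <dβ/dt, x> relative to <x, x>.
    """
    _check_stability_warn(cfg.W)
    n = cfg.W.shape[0]
    n_steps = int(round(cfg.duration / cfg.dt))
    rng = np.random.default_rng(cfg.seed)
    z = rng.standard_normal((n_steps, n))
    dbeta = cfg.sigma * np.sqrt(cfg.dt) * z
    noise = dbeta if cfg.D is None else dbeta @ cfg.D.T
    A = np.eye(n) + cfg.dt * cfg.W
    x0 = np.zeros(n) if cfg.x0 is None else np.asarray(cfg.x0, float)
    X = _linear_loop(np.ascontiguousarray(A), np.ascontiguousarray(noise),
                     np.ascontiguousarray(x0), 1, n_steps)
    _check_divergence(X)
    if cfg.sigma_obs > 0:
        X = X + cfg.sigma_obs * rng.standard_normal(X.shape)
    ts = TimeSeries(values=X.T, dt=cfg.dt)
    if return_drive:
        drive = TimeSeries(values=(dbeta / cfg.dt).T, dt=cfg.dt)
        return ts, drive
    return ts


def simulate_sigmoid(cfg: SigmoidSimConfig) -> TimeSeries:
    """Euler–Maruyama integration of the sigmoid-coupled SDE, decimated to
    ``output_rate`` before estimation (the default pipeline)."""
    _check_stability_warn(cfg.W * cfg.alpha / 4.0)  # small-signal linearization
    n = cfg.W.shape[0]
    n_steps = int(round(cfg.duration / cfg.dt))
    decim = 1 if cfg.downsample == "none" else max(int(round(1.0 / (cfg.dt * cfg.output_rate))), 1)
    n_rec = (n_steps + decim - 1) // decim
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.sigma * np.sqrt(cfg.dt) * rng.standard_normal((n_steps, n))
    x0 = np.zeros(n)
    X = _sigmoid_loop(np.ascontiguousarray(cfg.W), float(cfg.alpha),
                      np.ascontiguousarray(noise), float(cfg.dt), x0, decim, n_rec)
    _check_divergence(X)
    return TimeSeries(values=X.T, dt=cfg.dt * decim)


# ---------------------------------------------------------------------------
# Rössler system
# ---------------------------------------------------------------------------

@dataclass
class RosslerConfig:
    a: float = 0.2
    b: float = 0.2
    c: float = 5.7
    dt: float = 0.01
    duration: float = 1000.0
    transient_discard: float = 100.0
    x0: tuple[float, float, float] = (0.0, -6.78, 0.02)

    def __post_init__(self) -> None:
        if self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")


@njit(cache=True)
def _rossler_loop(a, b, c, dt, x0, n_steps):  # pragma: no cover - jitted
    out = np.empty((n_steps, 3))
    x1, x2, x3 = x0[0], x0[1], x0[2]
    for k in range(n_steps):
        out[k, 0] = x1
        out[k, 1] = x2
        out[k, 2] = x3
        d1 = -x2 - x3
        d2 = x1 + a * x2
        d3 = b + x3 * (x1 - c)
        x1 += dt * d1
        x2 += dt * d2
        x3 += dt * d3
    return out


def simulate_rossler(cfg: RosslerConfig) -> TimeSeries:
    """Fixed-step Euler integration of the Rössler attractor; the first
    ``transient_discard`` seconds are dropped."""
    n_steps = int(round(cfg.duration / cfg.dt))
    X = _rossler_loop(cfg.a, cfg.b, cfg.c, cfg.dt, np.asarray(cfg.x0, float), n_steps)
    _check_divergence(X)
    skip = int(round(cfg.transient_discard / cfg.dt))
    return TimeSeries(values=X[skip:].T, dt=cfg.dt)


# ---------------------------------------------------------------------------
# two-state nonstationary system
# ---------------------------------------------------------------------------

@dataclass
class TwoStateConfig:
    """Static connectivity, noise structure switching from D1 to D2 at
    ``switch_time`` — a nonstationary process with time-invariant coupling."""

    W: np.ndarray
    sigma: float = 1.0
    D1: Optional[np.ndarray] = None
    D2: Optional[np.ndarray] = None
    switch_time: float = 500.0
    duration: float = 1000.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        n = self.W.shape[0]
        self.D1 = np.eye(n) if self.D1 is None else np.asarray(self.D1, float)
        if self.D2 is None:
            if n != 3:
                raise ValueError("default D2 is 3x3; pass D2 explicitly for other sizes")
            self.D2 = TWO_STATE_D2.copy()
        else:
            self.D2 = np.asarray(self.D2, float)
        if not self.switch_time < self.duration:
            raise ValueError("switch_time must precede duration")


def simulate_two_state(cfg: TwoStateConfig) -> TimeSeries:
    _check_stability_warn(cfg.W)
    n = cfg.W.shape[0]
    n_steps = int(round(cfg.duration / cfg.dt))
    k_switch = int(round(cfg.switch_time / cfg.dt))
    rng = np.random.default_rng(cfg.seed)
    dbeta = cfg.sigma * np.sqrt(cfg.dt) * rng.standard_normal((n_steps, n))
    noise = np.empty_like(dbeta)
    noise[:k_switch] = dbeta[:k_switch] @ cfg.D1.T
    noise[k_switch:] = dbeta[k_switch:] @ cfg.D2.T
    A = np.eye(n) + cfg.dt * cfg.W
    X = _linear_loop(np.ascontiguousarray(A), np.ascontiguousarray(noise),
                     np.zeros(n), 1, n_steps)
    _check_divergence(X)
    return TimeSeries(values=X.T, dt=cfg.dt)


# ---------------------------------------------------------------------------
# leaky integrate-and-fire network
# ---------------------------------------------------------------------------

@dataclass
class LIFConfig:
    """Sparse LIF network with double-exponential synapses.

    The voltage obeys τ_m dV/dt = −V + W r + I_BIAS; a spike at threshold
    resets V. Numeric constants are repository defaults chosen for a sparse
    few-Hz firing regime, not literature-fixed values; ``i_bias`` in
    particular should be tuned jointly with the coupling (the balance
    I_BIAS ≈ 1 + rate·|w|·in-degree sets the operating point).
    """

    W: np.ndarray
    tau_m: float = 0.02
    tau_d: float = 0.01
    tau_r: float = 0.001
    v_thres: float = 1.0
    v_reset: float = 0.0
    i_bias: float = 12.0
    dt: float = 5e-5
    output_rate: float = 2000.0
    duration: float = 20.0
    seed: int = 0
    max_rate: float = 200.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        if not self.v_reset < self.v_thres:
            raise ValueError("v_reset must be below v_thres")
        if min(self.tau_m, self.tau_d, self.tau_r) <= 0:
            raise ValueError("all time constants must be positive")


@njit(cache=True)
def _lif_loop(W, dt, n_steps, tau_m, tau_d, tau_r, v_thres, v_reset, i_bias,
              v0, decim, max_spikes):  # pragma: no cover - jitted
    n = W.shape[0]
    n_rec = (n_steps + decim - 1) // decim
    V_out = np.empty((n_rec, n))
    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    n_spk = 0
    V = v0.copy()
    r = np.zeros(n)
    h = np.zeros(n)
    kick = 1.0 / (tau_d * tau_r)
    rec = 0
    overflow = False
    for k in range(n_steps):
        syn = W @ r
        dV = (-V + syn + i_bias) / tau_m
        V += dt * dV
        r += dt * (-r / tau_d + h)
        h += dt * (-h / tau_r)
        for i in range(n):
            if V[i] >= v_thres:
                V[i] = v_reset
                h[i] += kick
                if n_spk < max_spikes:
                    spike_neuron[n_spk] = i
                    spike_step[n_spk] = k
                    n_spk += 1
                else:
                    overflow = True
        if k % decim == 0:
            V_out[rec] = V
            rec += 1
        if overflow:
            break
    return V_out, spike_neuron[:n_spk], spike_step[:n_spk], overflow


def simulate_lif(cfg: LIFConfig) -> tuple[TimeSeries, SpikeTrains]:
    """Euler-integrate the LIF network; returns the decimated subthreshold
    voltage trace (reset applied before recording, so the reported trace
    never exceeds threshold) and the spike trains."""
    n = cfg.W.shape[0]
    n_steps = int(round(cfg.duration / cfg.dt))
    decim = max(int(round(1.0 / (cfg.dt * cfg.output_rate))), 1)
    rng = np.random.default_rng(cfg.seed)
    v0 = cfg.v_reset + (cfg.v_thres - cfg.v_reset) * rng.random(n)
    max_spikes = int(cfg.max_rate * 1.5 * cfg.duration * n) + n
    V_out, spk_n, spk_k, overflow = _lif_loop(
        np.ascontiguousarray(cfg.W), float(cfg.dt), n_steps, cfg.tau_m, cfg.tau_d,
        cfg.tau_r, cfg.v_thres, cfg.v_reset, cfg.i_bias, v0, decim, max_spikes)
    mean_rate = len(spk_n) / (n * cfg.duration)
    if overflow or mean_rate > cfg.max_rate:
        raise FloatingPointError(
            f"runaway firing (mean rate {mean_rate:.1f} Hz > {cfg.max_rate} Hz); "
            "reduce i_bias or strengthen inhibition"
        )
    trains = []
    times = spk_k * cfg.dt
    for i in range(n):
        trains.append(np.sort(times[spk_n == i]))
    ts = TimeSeries(values=V_out.T, dt=cfg.dt * decim)
    return ts, SpikeTrains(spike_times=tuple(trains), duration=cfg.duration)


@dataclass(frozen=True)
class ActivityPartition:
    """Active/quiet split of a voltage recording.

    ``active``/``quiet`` are the concatenated sample sets; the per-side
    ``*_segments`` lists keep the contiguous runs so that derivative-based
    cross-products can be formed within segments and never across gaps.
    """

    active: TimeSeries
    quiet: TimeSeries
    active_segments: tuple[TimeSeries, ...]
    quiet_segments: tuple[TimeSeries, ...]


def split_active_quiet(v: TimeSeries, spikes: SpikeTrains, window: float) -> ActivityPartition:
    """Partition samples into those within ±``window`` seconds of any spike
    (active) and the rest (quiet)."""
    all_spikes = np.sort(np.concatenate([t for t in spikes.spike_times])
                         if spikes.n_neurons else np.empty(0))
    times = v.times
    if all_spikes.size:
        idx = np.searchsorted(all_spikes, times)
        left = np.where(idx > 0, times - all_spikes[np.maximum(idx - 1, 0)], np.inf)
        right = np.where(idx < all_spikes.size,
                         all_spikes[np.minimum(idx, all_spikes.size - 1)] - times, np.inf)
        active_mask = np.minimum(left, right) <= window
    else:
        active_mask = np.zeros(times.size, dtype=bool)

    def _segments(mask: np.ndarray) -> tuple[TimeSeries, ...]:
        segs = []
        edges = np.flatnonzero(np.diff(mask.astype(int)))
        starts = np.r_[0, edges + 1]
        ends = np.r_[edges + 1, mask.size]
        for s, e in zip(starts, ends):
            if mask[s] and e - s >= 2:
                segs.append(v.with_values(v.values[:, s:e]))
        return tuple(segs)

    if not active_mask.any():
        raise ValueError("active partition is empty (no sample near any spike)")
    if active_mask.all():
        raise ValueError("quiet partition is empty (every sample is near a spike)")
    active = v.with_values(v.values[:, active_mask])
    quiet = v.with_values(v.values[:, ~active_mask])
    return ActivityPartition(
        active=active, quiet=quiet,
        active_segments=_segments(active_mask),
        quiet_segments=_segments(~active_mask),
    )


# ---------------------------------------------------------------------------
# reduced Wong–Wang model
# ---------------------------------------------------------------------------

@dataclass
class WongWangConfig:
    """Reduced Wong–Wang dynamic mean-field model.

    dS/dt = −S/τ + (1 − S) γ H(x) + σ ν, with input
    x_i = c J S_i + G J Σ_j W_ij S_j + I0 and the firing-rate transfer
    H(x) = (a x − b) / (1 − exp(−d (a x − b))).

    Transfer and kinetic constants default to the standard reduced-model
    values; the local coupling ``c`` and background current ``I0`` carry the
    brain-surface-simulation preset through :func:`wong_wang_dmri_preset`.
    """

    W: np.ndarray
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641
    tau: float = 0.1
    J: float = 0.2609
    G: float = 0.2
    c: float = 0.9
    I0: float = 0.3
    sigma: float = 0.01
    sample_rate: float = 1000.0
    duration: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        if np.any(self.W < 0):
            raise ValueError("structural W must be nonnegative (anatomical weights)")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")


def wong_wang_dmri_preset(W: np.ndarray, **overrides) -> WongWangConfig:
    """The diffusion-MRI simulation preset: c = 0.01, I0 = −0.1."""
    params = dict(c=0.01, I0=-0.1)
    params.update(overrides)
    return WongWangConfig(W=W, **params)


def wong_wang_transfer(x: np.ndarray, a: float = 270.0, b: float = 108.0,
                       d: float = 0.154) -> np.ndarray:
    """Firing-rate transfer H(x); the removable singularity at a·x = b is
    filled with its limit value 1/d."""
    u = a * np.asarray(x, float) - b
    du = d * u
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        out = np.where(np.abs(du) < 1e-8, 1.0 / d + u / 2.0,
                       u / (1.0 - np.exp(-np.clip(du, -700, 700))))
    return out


@njit(cache=True)
def _wong_wang_loop(W, a, b, d, gamma, tau, J, G, c, I0, noise, dt,
                    S0):  # pragma: no cover - jitted
    n = W.shape[0]
    n_steps = noise.shape[0]
    out = np.empty((n_steps, n))
    S = S0.copy()
    bad = 0
    for k in range(n_steps):
        x = c * J * S + G * J * (W @ S) + I0
        u = a * x - b
        H = np.empty(n)
        for i in range(n):
            du = d * u[i]
            if abs(du) < 1e-8:
                H[i] = 1.0 / d + u[i] / 2.0
            else:
                H[i] = u[i] / (1.0 - np.exp(-du))
        S = S + dt * (-S / tau + (1.0 - S) * gamma * H) + noise[k]
        for i in range(n):
            if S[i] < -0.1 or S[i] > 1.1:
                bad += 1
        out[k] = S
    return out, bad


def simulate_wong_wang(cfg: WongWangConfig) -> TimeSeries:
    dt = 1.0 / cfg.sample_rate
    n = cfg.W.shape[0]
    n_steps = int(round(cfg.duration * cfg.sample_rate))
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.sigma * np.sqrt(dt) * rng.standard_normal((n_steps, n))
    S0 = np.full(n, 0.1)
    X, bad = _wong_wang_loop(np.ascontiguousarray(cfg.W), cfg.a, cfg.b, cfg.d,
                             cfg.gamma, cfg.tau, cfg.J, cfg.G, cfg.c, cfg.I0,
                             np.ascontiguousarray(noise), dt, S0)
    _check_divergence(X)
    if bad > 0.001 * X.size:
        raise FloatingPointError(
            "gating variable left [-0.1, 1.1] persistently; reduce G, sigma or I0"
        )
    return TimeSeries(values=X.T, dt=dt)
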