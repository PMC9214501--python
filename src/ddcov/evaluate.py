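"""Estimate-versus-truth metrics and surrogate-data significance testing.

Error decomposition
-------------------
Estimates typically differ from the ground truth by an overall scale, so both
matrices are normalized to [−1, 1] (division by the largest absolute entry)
and the diagonal is always excluded; optionally only the strictly lower
triangle is compared. Over repeated trials the normalized error splits
orthogonally:

    Error   = ||W − Ŵ|| / ||W||        (RMS across trials)
    Bias    = ||W − W̄|| / ||W||        (W̄ = trial-mean estimate)
    Variance= ||Ŵ − W̄|| / ||W||        (RMS across trials)

with Error² = Bias² + Variance² holding exactly, and θb = arctan(Bias /
Variance) measuring the bias contribution.

Significance
------------
The AR bootstrap builds an edgewise null in which every node is an
independent autoregressive process fitted to its own trace (order selected
by BIC with a drop-by-2 rule), preserving each node's power spectrum while
destroying all cross-dependence. Surrogate datasets are re-estimated, a
Gaussian is fitted per edge, and two-sided tail probabilities are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "ErrorDecomposition",
    "ROCResult",
    "SignificanceResult",
    "normalize_for_comparison",
    "normalized_error",
    "error_bias_variance",
    "roc_auc",
    "c_sensitivity",
    "ar_bootstrap_significance",
    "binarize_by_significance",
    "subject_identification",
]


# ---------------------------------------------------------------------------
# matrix comparison
# ---------------------------------------------------------------------------

def _comparison_vector(M: np.ndarray, lower_triangle_only: bool) -> np.ndarray:
    M = np.asarray(M, float)
    n = M.shape[0]
    if lower_triangle_only:
        return M[np.tril_indices(n, k=-1)]
    return M[~np.eye(n, dtype=bool)]


def normalize_for_comparison(est: np.ndarray, truth: np.ndarray,
                             lower_triangle_only: bool = False
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Scale both matrices into [−1, 1] and vectorize the compared entries.

    The diagonal is always excluded; with ``lower_triangle_only`` only the
    strictly lower triangle (length n(n−1)/2) is kept. Each matrix is divided
    by its own largest absolute compared entry.
    """
    est = np.asarray(est, float)
    truth = np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.shape}")
    out = []
    for M in (est, truth):
        v = _comparison_vector(M, lower_triangle_only)
        m = np.max(np.abs(v))
        if m == 0:
            raise ValueError("cannot normalize an all-zero comparison matrix")
        out.append(v / m)
    return out[0], out[1]


def normalized_error(est: np.ndarray, truth: np.ndarray,
                     lower_triangle_only: bool = False) -> float:
    """Single-trial normalized error ||W − Ŵ|| / ||W|| after normalization."""
    e, w = normalize_for_comparison(est, truth, lower_triangle_only)
    return float(np.linalg.norm(w - e) / np.linalg.norm(w))


@dataclass(frozen=True)
class ErrorDecomposition:
    error: float
    bias: float
    variance: float
    theta_b: float
    n_trials: int


def error_bias_variance(estimates: Sequence[np.ndarray], truth: np.ndarray,
                        lower_triangle_only: bool = False) -> ErrorDecomposition:
    """Orthogonal error/bias/variance decomposition across trials."""
    if len(estimates) == 0:
        raise ValueError("need at least one trial estimate")
    vecs = []
    w = None
    for est in estimates:
        e, w = normalize_for_comparison(est, truth, lower_triangle_only)
        vecs.append(e)
    V = np.array(vecs)
    wn = np.linalg.norm(w)
    mean = V.mean(axis=0)
    err = float(np.sqrt(np.mean([np.linalg.norm(w - v) ** 2 for v in V])) / wn)
    bias = float(np.linalg.norm(w - mean) / wn)
    var = float(np.sqrt(np.mean([np.linalg.norm(v - mean) ** 2 for v in V])) / wn)
    tiny = 1e-14  # float residue does not count as real bias/variance
    if var <= tiny:
        theta = 0.0 if bias <= tiny else np.pi / 2.0
    else:
        theta = float(np.arctan(bias / var))
    return ErrorDecomposition(error=err, bias=bias, variance=var, theta_b=theta,
                              n_trials=len(estimates))


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(est: np.ndarray, truth_binary: np.ndarray) -> ROCResult:
    """ROC over |estimate| magnitudes for binary edge recovery.

    Sweeps binarization thresholds over the off-diagonal |est| values;
    sensitivity is the true-positive rate, specificity one minus the
    false-positive rate, and the AUC is the trapezoidal area.
    """
    from sklearn.metrics import roc_curve

    est = np.asarray(est, float)
    truth = np.asarray(truth_binary)
    y = _comparison_vector(truth, False).astype(int)
    s = np.abs(_comparison_vector(est, False))
    if y.min() == y.max():
        raise ValueError("ROC undefined: ground truth has a single class")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, auc=auc)


def c_sensitivity(est: np.ndarray, truth_binary: np.ndarray) -> float:
    """Fraction of true-edge |est| values above the 95th percentile of the
    non-edge |est| values."""
    est = np.asarray(est, float)
    truth = np.asarray(truth_binary)
    y = _comparison_vector(truth, False).astype(int)
    s = np.abs(_comparison_vector(est, False))
    tp = s[y == 1]
    fp = s[y == 0]
    if tp.size == 0:
        raise ValueError("c-sensitivity undefined: no true edges")
    if fp.size == 0:
        raise ValueError("c-sensitivity undefined: no non-edges")
    if fp.size < 20:
        warnings.warn("fewer than 20 non-edges: the 95th percentile is degenerate")
    cutoff = np.percentile(fp, 95)
    return float(np.mean(tp > cutoff))


# ---------------------------------------------------------------------------
# AR bootstrap significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificanceResult:
    p_values: np.ndarray
    n_surrogates: int
    ar_orders: tuple[int, ...]
    binarized: dict = field(default_factory=dict)


def _fit_ar_forward(y: np.ndarray, max_order: int, bic_drop: float = 2.0):
    """Forward BIC search: raise the order only while BIC drops by > 2.

    Returns (order, const, coefficients, residual sd)."""
    from statsmodels.tsa.ar_model import AutoReg

    best = None
    for q in range(0, max_order + 1):
        try:
            res = AutoReg(y, lags=q, trend="c").fit()
        except Exception as exc:  # noqa: BLE001 - report per node upstream
            raise RuntimeError(f"AR({q}) fit failed: {exc}") from exc
        if best is not None and res.bic >= best[0] - bic_drop:
            break
        params = np.asarray(res.params, float)
        best = (res.bic, q, params[0], params[1:], float(np.sqrt(res.sigma2)))
    _, q, const, coefs, sd = best
    return q, const, coefs, sd


def _simulate_ar(const: float, coefs: np.ndarray, sd: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    q = len(coefs)
    burn = 200 + 10 * q
    innov = const + sd * rng.standard_normal(n + burn)
    x = lfilter([1.0], np.r_[1.0, -coefs], innov)
    return x[burn:]


def ar_bootstrap_significance(ts: TimeSeries,
                              estimator: str | Callable[[TimeSeries], object],
                              n_surrogates: int = 1000, seed: int = 0,
                              max_order: int = 10,
                              estimator_params: Mapping | None = None
                              ) -> SignificanceResult:
    """Edgewise significance by the autoregressive bootstrap.

    Each node is fitted with its own AR model (order by forward BIC search,
    accepting a higher order only when BIC falls by more than 2). Surrogate
    datasets resample Gaussian innovations through the fitted filters,
    independently across nodes — the null of no cross-dependence with each
    node's power spectrum preserved. The estimator runs on every surrogate; a
    Gaussian fitted per edge to the null values yields two-sided p-values.
    """
    from .estimators import get_estimator

    if n_surrogates < 50:
        warnings.warn("fewer than 50 surrogates: Gaussian null fit may be unstable")
    if isinstance(estimator, str):
        est_fn = get_estimator(estimator, **(estimator_params or {}))
    else:
        est_fn = estimator

    def run(series: TimeSeries) -> np.ndarray:
        out = est_fn(series)
        return out.matrix if hasattr(out, "matrix") else np.asarray(out, float)

    n = ts.n_nodes
    fits = []
    for i in range(n):
        try:
            fits.append(_fit_ar_forward(ts.values[i], max_order))
        except RuntimeError as exc:
            raise RuntimeError(f"AR fit failed for node {ts.node_ids[i]}: {exc}") from exc
    observed = run(ts)
    rng = np.random.default_rng(seed)
    null = np.empty((n_surrogates, n, n))
    for s in range(n_surrogates):
        surro = np.empty_like(ts.values)
        for i, (_, const, coefs, sd) in enumerate(fits):
            surro[i] = _simulate_ar(const, coefs, sd, ts.n_time, rng)
        null[s] = run(ts.with_values(surro))
    from scipy.stats import norm

    mu = null.mean(axis=0)
    sd_null = null.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = np.abs(observed - mu) / sd_null
    p = 2.0 * norm.sf(zscores)
    p = np.where(sd_null == 0, np.where(observed == mu, 1.0, 0.0), p)
    np.fill_diagonal(p, 1.0)
    return SignificanceResult(p_values=p, n_surrogates=n_surrogates,
                              ar_orders=tuple(f[0] for f in fits))


def binarize_by_significance(res: SignificanceResult, alpha: float) -> np.ndarray:
    """Binary connection matrix: entry 1 iff p < alpha; diagonal 0."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    B = (res.p_values < alpha).astype(int)
    np.fill_diagonal(B, 0)
    return B


# ---------------------------------------------------------------------------
# matrix-collection identification
# ---------------------------------------------------------------------------

def subject_identification(database: Mapping[str, np.ndarray],
                           targets: Mapping[str, np.ndarray],
                           m: int = 1) -> float:
    """Soft identification accuracy across a labeled matrix collection.

    For every target matrix, database matrices are ranked by Pearson
    correlation of the vectorized off-diagonal entries; identification
    succeeds when the true label falls in the top-``m`` candidate pool.
    """
    if set(database) != set(targets):
        raise ValueError("database and target labels differ")
    labels = sorted(database)
    db = np.array([_comparison_vector(np.asarray(database[k], float), False)
                   for k in labels])
    db_c = db - db.mean(axis=1, keepdims=True)
    db_c /= np.linalg.norm(db_c, axis=1, keepdims=True)
    hits = 0
    for li, label in enumerate(labels):
        t = _comparison_vector(np.asarray(targets[label], float), False)
        t = t - t.mean()
        t /= np.linalg.norm(t)
        corr = db_c @ t
        top = np.argsort(-corr)[:m]
        hits += int(li in top)
    return hits / len(labels)
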