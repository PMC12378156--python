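"""Geographically weighted regression (GWR) with AICc bandwidth selection.

The model is the local linear regression

    y_i = a_0(u_i, v_i) + sum_k a_k(u_i, v_i) x_ik + eps_i

whose coefficients are estimated at each location by distance-kernel-weighted
least squares:  a_hat(i) = (X' W_i X)^-1 X' W_i y.  Two kernels are offered —
Gaussian ``w = exp(-d^2 / theta^2)`` with a fixed distance bandwidth, and the
compact-support bisquare ``w = (1 - (d/theta)^2)^2`` for ``d < theta`` with
either a fixed or an adaptive (k-nearest-neighbor) bandwidth.  The bandwidth
is chosen by golden-section search on the corrected Akaike information
criterion

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S)

where ``tr S`` is the trace of the hat matrix of the local smoother (its
effective number of parameters) and ``sigma_hat^2 = RSS / n``.

Coordinates must be projected meters; distances are Euclidean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GWRConfig",
    "GWRModel",
    "OversmoothingError",
    "kernel_weights",
    "fit_gwr",
    "aicc_score",
    "select_bandwidth",
    "predict_gwr",
    "predict_grid",
]


class OversmoothingError(ValueError):
    """tr(S) is too close to n for the AICc to be defined."""


@dataclass
class GWRConfig:
    """Kernel and bandwidth configuration.

    ``bandwidth`` is a distance theta in meters (``fixed_distance`` mode) or
    a neighbor count k (``adaptive_neighbors`` mode, where theta at each
    regression point is the distance to its k-th nearest training point).
    The defaults mirror the executed regional analysis: adaptive neighbor
    bandwidth with bisquare local weights; the Gaussian fixed-distance kernel
    is retained for the closed-form model.
    """

    kernel: str = "bisquare"
    bandwidth_mode: str = "adaptive_neighbors"
    bandwidth: float | int | None = None
    search_bounds: tuple[float, float] | None = None
    search_tol: float = 1.0
    ridge_fallback: float = 1e-8

    def __post_init__(self):
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValueError("kernel must be 'gaussian' or 'bisquare'")
        if self.bandwidth_mode not in ("fixed_distance", "adaptive_neighbors"):
            raise ValueError(
                "bandwidth_mode must be 'fixed_distance' or 'adaptive_neighbors'"
            )
        if self.ridge_fallback < 0:
            raise ValueError("ridge_fallback must be nonnegative")


def _kernel(d: np.ndarray, theta, kind: str) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("bandwidth must be positive")
    if kind == "gaussian":
        return np.exp(-(d**2) / theta**2)
    t = d / theta
    return np.where(t < 1.0, (1.0 - t**2) ** 2, 0.0)


def _adaptive_theta(d: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest training point (rows of d), 1-indexed."""
    n = d.shape[-1]
    k = int(np.clip(k, 1, n))
    part = np.partition(d, k - 1, axis=-1)[..., k - 1]
    return np.maximum(part, 1e-12)


def kernel_weights(
    point: np.ndarray, coords: np.ndarray, config: GWRConfig
) -> np.ndarray:
    """Kernel weights of every training location relative to one point.

    In adaptive mode the bandwidth resolves to the distance from ``point``
    to its ``k``-th nearest training location.  All weights lie in [0, 1];
    the bisquare kernel has compact support exactly at theta.
    """
    if config.bandwidth is None:
        raise ValueError("config.bandwidth is not set")
    point = np.asarray(point, dtype=float)
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords - point) ** 2).sum(axis=1))
    if config.bandwidth_mode == "adaptive_neighbors":
        theta = _adaptive_theta(d, int(config.bandwidth))
    else:
        theta = float(config.bandwidth)
        if theta <= 0:
            raise ValueError("bandwidth must be positive")
    return _kernel(d, theta, config.kernel)


@dataclass
class GWRModel:
    """Fitted local-coefficient model plus diagnostics."""

    coords: np.ndarray
    X: np.ndarray  # design with leading intercept column, (n, p+1)
    y: np.ndarray
    config: GWRConfig
    bandwidth: float | int
    coefficients: np.ndarray  # (n, p+1)
    fitted: np.ndarray
    residuals: np.ndarray
    hat_diag: np.ndarray
    trace_S: float
    rss: float
    sigma2: float
    aicc: float
    local_r2: np.ndarray | None = None
    feature_names: list[str] | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1] - 1

    def summary(self) -> dict:
        lr2 = self.local_r2
        q = (
            {}
            if lr2 is None
            else {
                "local_r2_mean": float(np.mean(lr2)),
                "local_r2_quartiles": [float(v) for v in np.percentile(lr2, [25, 50, 75])],
            }
        )
        return {
            "n": self.n,
            "p": self.p,
            "kernel": self.config.kernel,
            "bandwidth_mode": self.config.bandwidth_mode,
            "bandwidth": float(self.bandwidth),
            "trace_S": float(self.trace_S),
            "rss": float(self.rss),
            "aicc": float(self.aicc),
            **q,
        }


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def _weight_matrix(dmat: np.ndarray, config: GWRConfig, bandwidth) -> np.ndarray:
    if config.bandwidth_mode == "adaptive_neighbors":
        theta = _adaptive_theta(dmat, int(bandwidth))[:, None]
    else:
        theta = float(bandwidth)
    return _kernel(dmat, theta, config.kernel)


def _local_solutions(Xd, y, W, ridge):
    """Batched weighted-normal-equation solves for all regression points.

    Returns (coefficients (m, q), M_inv_x diagnostics helper) where row i of
    ``W`` holds the weights of the training points for regression point i.
    """
    q = Xd.shape[1]
    M = np.einsum("mn,nj,nk->mjk", W, Xd, Xd, optimize=True)
    b = np.einsum("mn,nj,n->mj", W, Xd, y, optimize=True)
    if ridge > 0:
        M = M + ridge * np.eye(q)[None, :, :]
    try:
        beta = np.linalg.solve(M, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        if ridge == 0:
            raise np.linalg.LinAlgError(
                "singular local system; set ridge_fallback > 0"
            )
        raise
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError(
            "non-finite local solution; increase ridge_fallback or bandwidth"
        )
    return beta, M


def fit_gwr(
    X,
    y,
    coords,
    config: GWRConfig,
    compute_diagnostics: bool = True,
    _dmat: np.ndarray | None = None,
) -> GWRModel:
    """Fit GWR at every training location by local weighted least squares.

    ``X`` is the (n, p) covariate matrix without intercept (one is added),
    ``coords`` the (n, 2) projected coordinates in meters.  Per location i
    the local coefficients solve the weighted normal equations; the hat
    diagonal ``s_ii = w_ii x_i' (X' W_i X)^-1 x_i`` accumulates into tr(S)
    and the AICc.  ``local_r2`` uses kernel-weighted total and residual sums
    of squares around the weighted local mean.

    Singular local systems are stabilized with ``config.ridge_fallback`` (a
    warning is emitted); with a zero fallback they raise.
    """
    Xd = _design(X)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, q = Xd.shape
    if coords.shape != (n, 2):
        raise ValueError("coords must be (n, 2) projected meters")
    if n <= q + 1:
        raise ValueError("need n > p + 2 observations")
    if config.bandwidth is None:
        raise ValueError("config.bandwidth is not set; run select_bandwidth first")
    dmat = (
        _dmat
        if _dmat is not None
        else np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    )
    W = _weight_matrix(dmat, config, config.bandwidth)
    ridge = config.ridge_fallback
    try:
        beta, M = _local_solutions(Xd, y, W, 0.0)
    except np.linalg.LinAlgError:
        if ridge == 0:
            raise
        warnings.warn(
            f"singular local system; adding ridge {ridge:g} to the normal equations"
        )
        beta, M = _local_solutions(Xd, y, W, ridge)

    fitted = np.einsum("ij,ij->i", Xd, beta)
    residuals = y - fitted
    # s_ii = w_ii * x_i' M_i^{-1} x_i
    Minv_x = np.linalg.solve(M, Xd[:, :, None])[:, :, 0]
    hat_diag = np.einsum("ii,ij,ij->i", W, Xd, Minv_x)
    trace_S = float(hat_diag.sum())
    rss = float(residuals @ residuals)
    sigma2 = rss / n
    try:
        aicc = aicc_score(rss, n, trace_S)
    except ValueError:  # oversmoothed (tr S ~ n) or an exact fit (RSS = 0)
        aicc = math.inf

    local_r2 = None
    if compute_diagnostics:
        yhat_local = beta @ Xd.T  # (i, j): prediction of y_j by model of point i
        wsum = W.sum(axis=1)
        ybar_w = (W @ y) / wsum
        rss_w = np.einsum("ij,ij->i", W, (y[None, :] - yhat_local) ** 2)
        tss_w = np.einsum("ij,ij->i", W, (y[None, :] - ybar_w[:, None]) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            local_r2 = np.where(tss_w > 0, 1.0 - rss_w / tss_w, np.nan)

    return GWRModel(
        coords=coords,
        X=Xd,
        y=y,
        config=config,
        bandwidth=config.bandwidth,
        coefficients=beta,
        fitted=fitted,
        residuals=residuals,
        hat_diag=hat_diag,
        trace_S=trace_S,
        rss=rss,
        sigma2=sigma2,
        aicc=aicc,
        local_r2=local_r2,
    )


def aicc_score(rss: float, n: int, trace_S: float) -> float:
    """Corrected AIC of a linear smoother with hat-trace ``trace_S``.

    ``AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr S)/(n - 2 - tr S)``
    with ``sigma_hat = sqrt(RSS / n)``.  Strictly increasing in RSS at fixed
    n and tr S.  Raises :class:`OversmoothingError` when ``tr S >= n - 2``.
    """
    if rss <= 0:
        raise ValueError("RSS must be positive")
    if n - 2 - trace_S <= 0:
        raise OversmoothingError(
            f"tr(S) = {trace_S:.2f} leaves no residual degrees of freedom (n = {n})"
        )
    sigma = math.sqrt(rss / n)
    return 2 * n * math.log(sigma) + n * math.log(2 * math.pi) + n * (
        (n + trace_S) / (n - 2 - trace_S)
    )


def _golden_section(f, lo: float, hi: float, tol: float, integer: bool):
    """Golden-section minimization with memoization; ties go to the smaller
    argument.  Returns (argmin, profile dict)."""
    invphi = (math.sqrt(5) - 1) / 2
    cache: dict[float, float] = {}

    def ev(x: float) -> float:
        x = float(round(x)) if integer else float(x)
        if x not in cache:
            cache[x] = f(x)
        return cache[x]

    a, b = float(lo), float(hi)
    ev(a), ev(b)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    while (b - a) > max(tol, 1.0 if integer else 0.0):
        if ev(c) <= ev(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    best = min(sorted(cache), key=lambda x: (cache[x], x))
    return best, cache


def select_bandwidth(
    X,
    y,
    coords,
    config: GWRConfig,
    bounds: tuple[float, float] | None = None,
    tol: float | None = None,
):
    """Golden-section bandwidth search minimizing the AICc of the GWR fit.

    Adaptive mode searches integer neighbor counts (default bounds
    ``[p + 2, n]``) with rounding and memoized evaluations; fixed mode
    searches a continuous distance.  Returns ``(config_with_bandwidth,
    profile)`` where profile is the list of evaluated ``(bandwidth, aicc)``
    pairs; infeasible bandwidths score ``inf``.  A minimizer at the upper
    bound triggers a boundary warning.
    """
    Xd = _design(X)
    n, q = Xd.shape
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y, dtype=float)
    dmat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    adaptive = config.bandwidth_mode == "adaptive_neighbors"
    if bounds is None:
        bounds = config.search_bounds
    if bounds is None:
        if adaptive:
            bounds = (q + 1, n)
        else:
            pos = dmat[dmat > 0]
            bounds = (float(pos.min()), float(dmat.max()))
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("search bounds must satisfy lo < hi")
    if tol is None:
        tol = config.search_tol if adaptive else max(config.search_tol, (hi - lo) * 1e-3)

    def objective(bw: float) -> float:
        cfg = GWRConfig(
            kernel=config.kernel,
            bandwidth_mode=config.bandwidth_mode,
            bandwidth=int(bw) if adaptive else bw,
            ridge_fallback=config.ridge_fallback,
        )
        try:
            model = fit_gwr(
                Xd[:, 1:], y, coords, cfg, compute_diagnostics=False, _dmat=dmat
            )
        except (np.linalg.LinAlgError, ValueError):
            return math.inf
        return model.aicc

    best, cache = _golden_section(objective, lo, hi, tol, integer=adaptive)
    profile = sorted(cache.items())
    if not np.isfinite(cache[best]):
        raise ValueError("no feasible bandwidth in the search interval")
    if best >= hi - (1 if adaptive else tol):
        warnings.warn(
            "AICc is still decreasing at the upper bandwidth bound; "
            "the returned bandwidth sits on the boundary"
        )
    out = GWRConfig(
        kernel=config.kernel,
        bandwidth_mode=config.bandwidth_mode,
        bandwidth=int(best) if adaptive else float(best),
        search_bounds=(lo, hi),
        search_tol=tol,
        ridge_fallback=config.ridge_fallback,
    )
    return out, profile


def predict_gwr(
    model: GWRModel,
    new_coords,
    new_X,
    clamp: tuple[float, float] | None = None,
    chunk: int = 2048,
) -> np.ndarray:
    """Predict at unsampled locations by refitting local coefficients.

    At each prediction point, kernel weights to the training points are
    computed with the model bandwidth (adaptive bandwidths resolve per
    point), the local coefficients are re-estimated from the training data
    only, and the prediction is ``x_new . a_hat``.  Points receiving zero
    weight from every training point (possible under a fixed-distance
    bisquare kernel) yield NaN with a warning.  ``clamp`` clips the output
    (use (0, 1) for a proportion response).
    """
    new_coords = np.atleast_2d(np.asarray(new_coords, dtype=float))
    Xd_new = _design(new_X)
    if Xd_new.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"design mismatch: training has {model.X.shape[1] - 1} covariates, "
            f"got {Xd_new.shape[1] - 1}"
        )
    cfg = model.config
    ridge = cfg.ridge_fallback
    out = np.empty(len(new_coords))
    n_empty = 0
    for start in range(0, len(new_coords), chunk):
        sl = slice(start, min(start + chunk, len(new_coords)))
        d = np.sqrt(
            ((new_coords[sl, None, :] - model.coords[None, :, :]) ** 2).sum(-1)
        )
        W = _weight_matrix(d, cfg, model.bandwidth)
        empty = W.sum(axis=1) <= 0
        n_empty += int(empty.sum())
        W[empty] = 1e-12  # placeholder; overwritten with NaN below
        try:
            beta, _ = _local_solutions(model.X, model.y, W, 0.0)
        except np.linalg.LinAlgError:
            if ridge == 0:
                raise
            beta, _ = _local_solutions(model.X, model.y, W, ridge)
        pred = np.einsum("ij,ij->i", Xd_new[sl], beta)
        pred[empty] = np.nan
        out[sl] = pred
    if n_empty:
        warnings.warn(
            f"{n_empty} prediction points lie beyond the kernel support of "
            "every training point; returned NaN"
        )
    if clamp is not None:
        out = np.clip(out, clamp[0], clamp[1])
    return out


def predict_grid(
    model: GWRModel,
    covariate_grids: dict[str, np.ndarray],
    feature_names: list[str],
    cell_size: float,
    mask: np.ndarray | None = None,
    clamp: tuple[float, float] | None = (0.0, 1.0),
    chunk: int = 2048,
) -> np.ndarray:
    """Wall-to-wall map prediction over a north-up raster lattice."""
    shape = next(iter(covariate_grids.values())).shape
    rows, cols = shape
    xs = (np.arange(cols) + 0.5) * cell_size
    ys = (rows - np.arange(rows) - 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    valid = np.ones(shape, bool) if mask is None else mask.astype(bool)
    coords = np.column_stack([xx[valid], yy[valid]])
    Xnew = np.column_stack(
        [np.asarray(covariate_grids[name], float)[valid] for name in feature_names]
    )
    pred = predict_gwr(model, coords, Xnew, clamp=clamp, chunk=chunk)
    out = np.full(shape, np.nan)
    out[valid] = pred
    return out
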