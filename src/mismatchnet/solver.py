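"""Coordinate-descent solver for weighted elastic-net objectives.

The objective is the raw (unnormalized) penalized residual sum of squares —
no ``1/(2n)`` factor in front of the squared-error term and no halving of
the ridge term::

    PRSS(b0, b) = sum_i (y_i - b0 - x_i . b)^2
                  + lam * [ (1 - alpha) * sum_j w_j b_j^2
                            + alpha * sum_j w_j |b_j| ]

with per-marker penalty weights ``w_j >= 0`` (``w_j = +inf`` excludes marker
``j`` outright).  To translate to the scikit-learn / glmnet convention divide
``lam`` by ``2n`` and note those backends halve the ridge term.

Design matrices are internally centered and (by default) scaled to unit
population standard deviation; coefficients are returned on the original
scale.  The intercept is never penalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._cd import cd_cycle

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-3  # used only in the lambda_max formula when alpha == 0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n x p allele-dosage matrix with line and marker identifiers."""

    values: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray
    attrs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 lines")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.marker_ids)) != p:
            raise ValueError("marker_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains non-finite values "
                             "(impute missing dosages at load time)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, row_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[row_idx], self.line_ids[row_idx],
                              self.marker_ids, dict(self.attrs))


@dataclass
class PenaltyWeights:
    """Per-marker penalty factors, possibly infinite (marker excluded).

    ``rescaled`` holds the weights actually applied by the solver: finite
    entries are normalized to average 1 (mirroring glmnet's penalty-factor
    rescaling, so lambda paths stay comparable across weighting schemes);
    infinite raw entries stay infinite and set ``excluded_mask``.
    """

    raw: np.ndarray
    rescaled: np.ndarray
    excluded_mask: np.ndarray

    @classmethod
    def from_raw(cls, raw) -> "PenaltyWeights":
        raw = np.asarray(raw, dtype=np.float64)
        if raw.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(np.isnan(raw)) or np.any(raw < 0):
            raise ValueError("raw weights must be non-negative (NaN found?)")
        excluded = np.isinf(raw)
        if excluded.all():
            raise ValueError("all weights are infinite: no marker survives")
        rescaled = raw.copy()
        finite = ~excluded
        m = raw[finite].mean()
        if m > 0:
            rescaled[finite] = raw[finite] / m
        return cls(raw=raw, rescaled=rescaled, excluded_mask=excluded)

    @classmethod
    def unit(cls, p: int) -> "PenaltyWeights":
        ones = np.ones(p)
        return cls(raw=ones.copy(), rescaled=ones,
                   excluded_mask=np.zeros(p, dtype=bool))

    @property
    def p(self) -> int:
        return self.raw.size


@dataclass
class ElasticNetFit:
    """Result of one weighted elastic-net fit (original data scale)."""

    intercept: float
    coefficients: np.ndarray
    lam: float
    alpha: float
    objective: float
    n_sweeps: int
    converged: bool
    # internal-scale artifacts kept for diagnostics / warm starts
    beta_std: np.ndarray = field(repr=False, default=None)
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)
    y_mean: float = field(repr=False, default=0.0)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))


@dataclass
class LambdaPath:
    grid: np.ndarray
    fits: list

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.size > 1 and not np.all(np.diff(g) < 0):
            raise ValueError("lambda grid must be strictly decreasing")


@dataclass
class CVResult:
    grid: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    fold_assignment: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0); ties |z| == gamma resolve to 0."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    return X


def _standardize(X: np.ndarray, standardize: bool):
    """Center columns; optionally scale to unit population SD (divisor n).

    Zero-variance columns are flagged and left at scale 1 (their coefficient
    is forced to 0 by the solver).
    """
    x_mean = X.mean(axis=0)
    if standardize:
        x_scale = X.std(axis=0)  # population convention
    else:
        x_scale = np.ones(X.shape[1])
    zero_var = np.isclose(X.std(axis=0), 0.0)
    safe_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xs = np.asfortranarray((X - x_mean) / safe_scale)
    if zero_var.any():
        logger.warning("%d zero-variance (monomorphic) markers: coefficients "
                       "forced to 0", int(zero_var.sum()))
    return Xs, x_mean, safe_scale, zero_var


def _resolve_weights(weights, p: int):
    """Return (finite-or-inf weight vector, excluded mask).

    ``None`` means unit weights.  A plain ndarray is applied literally
    (infinite entries exclude the marker); a PenaltyWeights object is applied
    through its mean-1 ``rescaled`` field.
    """
    if weights is None:
        return np.ones(p), np.zeros(p, dtype=bool)
    if isinstance(weights, PenaltyWeights):
        if weights.p != p:
            raise ValueError(f"weights length {weights.p} != p = {p}")
        return weights.rescaled.copy(), weights.excluded_mask.copy()
    w = np.asarray(weights, dtype=np.float64)
    if w.size != p:
        raise ValueError(f"weights length {w.size} != p = {p}")
    if np.any(np.isnan(w)) or np.any(w < 0):
        raise ValueError("weights must be non-negative")
    excluded = np.isinf(w)
    return w, excluded


def _objective(r: np.ndarray, beta: np.ndarray, lam: float, alpha: float,
               w: np.ndarray, included: np.ndarray) -> float:
    b = beta[included]
    wi = w[included]
    pen = (1.0 - alpha) * np.sum(wi * b * b) + alpha * np.sum(wi * np.abs(b))
    return float(r @ r + lam * pen)


def _kkt_terms(g: np.ndarray, beta: np.ndarray, lam: float, alpha: float,
               w: np.ndarray, included: np.ndarray):
    """Per-coordinate KKT violations in gradient units (included coords).

    For beta_j != 0 the stationarity residual is
    ``2 g_j - 2 lam (1-alpha) w_j beta_j - lam alpha w_j sign(beta_j)``
    (note ``2 rho_j - 2 (x_j.x_j) beta_j == 2 g_j`` with g = X'r);
    for beta_j == 0 it is ``max(0, |2 g_j| - lam alpha w_j)``.
    """
    viol = np.zeros_like(g)
    nz = included & (beta != 0)
    z = included & (beta == 0)
    if nz.any():
        viol[nz] = np.abs(2.0 * g[nz]
                          - 2.0 * lam * (1.0 - alpha) * w[nz] * beta[nz]
                          - lam * alpha * w[nz] * np.sign(beta[nz]))
    if z.any():
        viol[z] = np.maximum(0.0, np.abs(2.0 * g[z]) - lam * alpha * w[z])
    return viol


def _fit_std(Xs, yc, lam, alpha, w, included, xx, tol, max_sweeps,
             beta=None, grad_scale=None):
    """Solve the standardized problem by KKT-screened cyclic CD.

    Coordinates outside the current candidate set stay at their warm-start
    value (0 for a cold start); after each CD pass a full-gradient KKT check
    admits violators, so the final solution solves the full problem.
    """
    p = xx.size
    if beta is None:
        beta = np.zeros(p)
    else:
        beta = beta.copy()
    beta[~included] = 0.0
    wf = np.where(np.isfinite(w), w, 0.0)  # excluded coords never enter
    thr = np.where(included, 0.5 * lam * alpha * wf, np.inf)
    denom = np.where(included, xx + lam * (1.0 - alpha) * wf, 0.0)
    r = yc - Xs @ beta if np.any(beta) else yc.copy()
    if grad_scale is None:
        grad_scale = max(1.0, float(np.abs(2.0 * (Xs.T @ yc)).max(initial=0.0)))
    eps = 2.0 * tol * grad_scale  # 2e-7 * scale at the default tolerance

    cand = included & (beta != 0)
    g = Xs.T @ r
    cand |= included & (np.abs(2.0 * g) > lam * alpha * w)
    total_sweeps = 0
    converged = False
    tol_eff = tol
    for _ in range(100):
        idx = np.flatnonzero(cand).astype(np.int64)
        if idx.size:
            budget = max(1, max_sweeps - total_sweeps)
            sweeps, _hit = cd_cycle(Xs, r, beta, idx, thr, denom, xx,
                                    tol_eff, budget)
            total_sweeps += sweeps
        g = Xs.T @ r
        viol = _kkt_terms(g, beta, lam, alpha, w, included)
        bad = viol > eps
        if not bad.any():
            converged = True
            break
        if total_sweeps >= max_sweeps:
            break
        new = bad & ~cand
        cand |= bad
        if not new.any():
            tol_eff *= 0.25  # drift only: tighten and re-sweep
    return beta, r, total_sweeps, converged


def fit_weighted_enet(X, y, lam: float, alpha: float = 0.5, weights=None, *,
                      standardize: bool = True, tol: float = 1e-7,
                      max_sweeps: int = 100_000,
                      warm_start: ElasticNetFit | None = None) -> ElasticNetFit:
    """Minimize the weighted elastic-net PRSS by cyclic coordinate descent.

    Parameters
    ----------
    X : GenotypeMatrix or (n, p) array
    y : (n,) response
    lam : penalty strength (raw-PRSS convention, see module docstring)
    alpha : ridge/lasso mixing in [0, 1] (0 = ridge, 1 = lasso)
    weights : None (unit), (p,) array applied literally, or PenaltyWeights
        (mean-1 rescaled weights with exclusions applied)
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.size != Xm.shape[0]:
        raise ValueError("y must be a vector with one entry per row of X")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if not np.isfinite(lam) or lam < 0:
        raise ValueError("lam must be a non-negative finite number")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n, p = Xm.shape
    w, excluded = _resolve_weights(weights, p)

    Xs, x_mean, x_scale, zero_var = _standardize(Xm, standardize)
    included = ~excluded & ~zero_var
    y_mean = y.mean()
    yc = y - y_mean
    xx = np.einsum("ij,ij->j", Xs, Xs)

    beta0 = warm_start.beta_std if warm_start is not None else None
    beta, r, sweeps, converged = _fit_std(Xs, yc, lam, alpha, w, included,
                                          xx, tol, max_sweeps, beta=beta0)
    obj = _objective(r, beta, lam, alpha, w, included)
    coef = np.where(included, beta / x_scale, 0.0)
    intercept = float(y_mean - coef @ x_mean)
    return ElasticNetFit(intercept=intercept, coefficients=coef, lam=lam,
                         alpha=alpha, objective=obj, n_sweeps=sweeps,
                         converged=converged, beta_std=beta, x_mean=x_mean,
                         x_scale=x_scale, y_mean=float(y_mean))


def kkt_max_violation(fit: ElasticNetFit, X, y, weights=None) -> float:
    """Max KKT residual of a fit, normalized by the gradient scale.

    The residual is evaluated on the internal standardized scale; the
    returned value is ``max_j viol_j / max(1, |2 X'y|_inf)`` so a certified
    solution satisfies ``kkt_max_violation <= 1e-6``.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    p = Xm.shape[1]
    w, excluded = _resolve_weights(weights, p)
    Xs = np.asfortranarray((Xm - fit.x_mean) / fit.x_scale)
    zero_var = np.isclose(Xm.std(axis=0), 0.0)
    included = ~excluded & ~zero_var
    yc = y - fit.y_mean
    r = yc - Xs @ fit.beta_std
    g = Xs.T @ r
    viol = _kkt_terms(g, fit.beta_std, fit.lam, fit.alpha, w, included)
    scale = max(1.0, float(np.abs(2.0 * (Xs.T @ yc)).max(initial=0.0)))
    return float(viol.max(initial=0.0) / scale)


def objective_sweep_trace(X, y, lam, alpha, weights=None, n_sweeps: int = 10,
                          standardize: bool = True) -> np.ndarray:
    """PRSS after each full cyclic sweep from a cold start (no screening).

    Uses the same kernel as the fitting routine, one sweep at a time over
    every included coordinate, so descent of this trace certifies descent of
    the production updates.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    n, p = Xm.shape
    w, excluded = _resolve_weights(weights, p)
    Xs, x_mean, x_scale, zero_var = _standardize(Xm, standardize)
    included = ~excluded & ~zero_var
    yc = y - y.mean()
    xx = np.einsum("ij,ij->j", Xs, Xs)
    wf = np.where(np.isfinite(w), w, 0.0)
    thr = np.where(included, 0.5 * lam * alpha * wf, np.inf)
    denom = np.where(included, xx + lam * (1.0 - alpha) * wf, 0.0)
    beta = np.zeros(p)
    r = yc.copy()
    idx = np.flatnonzero(included).astype(np.int64)
    out = np.empty(n_sweeps)
    for s in range(n_sweeps):
        cd_cycle(Xs, r, beta, idx, thr, denom, xx, 0.0, 1)
        out[s] = _objective(r, beta, lam, alpha, w, included)
    return out


# ---------------------------------------------------------------------------
# lambda path and cross-validation
# ---------------------------------------------------------------------------

def compute_lambda_path(X, y, alpha: float, weights=None,
                        n_lambda: int = 100,
                        lambda_min_ratio: float | None = None,
                        standardize: bool = True) -> np.ndarray:
    """Log-spaced lambda grid from lambda_max down to a fraction of it.

    ``lambda_max = max_j 2 |x_j . y| / (alpha_eff * w_j)`` on the centered
    (and by default scaled) data; alpha_eff floors alpha at 0.001 so a ridge
    path has a finite top.  Default ``lambda_min_ratio`` is 1e-2 when n < p,
    else 1e-4.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    n, p = Xm.shape
    w, excluded = _resolve_weights(weights, p)
    if np.isclose(y.std(), 0.0):
        raise ValueError("response is constant; no lambda path exists")
    Xs, _, _, zero_var = _standardize(Xm, standardize)
    included = ~excluded & ~zero_var
    if not included.any():
        raise ValueError("no marker with a finite weight and variance")
    yc = y - y.mean()
    alpha_eff = max(alpha, ALPHA_FLOOR)
    g = np.abs(2.0 * (Xs.T @ yc))
    pos = included & (w > 0)  # zero-weight markers are never thresholded out
    if not pos.any():
        raise ValueError("every surviving marker is unpenalized (weight 0); "
                         "lambda_max is undefined")
    with np.errstate(divide="ignore"):
        lam_max = np.max(g[pos] / (alpha_eff * w[pos]))
    if not np.isfinite(lam_max) or lam_max <= 0:
        raise ValueError("cannot determine lambda_max (all weights zero or "
                         "response orthogonal to every marker)")
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-2 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _path_std(Xs, yc, grid, alpha, w, included, xx, tol, max_sweeps):
    """Warm-started path on standardized data; returns (p, L) beta matrix."""
    p = xx.size
    B = np.empty((p, grid.size))
    sweeps = np.empty(grid.size, dtype=int)
    conv = np.empty(grid.size, dtype=bool)
    grad_scale = max(1.0, float(np.abs(2.0 * (Xs.T @ yc)).max(initial=0.0)))
    beta = None
    for k, lam in enumerate(grid):
        beta, _r, s, c = _fit_std(Xs, yc, lam, alpha, w, included, xx,
                                  tol, max_sweeps, beta=beta,
                                  grad_scale=grad_scale)
        B[:, k] = beta
        sweeps[k] = s
        conv[k] = c
    return B, sweeps, conv


def fit_lambda_path(X, y, alpha: float, weights=None, grid=None,
                    n_lambda: int = 100, lambda_min_ratio: float | None = None,
                    standardize: bool = True, tol: float = 1e-7,
                    max_sweeps: int = 100_000) -> LambdaPath:
    """Fit the full regularization path with warm starts (largest lam first)."""
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    if grid is None:
        grid = compute_lambda_path(Xm, y, alpha, weights, n_lambda,
                                   lambda_min_ratio, standardize)
    grid = np.asarray(grid, dtype=float)
    p = Xm.shape[1]
    w, excluded = _resolve_weights(weights, p)
    Xs, x_mean, x_scale, zero_var = _standardize(Xm, standardize)
    included = ~excluded & ~zero_var
    y_mean = y.mean()
    yc = y - y_mean
    xx = np.einsum("ij,ij->j", Xs, Xs)
    B, sweeps, conv = _path_std(Xs, yc, grid, alpha, w, included, xx,
                                tol, max_sweeps)
    fits = []
    for k, lam in enumerate(grid):
        beta = B[:, k]
        r = yc - Xs @ beta
        coef = np.where(included, beta / x_scale, 0.0)
        fits.append(ElasticNetFit(
            intercept=float(y_mean - coef @ x_mean), coefficients=coef,
            lam=float(lam), alpha=alpha,
            objective=_objective(r, beta, lam, alpha, w, included),
            n_sweeps=int(sweeps[k]), converged=bool(conv[k]),
            beta_std=beta.copy(), x_mean=x_mean, x_scale=x_scale,
            y_mean=float(y_mean)))
    return LambdaPath(grid=grid, fits=fits)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Balanced random fold assignment: a permutation cut into k blocks."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"n = {n} < k = {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    assign[perm] = np.arange(n) % k
    return assign


def cross_validate_lambda(X, y, alpha: float, weights=None, k: int = 10,
                          seed: int = 0, grid=None, n_lambda: int = 100,
                          lambda_min_ratio: float | None = None,
                          standardize: bool = True, tol: float = 1e-7,
                          max_sweeps: int = 100_000) -> CVResult:
    """k-fold CV of held-out MSE along the lambda path (grid from full data)."""
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    n, p = Xm.shape
    if grid is None:
        grid = compute_lambda_path(Xm, y, alpha, weights, n_lambda,
                                   lambda_min_ratio, standardize)
    grid = np.asarray(grid, dtype=float)
    assign = make_folds(n, k, seed)
    w, excluded = _resolve_weights(weights, p)
    L = grid.size
    fold_mse = np.empty((k, L))
    for f in range(k):
        trn = assign != f
        val = ~trn
        Xt, yt = Xm[trn], y[trn]
        Xs, x_mean, x_scale, zero_var = _standardize(Xt, standardize)
        included = ~excluded & ~zero_var
        y_mean = yt.mean()
        yc = yt - y_mean
        xx = np.einsum("ij,ij->j", Xs, Xs)
        B, _, _ = _path_std(Xs, yc, grid, alpha, w, included, xx,
                            tol, max_sweeps)
        coefs = np.where(included[:, None], B / x_scale[:, None], 0.0)
        intercepts = y_mean - x_mean @ coefs
        preds = Xm[val] @ coefs + intercepts  # (n_val, L)
        fold_mse[f] = np.mean((y[val][:, None] - preds) ** 2, axis=0)
    mean = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(mean))
    lam_min = float(grid[i_min])
    ok = mean <= mean[i_min] + se[i_min]
    lam_1se = float(grid[np.flatnonzero(ok)[0]])  # grid decreasing
    return CVResult(grid=grid, cv_mse_mean=mean, cv_mse_se=se,
                    lambda_min=lam_min, lambda_1se=lam_1se,
                    fold_assignment=assign, seed=seed)


def predict(fit: ElasticNetFit, X_new) -> np.ndarray:
    """Predicted responses ``b0 + X_new . b`` on the original trait scale."""
    Xm = _as_matrix(X_new)
    if Xm.shape[1] != fit.coefficients.size:
        raise ValueError(f"X_new has {Xm.shape[1]} columns, "
                         f"fit expects {fit.coefficients.size}")
    return fit.intercept + Xm @ fit.coefficients
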