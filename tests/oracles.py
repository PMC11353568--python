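"""Independent reference implementations used as test oracles.

These deliberately avoid the package's coordinate-descent code path: the
elastic-net oracle is a FISTA proximal-gradient minimizer of the same
penalized residual sum of squares, written directly from the objective.
"""

import numpy as np


def prss(Xc, yc, beta, lam, alpha, w):
    r = yc - Xc @ beta
    pen = (1 - alpha) * np.sum(w * beta ** 2) + alpha * np.sum(w * np.abs(beta))
    return float(r @ r + lam * pen)


def prox_gradient_enet(Xc, yc, lam, alpha, w, max_iter=200_000, tol=1e-13):
    """FISTA on PRSS(beta) = ||yc - Xc beta||^2 + lam[(1-a) w b^2 + a w |b|].

    Expects centered Xc and yc (the intercept is handled by centering).
    """
    n, p = Xc.shape
    w = np.asarray(w, dtype=float)
    L = 2.0 * np.linalg.norm(Xc, 2) ** 2 + 2.0 * lam * (1 - alpha) * w.max()
    step = 1.0 / L
    beta = np.zeros(p)
    z = beta.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = -2.0 * (Xc.T @ (yc - Xc @ z)) + 2.0 * lam * (1 - alpha) * w * z
        u = z - step * grad
        gamma = step * lam * alpha * w
        new = np.sign(u) * np.maximum(np.abs(u) - gamma, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = new + ((t - 1.0) / t_new) * (new - beta)
        delta = np.abs(new - beta).max()
        beta, t = new, t_new
        if delta < tol:
            break
    return beta


def ridge_closed_form(X, y, lam, w):
    """(Xc'Xc + lam diag(w))^-1 Xc'yc on centered data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return np.linalg.solve(Xc.T @ Xc + lam * np.diag(w), Xc.T @ yc)
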