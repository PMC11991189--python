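"""Independent reference implementations used only to check results.

These deliberately share no code with the package: the elastic net is
solved by accelerated proximal gradient (FISTA) instead of coordinate
descent, and small problems are verified by exhaustive search.
"""

import numpy as np


def enet_objective(X, y, beta, alpha, rho):
    """(1/(2N))||y - X'b||^2 + alpha rho ||b||_1 + (alpha(1-rho)/2)||b||_2^2
    with X as predictors x observations."""
    N = X.shape[1]
    r = y - beta @ X
    return (r @ r) / (2 * N) + alpha * rho * np.abs(beta).sum() \
        + 0.5 * alpha * (1 - rho) * beta @ beta


def prox_gradient_enet(X, y, alpha, rho, max_iter=200_000, tol=1e-14):
    """FISTA on the scaled elastic-net objective."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    p, N = X.shape
    lip = np.linalg.eigvalsh(X @ X.T).max() / N + alpha * (1 - rho)
    step = 1.0 / lip
    thresh = step * alpha * rho
    b = np.zeros(p)
    z = b.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = X @ (z @ X - y) / N + alpha * (1 - rho) * z
        u = z - step * grad
        b_new = np.sign(u) * np.maximum(np.abs(u) - thresh, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = b_new + ((t - 1) / t_new) * (b_new - b)
        if np.abs(b_new - b).max() < tol:
            return b_new
        b, t = b_new, t_new
    return b


def soft_threshold(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def line_search_1d(x, y, alpha, rho, lo=-10, hi=10, n=2_000_001):
    """Exhaustive scan of the 1-predictor elastic-net objective."""
    grid = np.linspace(lo, hi, n)
    N = len(y)
    resid = y[None, :] - grid[:, None] * x[None, :]
    obj = (resid ** 2).sum(axis=1) / (2 * N) + alpha * rho * np.abs(grid) \
        + 0.5 * alpha * (1 - rho) * grid ** 2
    return grid[int(np.argmin(obj))]
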