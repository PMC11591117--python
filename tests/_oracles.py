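"""Independent reference computations used by multiple test modules."""

import numpy as np
from scipy import optimize


def first_canonical_correlation_oracle(X, Y, n_starts=6):
    """Numerically maximize corr(X a, Y b) over weight pairs.

    Derivative-free multistart optimization, independent of any
    whitening/SVD code path; correlation is scale-invariant so the
    search is unconstrained.
    """
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)

    def neg_corr(w):
        a, b = w[: X.shape[1]], w[X.shape[1] :]
        u, v = Xc @ a, Yc @ b
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom < 1e-12:
            return 0.0
        return -(u @ v) / denom

    best = 0.0
    rng = np.random.default_rng(0)
    for _ in range(n_starts):
        w0 = rng.standard_normal(X.shape[1] + Y.shape[1])
        res = optimize.minimize(
            neg_corr,
            w0,
            method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12},
        )
        # quasi-Newton from the same start: the objective is smooth and
        # scale-invariant, and the simplex can stall at degenerate scales
        polish = optimize.minimize(neg_corr, w0, method="BFGS",
                                   options={"maxiter": 500})
        best = max(best, -res.fun, -polish.fun)
    return best


def direct_eigen_correlations(X, Y):
    """Canonical correlations from the unsymmetric covariance-product
    eigenproblem — a second independent route."""
    n = X.shape[0]
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.solve(Cxx, Cxy) @ np.linalg.solve(Cyy, Cxy.T)
    ev = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    return np.sqrt(np.clip(ev, 0.0, None))
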