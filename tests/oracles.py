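"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def coordinate_descent_enet(X, y, mixing, lam, n_iter=50_000, tol=1e-14):
    """Cyclic coordinate descent for the elastic net, written from scratch.

    Minimizes ``1/(2n) ||y - b0 - X w||^2 + lam * (mixing ||w||_1 +
    (1 - mixing)/2 ||w||_2^2)`` with soft-threshold updates on centered
    data.  Deliberately naive (full residual recomputation per coordinate)
    so it shares no code path with the implementation it checks.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    col_ss = (Xc ** 2).sum(axis=0) / n
    w = np.zeros(p)
    for _ in range(n_iter):
        w_prev = w.copy()
        for j in range(p):
            partial = yc - Xc @ w + Xc[:, j] * w[j]
            rho = Xc[:, j] @ partial / n
            thresholded = np.sign(rho) * max(abs(rho) - lam * mixing, 0.0)
            w[j] = thresholded / (col_ss[j] + lam * (1.0 - mixing))
        if np.max(np.abs(w - w_prev)) < tol:
            break
    intercept = ym - xm @ w
    return w, float(intercept)


def pearson_t_pvalue(x, y):
    """Per-pair Pearson r, t statistic and two-sided p by the textbook formulas."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, t, p
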