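"""Small central-difference derivatives for covariance estimation."""

from __future__ import annotations

import numpy as np


def approx_hess(fun, x, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function at ``x``.

    Step per coordinate scales with magnitude; accurate to O(h^2), which is
    ample for Wald covariance at a smooth optimum.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = eps * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    # diagonal
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
    # off-diagonal
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H
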