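"""Shared numerical helpers: finite-difference derivatives of objectives."""

from __future__ import annotations

import numpy as np


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(1.0, np.abs(x))


def central_gradient(f, x, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def central_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference Hessian with step rel_step*max(1,|x_i|)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, rel_step)
    H = np.empty((n, n))
    f0 = f(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)
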