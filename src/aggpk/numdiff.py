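"""Central-difference derivatives used for Hessians and moment gradients.

Steps are taken on the natural (untransformed) parameter scale with a
relative step per coordinate, so information matrices and standard errors
refer to the parameters as reported.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["central_gradient", "central_hessian"]


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(np.abs(x), 1e-8)


def central_gradient(fun: Callable, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.empty_like(x)
    for j in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        g[j] = (fun(xp) - fun(xm)) / (2.0 * h[j])
    return g


def _hessian_once(fun: Callable, x: np.ndarray, h: np.ndarray, f0: float) -> np.ndarray:
    p = x.size
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for j in range(p):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        fp[j] = fun(xp)
        fm[j] = fun(xm)
        H[j, j] = (fp[j] - 2.0 * f0 + fm[j]) / h[j] ** 2
    for j in range(p):
        for k in range(j + 1, p):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[j, k]] += [h[j], h[k]]
            xpm[j] += h[j]
            xpm[k] -= h[k]
            xmp[j] -= h[j]
            xmp[k] += h[k]
            xmm[[j, k]] -= [h[j], h[k]]
            H[j, k] = H[k, j] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                4.0 * h[j] * h[k]
            )
    return H


def central_hessian(
    fun: Callable,
    x: np.ndarray,
    rel_step: float = 1e-4,
    richardson: bool = False,
) -> np.ndarray:
    """Symmetric central-difference Hessian of a scalar function.

    With ``richardson=True`` the O(h^2) stencil is evaluated at h and h/2 and
    extrapolated, ``(4 H(h/2) - H(h)) / 3``, removing the leading error term.
    """
    x = np.asarray(x, dtype=float)
    f0 = fun(x)
    h = _steps(x, rel_step)
    H = _hessian_once(fun, x, h, f0)
    if richardson:
        H2 = _hessian_once(fun, x, 0.5 * h, f0)
        H = (4.0 * H2 - H) / 3.0
    return 0.5 * (H + H.T)
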