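"""Weighted local linear regression (loess) used by the normalization step.

Degree-1 local polynomial with tricube kernel weights multiplied by
per-point fit weights.  The neighborhood is the ``ceil(span * n)`` points
nearest in x; fit weights do not enter neighborhood selection.
"""

from __future__ import annotations

import numpy as np

__all__ = ["weighted_loess"]


def weighted_loess(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    span: float = 0.7,
    max_eval: int | None = None,
) -> np.ndarray:
    """Fit y ~ x locally and return fitted values at each input x.

    Parameters
    ----------
    x, y
        1-D arrays of equal length.
    weights
        Non-negative fit weights, multiplied into the tricube kernel
        weights inside each local fit.  Default: all ones.
    span
        Fraction of points in each local neighborhood, in (0, 1].
    max_eval
        If set and smaller than n, the local fit is evaluated at this many
        points spread over the sorted x order and linearly interpolated in
        between (a speed approximation for large inputs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have the same length")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != n:
            raise ValueError("weights must match x in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    if n < 2:
        return y.copy()

    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], y[order], w[order]
    k = int(np.ceil(span * n))
    k = min(max(k, 2), n)

    if max_eval is not None and max_eval < n:
        eval_idx = np.unique(np.linspace(0, n - 1, max_eval).round().astype(np.intp))
    else:
        eval_idx = np.arange(n, dtype=np.intp)

    # Contiguous nearest-k window in sorted x: slide the left edge forward
    # while the point just beyond the window is closer than the left edge.
    starts = np.empty(eval_idx.size, dtype=np.intp)
    left = 0
    for pos, i in enumerate(eval_idx):
        while left + k < n and xs[i] - xs[left] > xs[left + k] - xs[i]:
            left += 1
        starts[pos] = left

    idx = starts[:, None] + np.arange(k)[None, :]  # (n_eval, k)
    xw = xs[idx]
    yw = ys[idx]
    fw = ws[idx]

    x_eval = xs[eval_idx]
    dist = np.abs(xw - x_eval[:, None])
    h = dist.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(h > 0, dist / h, 0.0)
    tri = np.clip(1.0 - u**3, 0.0, None) ** 3
    wt = tri * fw
    # Degenerate all-zero weight rows (e.g. all fit weights 0): fall back
    # to the plain tricube kernel so the fit is still defined.
    zero_rows = wt.sum(axis=1) <= 0
    if np.any(zero_rows):
        wt[zero_rows] = tri[zero_rows] if np.any(tri[zero_rows]) else 1.0

    # Closed-form weighted linear fit per row, evaluated at xs[i].
    sw = wt.sum(axis=1)
    xm = (wt * xw).sum(axis=1) / sw
    ym = (wt * yw).sum(axis=1) / sw
    xc = xw - xm[:, None]
    sxx = (wt * xc**2).sum(axis=1)
    sxy = (wt * xc * (yw - ym[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, 0.0)
    fitted_eval = ym + slope * (x_eval - xm)

    if eval_idx.size < n:
        fitted_sorted = np.interp(xs, x_eval, fitted_eval)
        fitted_sorted[eval_idx] = fitted_eval
    else:
        fitted_sorted = fitted_eval

    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted
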