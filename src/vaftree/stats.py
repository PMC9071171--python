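"""Small statistical helpers: weighted two-sample comparison.

Used to compare summary statistics of point-process trees against the
importance-weighted forward-simulation oracle (whose samples carry sojourn
weights).
"""

from __future__ import annotations

import numpy as np

__all__ = ["weighted_ks_2samp"]


def weighted_ks_2samp(x, y, x_weights=None, y_weights=None, alpha=0.01):
    """Two-sample Kolmogorov-Smirnov test allowing importance weights.

    Computes the sup-distance between the (weighted) empirical CDFs and
    compares it with the large-sample critical value at level ``alpha``,
    using Kish effective sample sizes for the weighted samples.

    Returns ``(statistic, critical_value, reject)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wx = np.ones_like(x) if x_weights is None else np.asarray(x_weights, float)
    wy = np.ones_like(y) if y_weights is None else np.asarray(y_weights, float)
    if np.any(wx < 0) or np.any(wy < 0):
        raise ValueError("weights must be non-negative")

    grid = np.sort(np.concatenate([x, y]))
    ix = np.argsort(x)
    iy = np.argsort(y)
    cx = np.concatenate([[0.0], np.cumsum(wx[ix])])
    cy = np.concatenate([[0.0], np.cumsum(wy[iy])])
    Fx = cx[np.searchsorted(x[ix], grid, side="right")] / cx[-1]
    Fy = cy[np.searchsorted(y[iy], grid, side="right")] / cy[-1]
    stat = float(np.max(np.abs(Fx - Fy)))

    n_eff_x = float(wx.sum() ** 2 / np.sum(wx**2))
    n_eff_y = float(wy.sum() ** 2 / np.sum(wy**2))
    c_alpha = np.sqrt(-0.5 * np.log(alpha / 2.0))
    crit = float(c_alpha * np.sqrt((n_eff_x + n_eff_y) / (n_eff_x * n_eff_y)))
    return stat, crit, stat > crit
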