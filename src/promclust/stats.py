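"""Shared statistical primitives.

The cluster-association test used throughout the package is a two-sided
Welch (unequal-variance) t-test comparing the values of one matrix row
inside a column cluster against the values outside it.  The degenerate
cases that arise on peak-call matrices (rows that are exactly constant
on one or both sides) are given a fixed, finite convention so that
-log10(p) bar heights stay plottable.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _sps

#: p-value reported when the two groups are constant but different
#: (the test statistic is formally infinite).
P_FLOOR = 1e-300


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test of ``mean(x) - mean(y)``.

    Returns ``(t, p)``.  Degenerate inputs follow a fixed convention:
    both groups constant and equal -> ``(0.0, 1.0)``; constant but
    different -> ``(±inf, P_FLOOR)``.

    Raises ``ValueError`` if either group has fewer than two values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("welch_t requires at least two values per group")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return 0.0, 1.0
        return math.copysign(math.inf, mx - my), P_FLOOR
    t = (mx - my) / math.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2 * se2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    p = 2.0 * _sps.t.sf(abs(t), df)
    p = max(p, P_FLOOR)
    return float(t), float(p)


def neglog10p(p: float) -> float:
    """Bar height used next to the heatmaps: -log10(p)."""
    return -math.log10(p)
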