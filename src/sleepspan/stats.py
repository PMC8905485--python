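"""Two-sample t statistics with degenerate-input handling.

Both the cluster contrasts and the DST before/after comparisons use the
classical Student (pooled-variance) two-sample two-tailed t test.  The
helpers here wrap :mod:`scipy.stats` and pin down the zero-variance corner
cases: two identical degenerate samples compare as t=0, p=1; degenerate
samples with different means as t=inf, p=0.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = ["two_sample_t", "t_from_moments"]


def two_sample_t(x, y, *, equal_var: bool = True) -> tuple[float, float]:
    """Student two-sample two-tailed t test on raw observations.

    Returns ``(t, p)``.  Requires at least two observations per sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("two_sample_t: need >= 2 observations per sample")
    mx, my = float(np.mean(x)), float(np.mean(y))
    # spread at rounding level counts as degenerate, not as signal
    tiny = 1e-12 * max(1.0, abs(mx), abs(my))
    if np.std(x) <= tiny and np.std(y) <= tiny:
        if abs(mx - my) <= tiny:
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def t_from_moments(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance t test from summary moments (means, SDs, sizes).

    Useful for checking printed summary tables: the t statistic depends on
    the data only through these moments.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("t_from_moments: need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0.0:
        if mean1 == mean2:
            return 0.0, 1.0
        return math.inf, 0.0
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
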