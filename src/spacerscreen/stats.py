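"""Welch's unequal-variance t-test and Pearson correlation.

Both statistics are computed directly from their definitions (sample SDs use
the n-1 denominator); only the t-distribution tail is delegated to the
regularized incomplete beta function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betainc


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def welch_t_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> WelchResult:
    """Welch's t-test with Welch-Satterthwaite degrees of freedom.

    ``t = (mx - my) / sqrt(vx/nx + vy/ny)``; the two-sided p-value is
    ``I_{df/(df+t^2)}(df/2, 1/2)``, the regularized incomplete beta tail of
    the t distribution.  Two samples with zero variance and equal means give
    the degenerate ``t=0, p=1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = float(np.var(x, ddof=1))
    vy = float(np.var(y, ddof=1))
    mx, my = float(np.mean(x)), float(np.mean(y))
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p_two = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    if alternative == "two-sided":
        p = p_two
    elif alternative == "greater":
        p = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    elif alternative == "less":
        p = p_two / 2.0 if t < 0 else 1.0 - p_two / 2.0
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WelchResult(t=t, df=df, p=min(max(p, 0.0), 1.0))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient, ``cov(x, y) / (sd_x * sd_y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one of the samples")
    r = float(dx @ dy) / (sx * sy)
    return min(max(r, -1.0), 1.0)
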