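"""Logicle (biexponential) transform for fluorescence intensities.

The logicle scale is linear around zero and logarithmic at high intensity,
which makes fluorescence distributions (including negatives produced by
compensation) approximately homoscedastic.  The scale y in [0, 1] relates to
the data value x through the biexponential

    B(y) = a*exp(b*y) - c*exp(-d*y) - f      for y >= x1,
    B(y) = -B(2*x1 - y)                      for y <  x1 (odd around x1),

with the constants determined by the four user parameters: T (top of scale),
M (number of decades), W (linearization width in decades) and A (extra
negative decades).  The forward transform inverts B numerically; here by
bisection to a tolerance of 1e-10 on the scale, vectorized over the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class LogicleParams:
    T: float          # top of scale (maximum expected data value)
    M: float = 4.5    # total decades
    W: float = 0.5    # linearization width, decades
    A: float = 0.0    # additional negative decades

    def __post_init__(self):
        if self.T <= 0 or self.M <= 0 or self.W < 0 or self.A < 0:
            raise ValueError(f"invalid logicle parameters {self}")


class LogicleTransform:
    """Callable forward/inverse logicle transform for fixed parameters."""

    def __init__(self, params: LogicleParams):
        self.params = params
        T, M, W, A = params.T, params.M, params.W, params.A
        self._w = W / (M + A)
        self._x2 = A / (M + A)
        self._x1 = self._x2 + self._w
        x0 = self._x2 + 2 * self._w
        self._b = (M + A) * np.log(10.0)
        b, w = self._b, self._w
        if w == 0:
            self._d = b
        else:
            # solve 2*(ln d - ln b) + w*(b + d) = 0 for d in (0, b)
            fn = lambda d: 2 * (np.log(d) - np.log(b)) + w * (b + d)
            self._d = brentq(fn, 1e-12, b, xtol=1e-14, rtol=1e-14)
        d = self._d
        c_a = np.exp(x0 * (b + d))
        f_a = np.exp(b * self._x1) - c_a / np.exp(d * self._x1)
        self._a = T / (np.exp(b) - f_a - c_a / np.exp(d))
        self._c = c_a * self._a
        self._f = f_a * self._a

    def inverse(self, y):
        """Biexponential B(y): scale -> data value."""
        y = np.asarray(y, dtype=float)
        yy = np.where(y >= self._x1, y, 2 * self._x1 - y)
        v = (self._a * np.exp(self._b * yy)
             - self._c * np.exp(-self._d * yy) - self._f)
        return np.where(y >= self._x1, v, -v)

    def __call__(self, x):
        """Forward transform: data value -> scale, by bisection (tol 1e-10)."""
        x = np.asarray(x, dtype=float)
        lo = np.full(x.shape, -1.0)
        hi = np.full(x.shape, 2.0)
        # expand upper bracket for values far above T
        for _ in range(20):
            over = self.inverse(hi) < x
            if not over.any():
                break
            hi = np.where(over, hi + 1.0, hi)
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            below = self.inverse(mid) < x
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
            if float(np.max(hi - lo)) < 1e-10:
                break
        return 0.5 * (lo + hi)


def estimate_logicle(values, M: float = 4.5) -> LogicleParams:
    """Auto-estimate logicle parameters from data.

    T = observed maximum; W from the 5th percentile r of the negative values,
    W = max(0, (M - log10(T/|r|)) / 2), defaulting to 0.5 when there are no
    negatives; A = 0.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    T = float(v.max())
    if T <= 0:
        raise ValueError("all values <= 0; logicle needs a positive top of "
                         "scale — consider offsetting the feature")
    neg = v[v < 0]
    if neg.size:
        r = float(np.percentile(neg, 5))
        W = max(0.0, (M - np.log10(T / abs(r))) / 2)
    else:
        W = 0.5
    return LogicleParams(T=T, M=M, W=W, A=0.0)
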