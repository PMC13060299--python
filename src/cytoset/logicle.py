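"""Logicle (biexponential) intensity transform.

The logicle scale is the cytometry community's standard display/analysis
transform: approximately linear around zero (width ``W`` decades) and
logarithmic at high intensity, covering ``M`` decades up to the instrument
top-of-scale ``T`` with ``A`` additional decades of negative range.

The transform maps a raw value ``x`` to the scale position ``y`` solving
``B(y) = x`` where ``B`` is the biexponential

    B(y) = a * exp(b*y) - c * exp(-d*y) - f,

with the coefficients derived from ``(T, W, M, A)`` so that ``B(1) = T``
and ``B`` is linear near ``y = (W + A)/(M + A)`` (the position of raw
value 0).  ``B`` is strictly increasing, so the forward transform is the
unique root; we compute it with a vectorised bisection.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

__all__ = ["LogicleTransform"]


class LogicleTransform:
    """Callable logicle scale with the community-default parameters.

    Parameters
    ----------
    T : top of scale value (raw units), default 262144 (18-bit).
    W : linearisation width in decades, default 0.5.
    M : total display range in decades, default 4.5.
    A : additional negative decades, default 0.
    """

    def __init__(self, T: float = 262144.0, W: float = 0.5, M: float = 4.5, A: float = 0.0):
        if T <= 0 or M <= 0 or W < 0 or W > M / 2 or A < 0:
            raise ValueError("invalid logicle parameters")
        self.T, self.W, self.M, self.A = float(T), float(W), float(M), float(A)

        w = W / (M + A)
        x2 = A / (M + A)
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        b = (M + A) * math.log(10.0)
        if w == 0.0:
            d = b
        else:
            # d solves 2*(ln d - ln b) + w*(d + b) = 0 on (0, b)
            d = brentq(lambda dd: 2.0 * (math.log(dd) - math.log(b)) + w * (dd + b),
                       1e-12, b, xtol=1e-15)
        c_a = math.exp(x0 * (b + d))
        mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
        a = T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
        # f fixes B(x1) = 0 so that raw 0 sits at scale position x1
        self._a, self._b, self._c, self._d, self._f = a, b, c_a * a, d, mf_a * a
        self._x1 = x1

    # B and its root --------------------------------------------------------
    def inverse(self, y):
        """Biexponential ``B(y)``: scale position -> raw value."""
        y = np.asarray(y, dtype=np.float64)
        return self._a * np.exp(self._b * y) - self._c * np.exp(-self._d * y) - self._f

    def scale(self, x):
        """Raw value -> scale position in (roughly) [0, 1]; vectorised."""
        x = np.asarray(x, dtype=np.float64)
        lo = np.full(x.shape, -1.5)
        hi = np.full(x.shape, 2.5)
        for _ in range(70):  # 4/2^70 << float64 eps
            mid = 0.5 * (lo + hi)
            below = self.inverse(mid) < x
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)

    __call__ = scale

    def params(self) -> dict:
        return {"T": self.T, "W": self.W, "M": self.M, "A": self.A}

    def __repr__(self):  # pragma: no cover
        return f"LogicleTransform(T={self.T}, W={self.W}, M={self.M}, A={self.A})"
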