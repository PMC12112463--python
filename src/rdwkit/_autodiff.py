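"""Forward-mode dual numbers for differentiating scalar box losses.

The box losses (IoU, CIoU, NWD, their mixtures) are scalar functions of a
handful of coordinates, so forward-mode differentiation — one pass per input
coordinate — is both exact and cheap. A :class:`Dual` carries a value and the
derivative of that value with respect to a single chosen seed coordinate;
the loss code is written generically over floats and Duals so the same
expressions serve evaluation and differentiation.

Piecewise primitives (``maximum``/``minimum``) use the one-sided derivative of
the active branch, which is the standard subgradient choice away from ties.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Dual", "value", "exp", "sqrt", "atan", "maximum", "minimum", "gradient"]


class Dual:
    """A number together with its derivative w.r.t. one seed variable."""

    __slots__ = ("val", "dot")

    def __init__(self, val: float, dot: float = 0.0):
        self.val = float(val)
        self.dot = float(dot)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dual({self.val}, {self.dot})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        o = _as_dual(other)
        return Dual(self.val + o.val, self.dot + o.dot)

    __radd__ = __add__

    def __sub__(self, other):
        o = _as_dual(other)
        return Dual(self.val - o.val, self.dot - o.dot)

    def __rsub__(self, other):
        o = _as_dual(other)
        return Dual(o.val - self.val, o.dot - self.dot)

    def __mul__(self, other):
        o = _as_dual(other)
        return Dual(self.val * o.val, self.dot * o.val + self.val * o.dot)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_dual(other)
        v = self.val / o.val
        return Dual(v, (self.dot - v * o.dot) / o.val)

    def __rtruediv__(self, other):
        return _as_dual(other).__truediv__(self)

    def __pow__(self, p: float):
        if isinstance(p, Dual):
            raise TypeError("dual exponents are not supported")
        return Dual(self.val**p, p * self.val ** (p - 1) * self.dot)

    def __neg__(self):
        return Dual(-self.val, -self.dot)

    # -- comparisons (on values; used for branch selection) ---------------
    def __lt__(self, other):
        return self.val < value(other)

    def __le__(self, other):
        return self.val <= value(other)

    def __gt__(self, other):
        return self.val > value(other)

    def __ge__(self, other):
        return self.val >= value(other)


def _as_dual(x) -> Dual:
    return x if isinstance(x, Dual) else Dual(float(x))


def value(x) -> float:
    """Strip the derivative part; identity on plain numbers."""
    return x.val if isinstance(x, Dual) else float(x)


def exp(x):
    if isinstance(x, Dual):
        e = math.exp(x.val)
        return Dual(e, e * x.dot)
    return math.exp(x)


def sqrt(x):
    if isinstance(x, Dual):
        s = math.sqrt(x.val)
        # guarded slope at the origin: sqrt is the only kink the losses
        # evaluate exactly at zero (identical boxes), where the true loss
        # minimum sits, so a zero derivative is the correct descent choice
        return Dual(s, 0.0 if s == 0.0 else x.dot / (2.0 * s))
    return math.sqrt(x)


def atan(x):
    if isinstance(x, Dual):
        return Dual(math.atan(x.val), x.dot / (1.0 + x.val * x.val))
    return math.atan(x)


def maximum(a, b):
    return a if value(a) >= value(b) else b


def minimum(a, b):
    return a if value(a) <= value(b) else b


def gradient(f: Callable, x: Sequence[float]) -> np.ndarray:
    """Gradient of scalar ``f`` at ``x`` by one forward-mode pass per input."""
    x = [float(v) for v in x]
    g = np.empty(len(x))
    for i in range(len(x)):
        seeded = [Dual(v, 1.0 if j == i else 0.0) for j, v in enumerate(x)]
        g[i] = _as_dual(f(seeded)).dot
    return g
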