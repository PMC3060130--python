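"""Parametrized display-scale transformations used by gate definitions.

All five kinds follow the harmonized (T, M, W, A) parameterization that
gate-interchange files converged on:

``flin``
    f(x) = (x + A) / (T + A) — linear, A is an offset.
``flog``
    f(x) = (1/M) log10(x/T) + 1 — M decades ending at top-of-scale T.
``fasinh``
    f(x) = (asinh(x sinh(M ln 10)/T) + A ln 10) / ((M + A) ln 10) —
    inverse hyperbolic sine with A extra negative decades.
``logicle``
    the inverse of a biexponential B(y) = a e^{by} - c e^{-dy} - f; linear
    of width W decades around zero, logarithmic above.
``hyperlog``
    the inverse of the strictly increasing EH(y) = a e^{by} + c y - f.

Every transform maps its top-of-scale value T to exactly 1 and is
strictly increasing.  Logicle/hyperlog forward values are obtained by
bracketed bisection on the closed-form inverse (the constants are
precomputed per instance); inverse evaluation is closed form.  Display
values outside [0, 1] are extrapolated, not rejected: the underlying
functions are defined there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError

__all__ = ["Transform", "apply_transform", "invert_transform", "KINDS"]

KINDS = ("flin", "flog", "fasinh", "logicle", "hyperlog")

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class Transform:
    """A named scale transformation.

    Parameters
    ----------
    id : str
        Identifier used by gate dimension references.
    kind : str
        One of ``flin``, ``flog``, ``fasinh``, ``logicle``, ``hyperlog``.
    T : float
        Top-of-scale data value (> 0); f(T) = 1.
    M : float
        Number of decades (> 0); unused by ``flin``.
    W : float
        Linearization width in decades (logicle/hyperlog only);
        0 <= W <= M/2, and W > 0 for hyperlog.
    A : float
        Additional negative decades (fasinh/logicle/hyperlog) or the
        linear offset (flin).  For logicle, A >= -W.
    """

    id: str
    kind: str
    T: float
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0
    _c: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        if self.T <= 0:
            raise ValidationError(f"transform {self.id}: T must be > 0")
        if self.kind != "flin" and self.M <= 0:
            raise ValidationError(f"transform {self.id}: M must be > 0")
        if self.kind in ("logicle", "hyperlog"):
            if self.W < 0 or self.W > self.M / 2:
                raise ValidationError(
                    f"transform {self.id}: need 0 <= W <= M/2, got W={self.W}"
                )
            if self.kind == "hyperlog" and self.W == 0:
                raise ValidationError(f"transform {self.id}: hyperlog needs W > 0")
            if self.kind == "logicle" and self.A < -self.W:
                raise ValidationError(f"transform {self.id}: logicle needs A >= -W")
        if self.kind == "fasinh" and self.M + self.A <= 0:
            raise ValidationError(f"transform {self.id}: fasinh needs M + A > 0")
        if self.kind == "flin" and self.T + self.A <= 0:
            raise ValidationError(f"transform {self.id}: flin needs T + A > 0")

    # -- constants for the root-finding kinds, cached per instance --------

    def _constants(self) -> dict:
        if self._c:
            return self._c
        T, M, W, A = self.T, self.M, self.W, self.A
        c: dict = {}
        if self.kind == "logicle":
            w = W / (M + A)
            x2 = A / (M + A)
            x1 = x2 + w
            x0 = x2 + 2 * w
            b = (M + A) * _LN10
            if w == 0:
                d = b
            else:
                # root of 2 ln(d/b) + w (b + d) = 0 in (0, b)
                d = brentq(
                    lambda dd: 2 * (math.log(dd) - math.log(b)) + w * (b + dd),
                    1e-12, b, xtol=1e-14, rtol=8.9e-16,
                )
            c_a = math.exp(x0 * (b + d))
            mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
            a = T / (math.exp(b) - mf_a - c_a / math.exp(d))
            c.update(a=a, b=b, c=c_a * a, d=d, f=mf_a * a, x1=x1, w=w)
        elif self.kind == "hyperlog":
            w = W / (M + A)
            x2 = A / (M + A)
            x1 = x2 + w
            x0 = x2 + 2 * w
            b = (M + A) * _LN10
            e0 = math.exp(b * x0)
            c_a = e0 / w
            f_a = math.exp(b * x1) + c_a * x1
            a = T / (math.exp(b) + c_a - f_a)
            c.update(a=a, b=b, c=c_a * a, f=f_a * a, x1=x1, w=w)
        self._c.update(c)
        return self._c

    # -- closed-form inverse (display -> data) for the biexponential kinds

    def _biexp(self, y: np.ndarray) -> np.ndarray:
        k = self._constants()
        a, b, cc, d, f, x1 = k["a"], k["b"], k["c"], k["d"], k["f"], k["x1"]
        y = np.asarray(y, dtype=np.float64)
        neg = y < x1
        yy = np.where(neg, 2 * x1 - y, y)
        v = a * np.exp(b * yy) - cc * np.exp(-d * yy) - f
        return np.where(neg, -v, v)

    def _eh(self, y: np.ndarray) -> np.ndarray:
        k = self._constants()
        a, b, cc, f, x1 = k["a"], k["b"], k["c"], k["f"], k["x1"]
        y = np.asarray(y, dtype=np.float64)
        neg = y < x1
        yy = np.where(neg, 2 * x1 - y, y)
        v = a * np.exp(b * yy) + cc * yy - f
        return np.where(neg, -v, v)


def _root_forward(t: Transform, x: np.ndarray) -> np.ndarray:
    """Invert the closed-form inverse by vectorized bisection.

    The inverse is strictly increasing, so a bracket can always be grown;
    120 halvings on the display axis leave the residual far below 1e-12.
    """
    inverse = t._biexp if t.kind == "logicle" else t._eh
    x = np.asarray(x, dtype=np.float64)
    lo = np.full(x.shape, -1.0)
    hi = np.full(x.shape, 2.0)
    for _ in range(64):  # widen brackets for extreme inputs
        too_low = inverse(hi) < x
        too_high = inverse(lo) > x
        if not too_low.any() and not too_high.any():
            break
        hi = np.where(too_low, hi + (hi - lo), hi)
        lo = np.where(too_high, lo - (hi - lo), lo)
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        below = inverse(mid) < x
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def apply_transform(t: Transform, x) -> np.ndarray:
    """Map data values to display units (f(T) = 1).

    ``flog`` entries with x <= 0 become NaN with a warning rather than
    raising, so whole channels can be transformed in one call.
    """
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if t.kind == "flin":
        y = (x + t.A) / (t.T + t.A)
    elif t.kind == "flog":
        bad = x <= 0
        if bad.any():
            warnings.warn(
                f"flog transform {t.id}: {int(bad.sum())} value(s) <= 0 set to NaN",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(bad, np.nan, (1.0 / t.M) * np.log10(x / t.T) + 1.0)
    elif t.kind == "fasinh":
        y = (np.arcsinh(x * math.sinh(t.M * _LN10) / t.T) + t.A * _LN10) / (
            (t.M + t.A) * _LN10
        )
    else:
        y = _root_forward(t, x)
    return y[0] if scalar else y


def invert_transform(t: Transform, y) -> np.ndarray:
    """Map display units back to data values (closed form for all kinds)."""
    y = np.asarray(y, dtype=np.float64)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    if t.kind == "flin":
        x = y * (t.T + t.A) - t.A
    elif t.kind == "flog":
        x = t.T * np.power(10.0, t.M * (y - 1.0))
    elif t.kind == "fasinh":
        x = (
            np.sinh((t.M + t.A) * _LN10 * y - t.A * _LN10)
            * t.T
            / math.sinh(t.M * _LN10)
        )
    elif t.kind == "logicle":
        x = t._biexp(y)
    else:
        x = t._eh(y)
    return x[0] if scalar else x
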