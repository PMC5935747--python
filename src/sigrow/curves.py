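"""Forward evaluation of the NSG and BSG sigmoidal growth models.

Two four-parameter growth curves for organism biomass ``w(t)`` (grams) over
time ``t`` (days):

* **NSG** (new sigmoidal growth).  Its growth *rate* is the square of a
  Ratkowsky-type expression with time in place of temperature,

  .. math:: r(t) = c^2 (t - t_b)^2 \\bigl(1 - e^{k (t - t_e)}\\bigr)^2,

  which is zero at the growth start ``t_b`` and the growth end ``t_e``.
  Biomass is the integral of this rate from ``t_b``; the integral has a
  closed form (see :func:`nsg_biomass`) obtained by expanding the square —
  the polynomial term contributes :math:`c^2 (t-t_b)^3/3` and the two
  exponential cross terms integrate to ``u^2 e^{mu}``-type antiderivatives.

* **BSG** (beta sigmoidal growth).  A flexible curve derived from the beta
  distribution function with unit shape exponent,

  .. math:: w(t) = c_m (t - t_b) \\frac{2 t_e - t_m - t}{2 t_e - t_m - t_b}
            \\Bigl(\\frac{t - t_b}{t_m - t_b}\\Bigr)^{(t_m - t_b)/(t_e - t_m)},

  where ``c_m`` is the maximum growth rate, attained at ``t_m``.

Both models reach their maximum biomass ``w_max`` at ``t_e``, so
``w_max = w(t_e)``; ``t_e`` doubles as the time to maturity.  All functions
are vectorised over ``t`` and return scalars for scalar input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ParameterError

__all__ = [
    "NSGParameters",
    "BSGParameters",
    "nsg_rate",
    "nsg_biomass",
    "nsg_max_biomass",
    "bsg_biomass",
    "bsg_max_biomass",
    "beta_rate",
    "bsg_simplified_biomass",
]

# exp() saturates instead of overflowing; only reachable when evaluating the
# raw NSG form past t_e with large k.
_EXP_CAP = 700.0


def _exp(x):
    return np.exp(np.minimum(x, _EXP_CAP))


@dataclass(frozen=True)
class NSGParameters:
    """Parameters of the NSG model.

    Attributes
    ----------
    c : float
        Scale constant, units (g/day)^0.5 per day.  The model depends only on
        ``c**2``, so ``c`` and ``-c`` are observationally identical; the
        non-positive representative is canonical and enforced here.
    k : float
        Decay-shape constant (1/day), > 0.  Large ``k`` collapses the
        exponential shoulder at ``t_e`` and the curve approaches the pure
        cubic ``c^2 (t - t_b)^3 / 3`` clamped at ``t_e``.
    t_b : float
        Time growth starts (day); may be negative (a conceptual start, like
        the sub-zero notional temperatures of the original rate model).
    t_e : float
        Time growth ends / maturity (day); must exceed ``t_b``.
    """

    c: float
    k: float
    t_b: float
    t_e: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.c, self.k, self.t_b, self.t_e]).all():
            raise ParameterError("NSG parameters must be finite")
        if self.c > 0:
            raise ParameterError(
                f"c must be <= 0 (canonical sign convention), got {self.c}"
            )
        if self.k <= 0:
            raise ParameterError(f"k must be > 0, got {self.k}")
        if self.t_e <= self.t_b:
            raise ParameterError(
                f"t_e must exceed t_b, got t_b={self.t_b}, t_e={self.t_e}"
            )

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.c, self.k, self.t_b, self.t_e)


@dataclass(frozen=True)
class BSGParameters:
    """Parameters of the BSG model.

    Attributes
    ----------
    c_m : float
        Maximum growth rate (g/day), > 0, attained at ``t_m``.
    t_m : float
        Time of maximum growth rate (day), strictly between ``t_b`` and
        ``t_e`` (the exponent ``(t_m - t_b)/(t_e - t_m)`` needs a positive
        base and denominator).
    t_b : float
        Time growth starts (day); often estimated negative on real data.
    t_e : float
        Time growth ends / maturity (day).
    """

    c_m: float
    t_m: float
    t_b: float
    t_e: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.c_m, self.t_m, self.t_b, self.t_e]).all():
            raise ParameterError("BSG parameters must be finite")
        if self.c_m <= 0:
            raise ParameterError(f"c_m must be > 0, got {self.c_m}")
        if not (self.t_b < self.t_m < self.t_e):
            raise ParameterError(
                "t_b < t_m < t_e required, got "
                f"t_b={self.t_b}, t_m={self.t_m}, t_e={self.t_e}"
            )

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.c_m, self.t_m, self.t_b, self.t_e)


def nsg_rate(t, p: NSGParameters):
    """NSG growth rate r(t) = c^2 (t-t_b)^2 (1 - e^{k(t-t_e)})^2 in g/day.

    Zero at ``t_b`` and ``t_e`` exactly; zero outside ``[t_b, t_e]`` (growth
    has not started / has ceased).
    """
    t = np.asarray(t, dtype=float)
    root = p.c * (t - p.t_b) * (1.0 - _exp(p.k * (t - p.t_e)))
    r = np.where((t < p.t_b) | (t > p.t_e), 0.0, root * root)
    return r if r.ndim else float(r)


def _nsg_biomass_raw(t, c, k, t_b, t_e):
    """Closed-form integral of the squared NSG rate from t_b to t.

    Expanding (1 - e^{k(t-t_e)})^2 gives three terms; with x = t - t_b:

    * polynomial:     x^3 / 3
    * -2 e^{k(s-t_e)}: I1 = e^{k(t-t_e)} (x^2/k - 2x/k^2 + 2/k^3)
                            - e^{k(t_b-t_e)} * 2/k^3
    * +e^{2k(s-t_e)}:  I2 = e^{2k(t-t_e)} (x^2/(2k) - x/(2k^2) + 1/(4k^3))
                            - e^{2k(t_b-t_e)} / (4k^3)

    and w = c^2 (x^3/3 - 2 I1 + I2).  Within [t_b, t_e] every exponent is
    non-positive, so the expression is overflow-free by construction.
    """
    x = t - t_b
    e1 = _exp(k * (t - t_e))
    e2 = _exp(2.0 * k * (t - t_e))
    e1b = np.exp(k * (t_b - t_e))
    e2b = np.exp(2.0 * k * (t_b - t_e))
    i1 = e1 * (x * x / k - 2.0 * x / k**2 + 2.0 / k**3) - e1b * 2.0 / k**3
    i2 = e2 * (x * x / (2.0 * k) - x / (2.0 * k**2) + 1.0 / (4.0 * k**3)) - (
        e2b / (4.0 * k**3)
    )
    return c * c * (x**3 / 3.0 - 2.0 * i1 + i2)


def nsg_biomass(t, p: NSGParameters, clamp_after_te: bool = True):
    """NSG biomass w(t) in grams: the integral of :func:`nsg_rate` from t_b.

    Parameters
    ----------
    t : array_like
        Time(s) in days.
    p : NSGParameters
    clamp_after_te : bool, default True
        The squared rate becomes positive again beyond ``t_e``, so the raw
        closed form resumes growing there.  By default biomass is held at
        ``w(t_e)`` for ``t > t_e`` (the rate has decayed to zero at
        maturity); pass False for the raw analytic continuation.

    Returns 0 for ``t <= t_b``.
    """
    t = np.asarray(t, dtype=float)
    t_eval = np.minimum(t, p.t_e) if clamp_after_te else t
    w = _nsg_biomass_raw(t_eval, p.c, p.k, p.t_b, p.t_e)
    w = np.where(t <= p.t_b, 0.0, w)
    return w if w.ndim else float(w)


def nsg_max_biomass(p: NSGParameters) -> float:
    """Maximum biomass w_max = w(t_e) of the NSG model, in grams."""
    return float(_nsg_biomass_raw(np.float64(p.t_e), p.c, p.k, p.t_b, p.t_e))


def bsg_biomass(t, p: BSGParameters, clamp_after_te: bool = False):
    """BSG biomass w(t) in grams, evaluated literally.

    Raises :class:`DomainError` for ``t < t_b``: the fractional power of a
    negative base is undefined there.  ``w(t_b) = 0`` exactly and the curve
    peaks with zero slope at ``t_e``; past ``t_e`` the raw curve decreases
    unless ``clamp_after_te`` holds it at ``w(t_e)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < p.t_b):
        raise DomainError(
            f"BSG biomass undefined for t < t_b ({p.t_b}); got min t = {t.min()}"
        )
    t_eval = np.minimum(t, p.t_e) if clamp_after_te else t
    c_m, t_m, t_b, t_e = p.astuple()
    x = t_eval - t_b
    w = (
        c_m
        * x
        * (2.0 * t_e - t_m - t_eval)
        / (2.0 * t_e - t_m - t_b)
        * (x / (t_m - t_b)) ** ((t_m - t_b) / (t_e - t_m))
    )
    return w if w.ndim else float(w)


def bsg_max_biomass(p: BSGParameters) -> float:
    """Maximum biomass w_max = w(t_e) of the BSG model, in grams."""
    return float(bsg_biomass(p.t_e, p))


def beta_rate(t, c_m: float, t_m: float, t_e: float):
    """Simplified beta growth-rate function (t_b = 0, unit shape exponent).

    dw/dt = c_m * ((t_e - t)/(t_e - t_m)) * (t/t_m)^{t_m/(t_e - t_m)},
    defined on [0, t_e] with 0 < t_m < t_e.  The rate equals ``c_m`` at
    ``t_m`` and 0 at ``t_e``.
    """
    if not 0.0 < t_m < t_e:
        raise ParameterError(f"need 0 < t_m < t_e, got t_m={t_m}, t_e={t_e}")
    t = np.asarray(t, dtype=float)
    if np.any((t < 0.0) | (t > t_e)):
        raise DomainError(f"beta rate defined on [0, {t_e}] only")
    r = c_m * ((t_e - t) / (t_e - t_m)) * (t / t_m) ** (t_m / (t_e - t_m))
    return r if r.ndim else float(r)


def bsg_simplified_biomass(t, w_max: float, t_m: float, t_e: float):
    """Simplified BSG curve: the integral of :func:`beta_rate` scaled to w_max.

    w(t) = w_max (1 + (t_e - t)/(t_e - t_m)) (t/t_e)^{t_e/(t_e - t_m)},

    the determinate beta growth function with the growth start pinned at 0:
    ``w(0) = 0`` (for ``t_m > 0``) and ``w(t_e) = w_max`` (both factors equal
    1 at ``t_e``).  It is the exact antiderivative of the simplified beta
    rate, with ``c_m = w_max (2 t_e - t_m) / (t_e (t_e - t_m))``-type
    scaling absorbed into ``w_max``.  Requires ``0 <= t_m < t_e`` and
    ``w_max > 0``; raises :class:`DomainError` for ``t < 0``.
    """
    if w_max <= 0:
        raise ParameterError(f"w_max must be > 0, got {w_max}")
    if not 0.0 <= t_m < t_e:
        raise ParameterError(f"need 0 <= t_m < t_e, got t_m={t_m}, t_e={t_e}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise DomainError("simplified BSG biomass undefined for t < 0")
    w = w_max * (1.0 + (t_e - t) / (t_e - t_m)) * (t / t_e) ** (t_e / (t_e - t_m))
    return w if w.ndim else float(w)
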