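"""Population f-I curve: a smoothed threshold-linear transfer function.

The firing rate of a population is a static nonlinear function of its
effective membrane potential V,

    f(V) = (V - V_th) / (tau_m (V_th - V_r)) * 1 / (1 - exp(-(V - V_th)/v))

with a removable singularity at V = V_th where f -> v / (tau_m (V_th - V_r)).
Far below threshold the rate decays exponentially to zero; far above, f
approaches a straight line of slope 1 / (tau_m (V_th - V_r)).  The slope of
the curve at the operating point (the population "gain") is what makes
network responses state dependent.

Units: potentials in mV, tau_m in seconds, g_l in nS, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["FICurve", "fi_rate", "fi_derivative", "fi_inverse"]

# series branch half-width for u = (V - V_th)/v; truncation error < 1e-12
_SERIES_CUT = 0.25


def _phi(u: np.ndarray) -> np.ndarray:
    """phi(u) = u / (1 - exp(-u)), continuous at u = 0 (phi(0) = 1)."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < _SERIES_CUT
    neg = (u <= -_SERIES_CUT)
    rest = ~(small | neg)
    us = u[small]
    # Bernoulli series of u/(1 - e^{-u})
    out[small] = 1.0 + us / 2 + us**2 / 12 - us**4 / 720 + us**6 / 30240
    un = u[neg]
    # rewrite with e^{u} (tiny) to avoid overflow of e^{-u}
    s = np.exp(un)
    out[neg] = -un * s / (1.0 - s)
    ur = u[rest]
    out[rest] = ur / (-np.expm1(-ur))
    return out


def _phi_prime(u: np.ndarray) -> np.ndarray:
    """d phi / du, continuous at u = 0 (phi'(0) = 1/2); positive for all u."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < _SERIES_CUT
    neg = (u <= -_SERIES_CUT)
    rest = ~(small | neg)
    us = u[small]
    out[small] = 0.5 + us / 6 - us**3 / 180 + us**5 / 5040
    un = u[neg]
    s = np.exp(un)  # tiny
    out[neg] = s * (s - 1.0 - un) / (s - 1.0) ** 2
    ur = u[rest]
    e = np.exp(-ur)
    out[rest] = (1.0 - e - ur * e) / (1.0 - e) ** 2
    return out


def fi_rate(V, v_th, v_r, v, tau_m):
    """Firing rate (Hz) at membrane potential V (mV).

    Broadcasts over arrays; parameters may be scalars or arrays of the
    shape of ``V`` (used for per-unit evaluation in unit networks).
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    u = (V - v_th) / v
    return (v / (tau_m * (v_th - v_r))) * _phi(u)


def fi_derivative(V, v_th, v_r, v, tau_m):
    """df/dV (Hz/mV); strictly positive for every V."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    u = (V - v_th) / v
    return _phi_prime(u) / (tau_m * (v_th - v_r))


@dataclass(frozen=True)
class FICurve:
    """Per-population f-I parameters.

    Parameters
    ----------
    v_th, v_r : float
        Threshold and reset potentials (mV); ``v_th > v_r``.
    v : float
        Smoothness scale of the transfer function (mV).
    tau_m : float
        Membrane time constant (seconds).
    g_l : float
        Leak conductance (nS); divides currents to give potentials.
    v_l : float
        Leak/reversal potential (mV), the zero-input operating point.
    """

    v_th: float = -50.0
    v_r: float = -60.0
    v: float = 1.0
    tau_m: float = 0.028
    g_l: float = 6.25
    v_l: float = -70.0

    def __post_init__(self):
        if not (self.v_th > self.v_r):
            raise ValueError("require v_th > v_r")
        if self.v <= 0 or self.tau_m <= 0 or self.g_l <= 0:
            raise ValueError("v, tau_m and g_l must be positive")

    def rate(self, V):
        return fi_rate(V, self.v_th, self.v_r, self.v, self.tau_m)

    def derivative(self, V):
        return fi_derivative(V, self.v_th, self.v_r, self.v, self.tau_m)

    def inverse(self, r: float) -> float:
        return fi_inverse(r, self)

    @property
    def d_infinity(self) -> float:
        """High-input limit of the inverse gain d(V) = g_l/f'(V), in pA·s.

        f' saturates at 1/(tau_m (V_th - V_r)), so the limit is
        g_l tau_m (V_th - V_r); d(V) approaches it from above.
        """
        return self.g_l * self.tau_m * (self.v_th - self.v_r)


def fi_inverse(r: float, p: FICurve) -> float:
    """Membrane potential (mV) at which the f-I curve takes rate ``r`` (Hz).

    The curve is strictly increasing, so the inverse is unique; solved by
    bracketed root finding to machine precision.
    """
    r = float(r)
    if not np.isfinite(r) or r <= 0:
        raise ValueError("rate must be positive and finite")
    # above threshold f(V) > slope*(V - v_th), so this bound overshoots r
    hi = p.v_th + r * p.tau_m * (p.v_th - p.v_r) + 1.0
    lo = p.v_th
    while float(p.rate(lo)) >= r:
        lo -= max(2.0 * (p.v_th - lo), 2.0)
        if lo < p.v_th - 2000.0:
            raise ValueError(f"could not bracket rate {r}")
    return brentq(lambda V: float(p.rate(V)) - r, lo, hi, xtol=1e-12, rtol=8.9e-16)
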