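"""Second-order structure of finite-difference angular velocities of an OU
process, used to de-bias the discrete-time fit.

When the turning speed ω(t) is an Ornstein–Uhlenbeck process (relaxation
time τ, stationary variance v0 = σ²τ/2) but is *observed* as successive
differences of chord headings reconstructed from positions sampled every
Δt, the observed series

    ω̃_n = (θ̃_n − θ̃_{n−1}) / Δt,     θ̃_n = direction of x_{n+1} − x_n

is a triangle-kernel average of ω over a window of width 2Δt.  A lag-1
autoregressive fit of ω̃ then converges to 1 − ρ₁(x) with x = Δt/τ, where
ρ₁ is the lag-1 autocorrelation of the kernel-averaged process — NOT to the
Euler gain x (the discrepancy does not vanish as Δt → 0; the naive fit
overestimates τ by tens of percent at any sampling rate).  This module
computes, for the triangle kernel,

    var_factor(x) = Var(ω̃) / v0              (attenuation)
    rho1(x)       = Corr(ω̃_n, ω̃_{n+1})
    gain(x)       = 1 − rho1(x)               (population lag-1 gain)

from the exact covariances of rectangle-window averages of θ, themselves
closed integrals of V(s) = Var(θ(t+s) − θ(t)) = 2 v0 τ² (s/τ − 1 + e^(−s/τ)).
Values are cached on a spline so the fit can invert gain(x) cheaply.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

__all__ = ["rho1", "var_factor", "gain_filtered", "x_from_gain"]

_X_MIN, _X_MAX = 1e-3, 3.0
_NODES = np.polynomial.legendre.leggauss(96)


def _V(s):
    """Var(θ(t+s) − θ(t)) for unit-variance, unit-τ OU angular velocity."""
    s = np.abs(s)
    return 2.0 * (s - 1.0 + np.exp(-s))


def _W(m: int, x: float) -> float:
    """Var(θ̄_{n+m} − θ̄_n) for rectangle-window (width x) averages of θ."""
    d0, w0 = _NODES
    d = d0 * x
    w = w0 * x
    weight = x - np.abs(d)
    integrand = 0.5 * (_V(m * x + d) + _V(m * x - d)) - _V(d)
    return float(np.sum(w * weight * integrand)) / x**2


def _cov(m: int, x: float) -> float:
    """Cov(ω̃_n, ω̃_{n+m}) in units of v0, for ω̃_n = (θ̄_n − θ̄_{n−1})/Δt."""
    if m == 0:
        return _W(1, x) / x**2
    return (_W(m + 1, x) + _W(m - 1, x) - 2.0 * _W(m, x)) / (2.0 * x**2)


@lru_cache(maxsize=1)
def _splines():
    xs = np.geomspace(_X_MIN, _X_MAX, 200)
    c0 = np.array([_cov(0, x) for x in xs])
    c1 = np.array([_cov(1, x) for x in xs])
    return CubicSpline(xs, c0), CubicSpline(xs, c1)

def var_factor(x):
    """Var(ω̃) / v0: variance attenuation of the chord-difference estimate."""
    s0, _ = _splines()
    return np.clip(s0(np.clip(x, _X_MIN, _X_MAX)), 1e-12, None)


def rho1(x):
    """Lag-1 autocorrelation of the chord-difference angular velocity."""
    s0, s1 = _splines()
    xc = np.clip(x, _X_MIN, _X_MAX)
    return s1(xc) / np.clip(s0(xc), 1e-12, None)


def gain_filtered(x):
    """Population lag-1 regression gain 1 − ρ₁(x) of the observed series."""
    return 1.0 - rho1(x)


def x_from_gain(b: float) -> float:
    """Invert gain_filtered: the x = Δt/τ whose population gain equals ``b``."""
    lo, hi = gain_filtered(_X_MIN), gain_filtered(_X_MAX)
    if b <= lo:
        return _X_MIN
    if b >= hi:
        return _X_MAX
    return float(brentq(lambda x: gain_filtered(x) - b, _X_MIN, _X_MAX, xtol=1e-12))
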