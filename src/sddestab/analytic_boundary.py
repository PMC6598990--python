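"""Closed-form stability boundary for the fixed-delay specialisation.

When the maturation rate is one constant g (so tau = (x2 - x1)/g), the
self-renewal fraction is unregulated (k_a = 0) and d == 0, the positive
equilibrium's characteristic equation collapses, after the rescaling
lambda = z tau, to

    r m (lambda + eta) e^{-lambda} + lambda^2 + m lambda = 0

with dimensionless groups eta = mu_w tau, m = mu tau and
r = 1 - mu_w / ((2a - 1) p) in (0, 1) on the existence region.  Purely
imaginary roots lambda = i omega give the boundary parametrisation

    r(omega) = omega / f_eta(omega),
    m(omega) = omega f_eta(omega) / g_eta(omega),

with the trigonometric auxiliaries f_eta = eta sin w - w cos w and
g_eta = w sin w + eta cos w.  This module evaluates the parametrisation,
its singularity catalogue, the crossing determinant, and the qualitative
shape of the boundary r(m) (unique minimum for eta < 3, increasing for
eta >= 3, with the minimiser at omega = pi/2 exactly at eta = pi^2/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BoundaryPoint",
    "f_eta",
    "g_eta",
    "H1",
    "H2",
    "boundary_point",
    "singularities",
    "boundary_curve",
    "det_H",
    "dr_domega_numerator",
    "classify_shape",
    "minimiser_omega",
    "monotone_eta_threshold",
    "minimiser_at_pi_half_threshold",
    "to_mu_p",
    "crossing_p_analytic",
    "parametrisation_interval",
]

_SING_MARGIN = 1e-6


@dataclass(frozen=True)
class BoundaryPoint:
    """One point of the stability boundary, in scaled and physical coordinates."""

    omega: float
    m: float
    r: float
    mu: float = float("nan")
    p: float = float("nan")
    det_sign: int = 0


def f_eta(omega, eta):
    """eta sin(w) - w cos(w): denominator of r(omega)."""
    omega = np.asarray(omega, dtype=float)
    return eta * np.sin(omega) - omega * np.cos(omega)


def g_eta(omega, eta):
    """w sin(w) + eta cos(w): denominator of m(omega)."""
    omega = np.asarray(omega, dtype=float)
    return omega * np.sin(omega) + eta * np.cos(omega)


def H1(m, r, nu, omega, eta):
    """Real part of the scaled characteristic function at lambda = nu + i omega."""
    return (nu**2 - omega**2 + m * nu
            + m * r * math.exp(-nu) * ((nu + eta) * math.cos(omega) + omega * math.sin(omega)))


def H2(m, r, nu, omega, eta):
    """Imaginary part of the scaled characteristic function."""
    return (2 * nu * omega + m * omega
            + m * r * math.exp(-nu) * (omega * math.cos(omega) - (nu + eta) * math.sin(omega)))


def boundary_point(omega: float, eta: float) -> tuple[float, float]:
    """(m, r) at crossing frequency omega; raises near a singularity."""
    f = float(f_eta(omega, eta))
    g = float(g_eta(omega, eta))
    if abs(f) < 1e-12 or abs(g) < 1e-12:
        raise ZeroDivisionError(f"omega={omega} is (numerically) a singularity")
    return omega * f / g, omega / f


def det_H(m: float, r: float, omega: float, eta: float) -> float:
    """Determinant of d(H1, H2)/d(m, r) at a purely imaginary crossing.

    Closed form -omega * m * (eta cos w + w sin w); negative along the
    stability boundary, so the conjugate root pair crosses left-to-right.
    """
    return -omega * m * (eta * math.cos(omega) + omega * math.sin(omega))


# ---------------------------------------------------------------------------
# singularities of the parametrisation
# ---------------------------------------------------------------------------


def singularities(eta: float, count: int) -> list[tuple[float, str]]:
    """Ordered singularities omega_0 = 0 < omega_1 < ... < omega_count.

    For j >= 1 the singularities are the zeros of f_eta and g_eta, which
    alternate between half-pi-wide windows:

    * eta >= 1: omega_j in (pi/2, pi) + (j-1) pi/2, alternating g, f, g, ...
    * eta <  1: omega_j in (0, pi/2) + (j-1) pi/2, alternating f, g, f, ...

    Returns (omega_j, which) pairs with which in {"origin", "f", "g"}.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    out: list[tuple[float, str]] = [(0.0, "origin")]
    for j in range(1, count + 1):
        if eta >= 1.0:
            lo = math.pi / 2 + (j - 1) * math.pi / 2
            hi = math.pi + (j - 1) * math.pi / 2
            fun_name = "g" if j % 2 == 1 else "f"
        else:
            lo = (j - 1) * math.pi / 2
            hi = math.pi / 2 + (j - 1) * math.pi / 2
            fun_name = "f" if j % 2 == 1 else "g"
        fun = f_eta if fun_name == "f" else g_eta
        a, b = lo + 1e-13, hi - 1e-13
        fa, fb = float(fun(a, eta)), float(fun(b, eta))
        if fa * fb > 0:
            raise RuntimeError(
                f"no sign change of {fun_name}_eta in ({lo:.6g}, {hi:.6g}) for eta={eta}")
        root = brentq(lambda w: float(fun(w, eta)), a, b, xtol=1e-12, rtol=1e-15)
        out.append((float(root), fun_name))
    return out


def parametrisation_interval(eta: float) -> tuple[float, float]:
    """Open omega-interval parametrising the stability boundary.

    (0, omega_1) for eta >= 1 and (omega_1, omega_2) for eta < 1.
    """
    if eta >= 1.0:
        return 0.0, singularities(eta, 1)[1][0]
    s = singularities(eta, 2)
    return s[1][0], s[2][0]


def boundary_curve(eta: float, n_points: int = 200,
                   margin: float = _SING_MARGIN) -> list[BoundaryPoint]:
    """Sample the boundary on its parametrisation interval (endpoints excluded)."""
    lo, hi = parametrisation_interval(eta)
    omegas = np.linspace(lo + margin, hi - margin, n_points)
    pts = []
    for w in omegas:
        m, r = boundary_point(float(w), eta)
        pts.append(BoundaryPoint(omega=float(w), m=m, r=r,
                                 det_sign=int(math.copysign(1.0, det_H(m, r, float(w), eta)))))
    return pts


# ---------------------------------------------------------------------------
# shape of r as a function of m
# ---------------------------------------------------------------------------


def dr_domega_numerator(omega, eta):
    """Sign-equivalent numerator of dr/domega: (eta - w^2) sin w - eta w cos w.

    r'(omega) = N(omega) / f_eta(omega)^2, so the sign of N is the sign of
    r' wherever the parametrisation is defined.
    """
    omega = np.asarray(omega, dtype=float)
    return (eta - omega**2) * np.sin(omega) - eta * omega * np.cos(omega)


def minimiser_omega(eta: float, margin: float = 1e-9) -> float | None:
    """Crossing frequency of the boundary minimum of r(m), or None if monotone."""
    lo, hi = parametrisation_interval(eta)
    grid = np.linspace(lo + max(margin, 1e-9), hi - max(margin, _SING_MARGIN), 4001)
    N = dr_domega_numerator(grid, eta)
    sign = np.sign(N)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    return float(brentq(lambda w: float(dr_domega_numerator(w, eta)),
                        grid[i], grid[i + 1], xtol=1e-12, rtol=1e-15))


def classify_shape(eta: float, tol: float = 1e-9) -> dict:
    """Qualitative shape of r(m): minimum vs monotone, minimiser vs pi/2."""
    wstar = minimiser_omega(eta)
    if wstar is None:
        return {"shape": "monotone-increasing", "omega_min": None, "min_location": None}
    if abs(wstar - math.pi / 2) <= tol:
        loc = "omega=pi/2"
    elif wstar > math.pi / 2:
        loc = "omega>pi/2"
    else:
        loc = "omega<pi/2"
    return {"shape": "non-monotone-with-minimum", "omega_min": wstar, "min_location": loc}


def _is_monotone(eta: float, n_grid: int = 4001, margin: float = 1e-4) -> bool:
    """No negative dr/domega on a dense grid over the parametrisation interval."""
    lo, hi = parametrisation_interval(eta)
    grid = np.linspace(lo + margin, hi - _SING_MARGIN, n_grid)
    return bool(np.all(dr_domega_numerator(grid, eta) >= 0.0))


def monotone_eta_threshold(lo: float = 1.0, hi: float = 5.0, tol: float = 1e-3) -> float:
    """Smallest eta for which r(m) is increasing on the whole boundary.

    Deterministic bisection on the monotonicity classification; the
    interior minimum disappears at eta = 3 (series expansion of r' at the
    origin), which this recovers numerically to ``tol``.
    """
    if _is_monotone(lo) or not _is_monotone(hi):
        raise ValueError("bisection bracket does not straddle the threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _is_monotone(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def minimiser_at_pi_half_threshold(lo: float = 1.1, hi: float = 2.99,
                                   tol: float = 1e-3) -> float:
    """eta at which the boundary minimum sits exactly at omega = pi/2.

    Bisection on omega_min(eta) - pi/2 (the minimiser moves left as eta
    grows); the exact value is pi^2 / 4.
    """
    def excess(eta):
        w = minimiser_omega(eta)
        if w is None:
            return -math.pi  # monotone: treat as minimiser far left
        return w - math.pi / 2

    if excess(lo) <= 0 or excess(hi) >= 0:
        raise ValueError("bisection bracket does not straddle the threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# mapping to the physical parameter plane
# ---------------------------------------------------------------------------


def to_mu_p(bp: BoundaryPoint | tuple[float, float], tau: float, mu_w: float,
            a: float) -> tuple[float, float]:
    """Unscale a boundary point: mu = m / tau, p = mu_w / ((2a - 1)(1 - r))."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    m, r = (bp.m, bp.r) if isinstance(bp, BoundaryPoint) else bp
    if r >= 1.0:
        raise ValueError(f"r = {r} >= 1: no finite division rate p reaches this point")
    return m / tau, mu_w / ((2.0 * a - 1.0) * (1.0 - r))


def crossing_p_analytic(mu: float, tau: float, mu_w: float, a: float) -> float | None:
    """Boundary division rate p at given mu, from the closed-form curve.

    Inverts the (monotone) map omega -> m at m = mu tau on the
    parametrisation interval and maps r(omega) to p.  Returns None when the
    boundary does not reach this mu (r >= 1: stable for every p).
    """
    eta = mu_w * tau
    m_target = mu * tau
    lo, hi = parametrisation_interval(eta)
    a_, b_ = lo + 1e-11, hi - 1e-11

    def mfun(w):
        # raw formula: m -> 0 at the r-singularity end, so no guard needed
        return w * float(f_eta(w, eta)) / float(g_eta(w, eta)) - m_target

    # m is increasing from 0 to +inf on the open interval (Lemma 5.4 analogue)
    while mfun(b_) < 0 and hi - b_ > 1e-14:
        b_ = hi - 0.1 * (hi - b_)
    if mfun(a_) > 0 or mfun(b_) < 0:
        return None
    w = brentq(mfun, a_, b_, xtol=1e-13, rtol=1e-15)
    _, r = boundary_point(w, eta)
    if not (0.0 < r < 1.0):
        return None
    return mu_w / ((2.0 * a - 1.0) * (1.0 - r))
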