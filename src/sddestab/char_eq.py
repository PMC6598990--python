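"""Characteristic equations of the linearised model and root localisation.

For the trivial equilibrium the characteristic function factorises as
(z - q(0)) (z + mu).  For the positive equilibrium (w, v) it is the
transcendental function

    chi(v, z) = z k_hat(z)
                + mu v e^{-tau z} [ z (gamma'/gamma(v) - D2g/g(x1, v)) + q'(v) ]
                - z^2 + (v D2g/g(x2, v) - 1) mu z,

where k_hat is the finite Laplace transform of a kernel k(v)(t) supported
on [0, tau] that collects the maturity-trajectory sensitivities; the kernel
vanishes identically when d == 0 and g is independent of maturity.  A
cascade of simplified closed forms is available for progressively more
special rate choices (cases "a"-"e"); case "e" is the fixed-delay equation
whose boundary the analytic module parametrises.

Roots are localised in rectangles of the complex plane by the argument
principle (adaptive phase tracking on the rectangle boundary, recursive
subdivision to unit winding count, Newton polish).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .equilibria import Equilibrium, positive_equilibrium
from .rates import ModelConfig, RateDerivatives, rate_derivatives
from .sd_dde_core import resolve_h

__all__ = [
    "CharContext",
    "CharRoot",
    "chi_trivial",
    "kernel_k",
    "chi",
    "chi_simplified",
    "find_roots",
    "build_context",
]

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl(n):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


# ---------------------------------------------------------------------------
# context
# ---------------------------------------------------------------------------


@dataclass
class CharContext:
    """Everything chi(v, z) needs at one positive equilibrium."""

    config: ModelConfig
    eq: Equilibrium
    tau_v: float
    y_of_t: Callable           # t in [0, tau] -> maturity along the trajectory
    deriv: RateDerivatives
    kernel_zero: bool
    _kernel_cache: dict = field(default_factory=dict)

    @property
    def v(self) -> float:
        return self.eq.v


def _y_constant_history(config: ModelConfig, v: float) -> tuple[float, Callable]:
    """Trajectory and delay for the constant history v.

    With a constant history the maturity ODE is autonomous, so
    tau = int_{x1}^{x2} dx / g(x, v) and t(y) is the antiderivative; y(t) is
    recovered on a Chebyshev-fine grid and interpolated monotonically.
    """
    mat = config.mat
    x, w = _gl(48)
    xs = 0.5 * mat.delta * x + 0.5 * (mat.x1 + mat.x2)
    tau = 0.5 * mat.delta * float(np.sum(w / mat.g(xs, v)))
    if mat.is_x_independent:
        g = float(mat.g(mat.x2, v))
        return tau, lambda t: mat.x2 - g * np.asarray(t)
    # tabulate t(y) = int_y^{x2} dx / g(x, v) by per-panel Gauss quadrature
    # (machine-accurate panel integrals; only spline interpolation error left)
    ygrid = np.linspace(mat.x2, mat.x1, 401)  # descending: traversal order
    xq, wq = _gl(8)
    mids = 0.5 * (ygrid[:-1] + ygrid[1:])
    halfs = 0.5 * (ygrid[1:] - ygrid[:-1])  # negative
    panel_pts = mids[:, None] + halfs[:, None] * xq[None, :]
    panel_int = -halfs * np.sum(wq / mat.g(panel_pts, v), axis=1)
    tgrid = np.concatenate([[0.0], np.cumsum(panel_int)])  # increasing to tau
    from scipy.interpolate import CubicSpline
    y_interp = CubicSpline(tgrid, ygrid)
    tau = float(tgrid[-1])

    def y_of_t(t):
        return y_interp(np.clip(np.asarray(t, dtype=float), 0.0, tau))

    return tau, y_of_t


def build_context(config: ModelConfig, eq: Equilibrium | None = None) -> CharContext:
    """Assemble the characteristic context at the positive equilibrium."""
    if eq is None:
        eq = positive_equilibrium(config)
    if eq.kind != "positive":
        raise ValueError("chi(v, z) is defined at the positive equilibrium")
    tau, y_of_t = _y_constant_history(config, eq.v)
    h = resolve_h(config)
    if not tau < h:
        raise ValueError(f"tau = {tau} must be below the horizon h = {h}")
    kernel_zero = config.d.is_zero and config.mat.is_x_independent
    return CharContext(config=config, eq=eq, tau_v=tau, y_of_t=y_of_t,
                       deriv=rate_derivatives(config), kernel_zero=kernel_zero)


# ---------------------------------------------------------------------------
# trivial equilibrium
# ---------------------------------------------------------------------------


def chi_trivial(z: complex, config: ModelConfig) -> complex:
    """(z - q(0)) (z + mu): the characteristic function at extinction."""
    return (z - config.stem.q(0.0)) * (z + config.stem.mu)


# ---------------------------------------------------------------------------
# kernel and chi at the positive equilibrium
# ---------------------------------------------------------------------------


def _D1g_antiderivative(ctx: CharContext) -> Callable:
    """I(s) = int_0^s D1g(y(theta), v) dtheta, by fixed high-order quadrature."""
    mat, v, y = ctx.config.mat, ctx.v, ctx.y_of_t
    x, w = _gl(40)

    def I(s):
        s = float(s)
        if s == 0.0:
            return 0.0
        half = 0.5 * s
        th = half * x + half
        return half * float(np.sum(w * mat.D1g(y(th), v)))

    return I


def kernel_k(t: float, ctx: CharContext) -> float:
    """Kernel k(v)(t) of the distributed-delay term, t in [0, tau].

    Three contributions, all proportional to mu*v: the direct sensitivity
    D2(d - D1g) along the trajectory; a boundary term weighted by the
    dilation factor exp(-int_t^tau D1g); and an integral term propagating
    D1(d - D1g) back from sigma to t.
    """
    tau, v = ctx.tau_v, ctx.v
    if t < -1e-12 or t > tau + 1e-12:
        raise ValueError(f"kernel argument t={t} outside [0, tau={tau}]")
    t = min(max(t, 0.0), tau)
    if ctx.kernel_zero:
        return 0.0
    cfg, mat, d = ctx.config, ctx.config.mat, ctx.config.d
    stem = cfg.stem
    y = ctx.y_of_t
    I = ctx._kernel_cache.setdefault("I", _D1g_antiderivative(ctx))
    yt = float(y(t))
    term1 = d.deriv_v(yt, v) - mat.D2D1g(yt, v)
    dmd1g_x1 = (d(mat.x1, v) - mat.D1g(mat.x1, v)) / mat.g(mat.x1, v)
    term2 = -dmd1g_x1 * math.exp(-(I(tau) - I(t))) * mat.D2g(yt, v)
    # int_t^tau D1(d - D1g)(y(sigma), v) exp(-int_t^sigma D1g) dsigma
    x, wq = _gl(40)
    half = 0.5 * (tau - t)
    if half > 0:
        sig = half * x + 0.5 * (tau + t)
        ys = y(sig)
        vals = (d.deriv_x(ys, v) - mat.D1D1g(ys, v)) * np.exp(
            -(np.array([I(s) for s in sig]) - I(t)))
        inner = half * float(np.sum(wq * vals))
    else:
        inner = 0.0
    term3 = -mat.D2g(yt, v) * inner
    return stem.mu * v * (term1 + term2 + term3)


def _kernel_hat(z: complex, ctx: CharContext, reltol: float = 1e-10) -> complex:
    """Finite Laplace transform int_0^tau k(t) e^{-z t} dt, order-doubling GL."""
    if ctx.kernel_zero:
        return 0.0 + 0.0j
    tau = ctx.tau_v

    def at(n):
        key = ("kvals", n)
        if key not in ctx._kernel_cache:
            x, w = _gl(n)
            tq = 0.5 * tau * x + 0.5 * tau
            ctx._kernel_cache[key] = (tq, w, np.array([kernel_k(t, ctx) for t in tq]))
        tq, w, kv = ctx._kernel_cache[key]
        return 0.5 * tau * complex(np.sum(w * kv * np.exp(-z * tq)))

    prev, n = at(16), 32
    while n <= 256:
        cur = at(n)
        if abs(cur - prev) <= reltol * max(1.0, abs(cur)):
            return cur
        prev, n = cur, 2 * n
    return prev


def chi(z: complex, ctx: CharContext) -> complex:
    """The characteristic function at the positive equilibrium."""
    cfg = ctx.config
    stem, mat = cfg.stem, cfg.mat
    v, tau = ctx.v, ctx.tau_v
    khat = _kernel_hat(z, ctx)
    bracket = z * (stem.gamma_prime(v) / stem.gamma(v)
                   - mat.D2g(mat.x1, v) / mat.g(mat.x1, v)) + stem.q_prime(v)
    return (z * khat
            + stem.mu * v * cmath.exp(-tau * z) * bracket
            - z * z
            + (v * mat.D2g(mat.x2, v) / mat.g(mat.x2, v) - 1.0) * stem.mu * z)


# ---------------------------------------------------------------------------
# simplified cascade
# ---------------------------------------------------------------------------


def chi_simplified(z: complex, config: ModelConfig, case: str,
                   eq: Equilibrium | None = None,
                   ctx: CharContext | None = None) -> complex:
    """Closed forms of chi for progressively more special rate choices.

    * "a": g independent of maturity (D1g == 0); kernel from d only.
    * "b": additionally d independent of v and g constant; delay tau = delta/g.
    * "c": additionally q, gamma from the built-in stem-cell family.
    * "d": additionally unregulated self-renewal (k_a = 0).
    * "e": additionally the built-in division rate; the fixed-delay form
      [1 - mu_w/((2a-1)p)] mu (z + mu_w) e^{-z tau} + z^2 + mu z, which is
      the negative of case "d" after substitution (roots are identical).
    """
    stem, mat = config.stem, config.mat
    if case in ("a", "b") and not mat.is_x_independent:
        raise ValueError("cases a/b require g independent of maturity")
    if eq is None:
        eq = positive_equilibrium(config)
    v = eq.v
    if case == "a":
        if ctx is None:
            ctx = build_context(config, eq)
        khat = _kernel_hat(z, ctx)
        gp = mat.D2g(mat.x2, v)
        g = mat.g(mat.x2, v)
        return (z * khat
                + stem.mu * v * (z * (stem.gamma_prime(v) / stem.gamma(v) - gp / g)
                                 + stem.q_prime(v)) * cmath.exp(-ctx.tau_v * z)
                - z * z + (v * gp / g - 1.0) * stem.mu * z)
    if not (mat.is_constant and config.d.is_zero):
        raise ValueError(f"case {case!r} requires constant g and d == 0")
    g = float(mat.g(mat.x2, 0.0))
    tau = mat.delta / g
    if case == "b":
        return (stem.mu * v * (stem.gamma_prime(v) / stem.gamma(v) * z + stem.q_prime(v))
                * cmath.exp(-tau * z) - z * z - stem.mu * z)
    if case == "c":
        s, sp = stem.s(v), stem.s_prime(v)
        dw, dwp = stem.d_w(v), stem.d_w_prime(v)
        return (stem.mu * v * ((dwp / dw - sp / (1.0 - s)) * z
                               + 2.0 * sp * dw + dwp * (2.0 * s - 1.0))
                * cmath.exp(-tau * z) - z * z - stem.mu * z)
    if case == "d":
        if stem.k_a != 0.0:
            raise ValueError("case d requires unregulated self-renewal (k_a = 0)")
        dw, dwp = stem.d_w(v), stem.d_w_prime(v)
        return (dwp / dw * stem.mu * v * (z + stem.mu_w) * cmath.exp(-tau * z)
                - z * z - stem.mu * z)
    if case == "e":
        if stem.k_a != 0.0:
            raise ValueError("case e requires unregulated self-renewal (k_a = 0)")
        coef = 1.0 - stem.mu_w / ((2.0 * stem.a - 1.0) * stem.p)
        return (coef * stem.mu * (z + stem.mu_w) * cmath.exp(-z * tau)
                + z * z + stem.mu * z)
    raise ValueError(f"unknown case {case!r}")


# ---------------------------------------------------------------------------
# root localisation by the argument principle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharRoot:
    """A located characteristic root with a residual certificate."""

    z: complex
    residual: float
    multiplicity: int = 1


def _winding(f: Callable, corners: list[complex], n0: int = 32,
             max_pts: int = 16384) -> int:
    """Winding number of f around a closed polygon, adaptive phase tracking."""
    pts: list[complex] = []
    for a, b in zip(corners, corners[1:] + corners[:1]):
        seg = [a + (b - a) * k / n0 for k in range(n0)]
        pts.extend(seg)
    vals = [f(p) for p in pts]
    total = 0.0
    i = 0
    n = len(pts)
    while i < n:
        z0, z1 = vals[i], vals[(i + 1) % n]
        if z0 == 0 or z1 == 0:
            raise RuntimeError("root on the contour; perturb the rectangle")
        dphi = cmath.phase(z1 / z0)
        if abs(dphi) > 0.5 * math.pi and n < max_pts:
            # refine this edge in place
            mid = 0.5 * (pts[i] + pts[(i + 1) % n])
            pts.insert(i + 1, mid)
            vals.insert(i + 1, f(mid))
            n += 1
            continue
        total += dphi
        i += 1
    return round(total / (2.0 * math.pi))


def _newton_polish(f: Callable, z0: complex, tol: float, maxit: int = 60) -> complex:
    z = z0
    for _ in range(maxit):
        step = 1e-7 * (1.0 + abs(z))
        df = (f(z + step) - f(z - step)) / (2.0 * step)
        if df == 0:
            break
        dz = f(z) / df
        z = z - dz
        if abs(dz) < tol:
            break
    return z


def find_roots(f: Callable | CharContext, rectangle: dict,
               scale: float | None = None, min_box: float = 1e-8) -> list[CharRoot]:
    """All roots of an analytic function inside a rectangle.

    ``rectangle`` has keys ``re_lo``, ``re_hi``, ``im_hi`` (and optionally
    ``im_lo``; default -im_hi).  Winding numbers on recursively subdivided
    boxes isolate the roots; each is polished by damped Newton and returned
    with |f| residual.  The total root count matches the outer winding
    number by construction.
    """
    if isinstance(f, CharContext):
        ctx = f
        f = lambda z: chi(z, ctx)  # noqa: E731
    re_lo, re_hi = rectangle["re_lo"], rectangle["re_hi"]
    im_hi = rectangle["im_hi"]
    im_lo = rectangle.get("im_lo", -im_hi)
    if scale is None:
        scale = max(1.0, abs(f(complex(re_hi, im_hi))), abs(f(complex(re_lo, 0.1))))
    roots: list[CharRoot] = []

    def box_corners(a, b, c, d):  # re in [a,b], im in [c,d]
        return [complex(a, c), complex(b, c), complex(b, d), complex(a, d)]

    def recurse(a, b, c, d, depth=0):
        try:
            wn = _winding(f, box_corners(a, b, c, d))
        except RuntimeError:
            eps = 1e-6 * (1.0 + max(b - a, d - c))
            wn = _winding(f, box_corners(a - eps, b + eps, c - eps, d + eps))
        if wn == 0:
            return
        if wn == 1 or (b - a < min_box and d - c < min_box):
            z0 = complex(0.5 * (a + b), 0.5 * (c + d))
            z = _newton_polish(f, z0, tol=1e-13 * (1.0 + abs(z0)))
            res = abs(f(z))
            inside = (a - 1e-6 <= z.real <= b + 1e-6
                      and c - 1e-6 <= z.imag <= d + 1e-6)
            if inside or (b - a <= min_box and d - c <= min_box):
                roots.append(CharRoot(z=z, residual=res, multiplicity=wn))
                return
            # Newton escaped the box: fall through to subdivision
        # subdivide along the longer side
        if b - a >= d - c:
            mid = 0.5 * (a + b)
            recurse(a, mid, c, d, depth + 1)
            recurse(mid, b, c, d, depth + 1)
        else:
            mid = 0.5 * (c + d)
            recurse(a, b, c, mid, depth + 1)
            recurse(a, b, mid, d, depth + 1)

    recurse(re_lo, re_hi, im_lo, im_hi)
    # merge duplicates found across box borders
    merged: list[CharRoot] = []
    for r in sorted(roots, key=lambda r: (r.z.real, r.z.imag)):
        if merged and abs(r.z - merged[-1].z) < 1e-7 * (1.0 + abs(r.z)):
            continue
        merged.append(r)
    return merged
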