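"""The state-dependent delay differential equation and its time integration.

The model for stem cells w(t) and mature cells v(t) is

    w'(t) = q(v(t)) w(t)
    v'(t) = gamma(v(t - tau)) g(x2, v(t)) / g(x1, v(t - tau)) * w(t - tau)
            * exp( int_0^tau (d - D1 g)(y(s), v(t - s)) ds )  -  mu v(t)

where tau = tau(v_t) is the threshold delay: the time a progenitor cell
needs to mature from x1 to x2, defined implicitly through the backward
maturity trajectory

    y'(s) = -g(y(s), v_t(-s)),   y(0) = x2,      y(tau) = x1.

States of the system are pairs of history functions on [-h, 0]; the horizon
h must strictly dominate every threshold delay encountered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .rates import ModelConfig

__all__ = [
    "HistoryPair",
    "DelaySolve",
    "SolutionPath",
    "HorizonError",
    "resolve_h",
    "maturity_trajectory",
    "threshold_delay",
    "rhs_F",
    "integrate",
    "solution_manifold_residual",
    "gauss_legendre_integral",
]

_ODE_RTOL = 1e-10
_ODE_ATOL = 1e-10
TOL_EVENT = 1e-12


class HorizonError(RuntimeError):
    """The maturity trajectory did not reach x1 within the history horizon h."""


# ---------------------------------------------------------------------------
# histories
# ---------------------------------------------------------------------------


@dataclass
class HistoryPair:
    """Two history functions (phi, psi) on [-h, 0] for (w, v).

    ``phi`` and ``psi`` are callables accepting theta in [-h, 0] (scalar or
    array).  ``dphi0`` / ``dpsi0`` optionally give the one-sided derivative
    at 0-, used by the solution-manifold residual; if absent a backward
    finite difference on the callable is used.
    """

    phi: Callable
    psi: Callable
    h: float
    dphi0: Optional[float] = None
    dpsi0: Optional[float] = None

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("history horizon h must be positive")
        if np.any(np.asarray(self.psi(np.linspace(-self.h, 0.0, 31))) < -1e-8):
            raise ValueError("mature-cell history psi must be nonnegative on [-h, 0]")

    @classmethod
    def constant(cls, w: float, v: float, h: float) -> "HistoryPair":
        if v < 0:
            raise ValueError("constant mature-cell history must be nonnegative")
        return cls(phi=lambda th: w + 0.0 * np.asarray(th, dtype=float),
                   psi=lambda th: v + 0.0 * np.asarray(th, dtype=float),
                   h=h, dphi0=0.0, dpsi0=0.0)


@dataclass
class DelaySolve:
    """Threshold delay tau and backward maturity trajectory y on [0, tau]."""

    tau: float
    trajectory: Callable  # s in [0, tau] -> maturity y(s)
    method: str
    nfev: int = 0

    def __call__(self, s):
        return self.trajectory(s)


@dataclass
class SolutionPath:
    """A computed solution (w, v) of the model on [0, t_end].

    ``w`` and ``v`` are callables valid on [-h, t_end] (history included);
    ``t``, ``w_vals``, ``v_vals`` sample the accepted solver steps.
    """

    t: np.ndarray
    w_vals: np.ndarray
    v_vals: np.ndarray
    w: Callable
    v: Callable
    h: float
    taus: np.ndarray = field(default_factory=lambda: np.empty(0))

    def history_at(self, t: float) -> HistoryPair:
        """The state (w_t, v_t) as a history pair on [-h, 0]."""
        wf, vf = self.w, self.v
        return HistoryPair(phi=lambda th: wf(t + np.asarray(th)),
                           psi=lambda th: np.maximum(vf(t + np.asarray(th)), 0.0),
                           h=self.h)


# ---------------------------------------------------------------------------
# quadrature helper
# ---------------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def gauss_legendre_integral(f: Callable, a: float, b: float, abstol: float = 1e-10,
                            n0: int = 16, nmax: int = 512) -> float:
    """Integrate a smooth vectorised integrand with order doubling.

    Gauss-Legendre of order n is compared with order 2n; the order doubles
    until successive values agree to ``abstol`` (absolute).
    """
    if a == b:
        return 0.0
    half, mid = 0.5 * (b - a), 0.5 * (b + a)

    def at(n):
        x, w = _gl_nodes(n)
        return half * float(np.sum(w * np.asarray(f(mid + half * x), dtype=float)))

    prev = at(n0)
    n = 2 * n0
    while n <= nmax:
        cur = at(n)
        if abs(cur - prev) <= abstol * max(1.0, abs(cur)):
            return cur
        prev, n = cur, 2 * n
    return prev


# ---------------------------------------------------------------------------
# threshold delay
# ---------------------------------------------------------------------------


def resolve_h(config: ModelConfig, safety: float = 2.0) -> float:
    """History horizon: 2x the largest threshold delay over v in [0, v_max].

    For constant histories the delay is tau(v) = int_{x1}^{x2} dx / g(x, v),
    maximised over a grid of v values.
    """
    if config.h is not None:
        return config.h
    mat = config.mat
    vs = np.linspace(0.0, config.v_max, 41)
    x, w = _gl_nodes(32)
    xs = 0.5 * (mat.x2 - mat.x1) * x + 0.5 * (mat.x2 + mat.x1)
    taus = [0.5 * mat.delta * float(np.sum(w / mat.g(xs, v))) for v in vs]
    return safety * max(taus)


def maturity_trajectory(psi: Callable | HistoryPair, config: ModelConfig,
                        h: Optional[float] = None, method: str = "auto") -> DelaySolve:
    """Solve the backward maturity problem y' = -g(y, psi(-s)), y(0) = x2.

    Returns the trajectory together with the threshold delay tau defined by
    y(tau) = x1.  Three routes:

    * ``"ode"``      -- adaptive Runge-Kutta with terminal event at y = x1;
    * ``"integral"`` -- when g does not depend on x, y is the explicit
      integral y(s) = x2 - int_{-s}^0 g(psi(theta)) dtheta and tau solves a
      scalar equation (root found by Brent's method);
    * ``"fixed"``    -- fixed-step classical Runge-Kutta with Hermite
      crossing location; less accurate per step than the adaptive route but
      a smooth function of the history values, which finite-difference
      Jacobians require (adaptive step-acceptance decisions are not);
    * ``"auto"``     -- integral route when D1 g == 0, fixed-step route
      otherwise (tau = delta / g immediately when g is a single constant).
    """
    if isinstance(psi, HistoryPair):
        h = h if h is not None else psi.h
        psi = psi.psi
    if h is None:
        h = resolve_h(config)
    mat = config.mat
    if method == "auto":
        method = "integral" if mat.is_x_independent else "fixed"
    if method == "fixed":
        return _fixed_step_trajectory(psi, config, h)

    if method == "integral":
        if not mat.is_x_independent:
            raise ValueError("integral route requires g independent of maturity x")
        if mat.is_constant:
            gconst = float(mat.g(mat.x1, 0.0))
            tau = mat.delta / gconst
            if tau >= h:
                raise HorizonError(f"threshold delay {tau} >= horizon h={h}")
            return DelaySolve(tau=tau, trajectory=lambda s: mat.x2 - gconst * np.asarray(s),
                              method="constant")

        def gpsi(u):  # g along the history, u = backward time
            return mat.g(mat.x2, psi(-np.asarray(u)))

        x16, w16 = _gl_nodes(24)

        def arc(s):  # int_0^s g(psi(-u)) du, high-order fixed rule (smooth)
            half = 0.5 * s
            return half * float(np.sum(w16 * gpsi(half * x16 + half)))

        target = mat.delta
        if arc(h) <= target:
            raise HorizonError(f"maturity x1 not reached within horizon h={h}")
        from scipy.optimize import brentq
        tau = brentq(lambda s: arc(s) - target, 0.0, h, xtol=TOL_EVENT, rtol=1e-15)
        return DelaySolve(tau=float(tau),
                          trajectory=lambda s: mat.x2 - np.vectorize(arc)(np.asarray(s)),
                          method="integral")

    # generic ODE route with event detection
    nfev = 0

    def rhs(s, y):
        nonlocal nfev
        nfev += 1
        return [-mat.g(y[0], float(psi(-s)))]

    def hit_x1(s, y):
        return y[0] - mat.x1

    hit_x1.terminal = True
    hit_x1.direction = -1
    sol = solve_ivp(rhs, (0.0, h), [mat.x2], events=hit_x1, dense_output=True,
                    rtol=_ODE_RTOL, atol=_ODE_ATOL)
    if not sol.t_events[0].size:
        raise HorizonError(f"maturity x1 not reached within horizon h={h}")
    tau = float(sol.t_events[0][0])
    dense = sol.sol

    def traj(s):
        s = np.asarray(s, dtype=float)
        return dense(np.clip(s, 0.0, tau))[0] if s.ndim else float(dense(min(max(s, 0.0), tau))[0])

    return DelaySolve(tau=tau, trajectory=traj, method="ode", nfev=nfev)


def _fixed_step_trajectory(psi: Callable, config: ModelConfig, h: float,
                           n_steps: int = 384) -> DelaySolve:
    """Fixed-step RK4 for the maturity ODE with Hermite crossing location.

    All abscissae are fixed fractions of h, so the computed tau and
    trajectory depend smoothly on the history values -- the property that
    finite-difference Jacobians of the discretised system rely on.
    """
    mat = config.mat
    dt = h / n_steps
    # history values at all step and half-step abscissae, one vector call
    grid = np.arange(2 * n_steps + 1) * (0.5 * dt)
    psivals = np.maximum(np.asarray(psi(-grid), dtype=float), 0.0)

    def f(idx_half: int, y: float) -> float:
        return -float(mat.g(y, psivals[idx_half]))

    ss = [0.0]
    ys = [mat.x2]
    ds = [f(0, mat.x2)]
    y = mat.x2
    crossed = False
    for i in range(n_steps):
        s = i * dt
        k1 = f(2 * i, y)
        k2 = f(2 * i + 1, y + 0.5 * dt * k1)
        k3 = f(2 * i + 1, y + 0.5 * dt * k2)
        k4 = f(2 * i + 2, y + dt * k3)
        y_new = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        ss.append(s + dt)
        ys.append(y_new)
        ds.append(f(2 * i + 2, y_new))
        if y_new <= mat.x1:
            crossed = True
            break
        y = y_new
    if not crossed:
        raise HorizonError(f"maturity x1 not reached within horizon h={h}")
    from scipy.interpolate import CubicHermiteSpline
    spline = CubicHermiteSpline(np.array(ss), np.array(ys), np.array(ds))
    from scipy.optimize import brentq
    tau = brentq(lambda s: float(spline(s)) - mat.x1, ss[-2], ss[-1],
                 xtol=1e-14, rtol=1e-15)

    def traj(s):
        s = np.asarray(s, dtype=float)
        return spline(np.clip(s, 0.0, tau))

    return DelaySolve(tau=float(tau), trajectory=traj, method="fixed",
                      nfev=4 * len(ss))


def threshold_delay(psi: Callable | HistoryPair, config: ModelConfig,
                    h: Optional[float] = None, method: str = "auto") -> float:
    """Threshold delay tau(psi) with y(tau) = x1."""
    return maturity_trajectory(psi, config, h=h, method=method).tau


# ---------------------------------------------------------------------------
# right-hand-side functional
# ---------------------------------------------------------------------------


def _exponent_integral(delay: DelaySolve, psi: Callable, config: ModelConfig) -> float:
    """int_0^tau (d - D1 g)(y(s), psi(-s)) ds; zero when d == 0 and D1 g == 0."""
    if config.d.is_zero and config.mat.is_x_independent:
        return 0.0
    mat, d = config.mat, config.d

    def integrand(s):
        s = np.asarray(s)
        ys = delay(s)
        vs = psi(-s)
        return d(ys, vs) - mat.D1g(ys, vs)

    return gauss_legendre_integral(integrand, 0.0, delay.tau, abstol=1e-10)


def rhs_F(state: HistoryPair, config: ModelConfig, h: Optional[float] = None,
          delay: Optional[DelaySolve] = None) -> tuple[float, float]:
    """The functional F = (F1, F2) driving the model.

    F1(phi, psi) = q(psi(0)) phi(0);
    F2 couples the delayed stem-cell outflow, amplified or attenuated along
    the maturity trajectory, to mature-cell mortality.
    """
    mat, stem = config.mat, config.stem
    phi, psi = state.phi, state.psi
    if h is None:
        h = state.h
    if delay is None:
        delay = maturity_trajectory(psi, config, h=h)
    tau = delay.tau
    psi0 = float(psi(0.0))
    psitau = float(psi(-tau))
    F1 = stem.q(psi0) * float(phi(0.0))
    g2 = mat.g(mat.x2, psi0)
    g1 = mat.g(mat.x1, psitau)
    if g1 <= 0.0 or g2 <= 0.0:
        raise ValueError("maturation rate nonpositive at a boundary evaluation")
    expo = math.exp(_exponent_integral(delay, psi, config))
    F2 = stem.gamma(psitau) * g2 * float(phi(-tau)) / g1 * expo - stem.mu * psi0
    return (float(F1), float(F2))


def solution_manifold_residual(state: HistoryPair, config: ModelConfig,
                               h: Optional[float] = None) -> float:
    """Norm of (phi'(0), psi'(0)) - F(phi, psi).

    Zero exactly on the solution manifold (states that are segments of
    solutions, including equilibria).
    """
    if h is None:
        h = state.h
    F1, F2 = rhs_F(state, config, h=h)
    if state.dphi0 is not None and state.dpsi0 is not None:
        dphi0, dpsi0 = state.dphi0, state.dpsi0
    else:
        # one-sided 2nd-order backward difference at theta = 0
        eps = 1e-6 * max(1.0, h)
        dphi0 = (3.0 * state.phi(0.0) - 4.0 * state.phi(-eps) + state.phi(-2 * eps)) / (2 * eps)
        dpsi0 = (3.0 * state.psi(0.0) - 4.0 * state.psi(-eps) + state.psi(-2 * eps)) / (2 * eps)
    return float(math.hypot(dphi0 - F1, dpsi0 - F2))


# ---------------------------------------------------------------------------
# time integration (method of steps)
# ---------------------------------------------------------------------------


class _PiecewiseHistory:
    """Dense solution record: initial history plus accepted solver segments."""

    def __init__(self, initial: HistoryPair):
        self.initial = initial
        self.seg_bounds: list[tuple[float, float]] = []
        self.segments: list = []  # scipy OdeSolution objects
        self.t_last = 0.0

    def add(self, t_lo: float, t_hi: float, dense) -> None:
        self.seg_bounds.append((t_lo, t_hi))
        self.segments.append(dense)
        self.t_last = t_hi

    def _eval(self, t: float, comp: int) -> float:
        if t <= 0.0:
            f = self.initial.phi if comp == 0 else self.initial.psi
            return float(f(max(t, -self.initial.h)))
        for (lo, hi), seg in zip(self.seg_bounds, self.segments):
            if t <= hi + 1e-14:
                return float(seg(min(t, hi))[comp])
        # slight extrapolation beyond the last accepted step (in-step lookups)
        if self.segments:
            return float(self.segments[-1](t)[comp])
        return float((self.initial.phi if comp == 0 else self.initial.psi)(0.0))

    def w(self, t):
        t = np.asarray(t, dtype=float)
        if t.ndim:
            return np.array([self._eval(ti, 0) for ti in t.ravel()]).reshape(t.shape)
        return self._eval(float(t), 0)

    def v(self, t):
        t = np.asarray(t, dtype=float)
        if t.ndim:
            return np.array([self._eval(ti, 1) for ti in t.ravel()]).reshape(t.shape)
        return self._eval(float(t), 1)


def integrate(initial: HistoryPair, config: ModelConfig, t_end: float,
              rtol: float = 1e-9, atol: float = 1e-11,
              max_step_frac: float = 0.05) -> SolutionPath:
    """Integrate the model forward from a history pair by the method of steps.

    The history is maintained as the initial data plus the dense output of
    every accepted solver window.  In-step delayed lookups that reach past
    the last accepted step use the continuous extension of that step;
    windows are kept below a fraction of the current threshold delay so the
    extension is only ever evaluated over a short overhang.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    h = initial.h
    hist = _PiecewiseHistory(initial)
    ts = [0.0]
    ws = [float(initial.phi(0.0))]
    vs = [float(initial.psi(0.0))]
    taus = []

    t0 = 0.0
    while t0 < t_end - 1e-13:
        psi_t0 = lambda th: hist.v(t0 + np.asarray(th))
        tau0 = threshold_delay(psi_t0, config, h=h)
        taus.append(tau0)
        window = min(t_end - t0, max(0.5 * tau0, 10 * max_step_frac * tau0))
        max_step = max_step_frac * tau0

        def rhs(t, y):
            wv, vv = y
            if vv < -100 * atol - 1e-12:
                raise RuntimeError(f"v(t) left the admissible domain at t={t}: v={vv}")
            vv = max(vv, 0.0)
            t_anchor = hist.t_last
            w_anchor, v_anchor = hist.w(t_anchor), hist.v(t_anchor)

            def lookup(s, comp, cur):
                # history where recorded; linear continuous extension on the
                # short overhang (t_anchor, t] of the step in progress
                if s <= t_anchor or t <= t_anchor:
                    val = hist.w(s) if comp == 0 else hist.v(s)
                else:
                    frac = (s - t_anchor) / (t - t_anchor)
                    base = w_anchor if comp == 0 else v_anchor
                    val = base + frac * (cur - base)
                return max(val, 0.0) if comp == 1 else val

            def phi(th):
                th = np.asarray(th, dtype=float)
                if th.ndim:
                    return np.array([lookup(t + x, 0, wv) for x in th.ravel()]).reshape(th.shape)
                return lookup(t + float(th), 0, wv)

            def psi(th):
                th = np.asarray(th, dtype=float)
                if th.ndim:
                    return np.array([lookup(t + x, 1, vv) for x in th.ravel()]).reshape(th.shape)
                return lookup(t + float(th), 1, vv)

            f1 = config.stem.q(vv) * wv
            delay = maturity_trajectory(psi, config, h=h)
            tau = delay.tau
            psitau = float(psi(-tau))
            g2 = config.mat.g(config.mat.x2, vv)
            g1 = config.mat.g(config.mat.x1, psitau)
            expo = math.exp(_exponent_integral(delay, psi, config))
            f2 = config.stem.gamma(psitau) * g2 * float(phi(-tau)) / g1 * expo \
                - config.stem.mu * vv
            return [f1, f2]

        sol = solve_ivp(rhs, (t0, t0 + window), [ws[-1], vs[-1]], rtol=rtol,
                        atol=atol, max_step=max_step, dense_output=True)
        if not sol.success:
            raise RuntimeError(f"integration aborted at t={t0}: {sol.message}")
        hist.add(t0, sol.t[-1], sol.sol)
        ts.extend(sol.t[1:].tolist())
        ws.extend(sol.y[0, 1:].tolist())
        vs.extend(sol.y[1, 1:].tolist())
        t0 = sol.t[-1]

    return SolutionPath(t=np.array(ts), w_vals=np.array(ws), v_vals=np.array(vs),
                        w=hist.w, v=hist.v, h=h, taus=np.array(taus))
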