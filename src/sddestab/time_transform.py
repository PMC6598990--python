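"""Time transformation to a fixed-delay system when g is maturity-independent.

If the maturation rate depends only on the mature-cell amount, g = g(v),
the threshold condition becomes int_{-tau}^0 g(v(t+theta)) dtheta = delta
with delta = x2 - x1, and rescaling time by the accumulated maturation

    Phi_f(t) = int_0^t g(f(theta)) dtheta      (T_f its inverse-building map)

turns the state-dependent delay into the fixed delay delta.  The
transformed system for (omega, u) = (w, v) o Phi_v^{-1} is driven by the
functional

    G1 = q(u(0)) omega(0) / g(u(0))
    G2 = gamma(u(-delta)) omega(-delta) / g(u(-delta))
         * exp( int_0^delta d(x2 - s, u(-s)) / g(u(-s)) ds )
         - mu u(0) / g(u(0)).

Constant states are equilibria of one system iff of the other, and the
characteristic roots correspond through z <-> z / g(v): stability verdicts
are invariant under the transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .equilibria import Equilibrium, positive_equilibrium
from .pseudospectral import jacobian_eigenvalues
from .rates import ModelConfig
from .sd_dde_core import HistoryPair, SolutionPath, gauss_legendre_integral

__all__ = [
    "TransformedConfig",
    "phi_transform",
    "t_transform",
    "tau_zeta",
    "transformed_rhs_G",
    "transform_solution",
    "eigenvalue_correspondence",
    "make_G_functional",
]


def _require_x_independent(config: ModelConfig) -> Callable:
    if not config.mat.is_x_independent:
        raise ValueError("time transformation requires g independent of maturity")
    mat = config.mat
    return lambda v: mat.g(mat.x2, v)


@dataclass(frozen=True)
class TransformedConfig:
    """A model instance certified for the fixed-delay reformulation."""

    config: ModelConfig
    delta: float

    @classmethod
    def from_config(cls, config: ModelConfig) -> "TransformedConfig":
        _require_x_independent(config)
        return cls(config=config, delta=config.mat.delta)


def phi_transform(f: Callable, t: float, config: ModelConfig,
                  abstol: float = 1e-12) -> float:
    """Phi_f(t): signed integral of g(f(theta)) from 0 to t."""
    g = _require_x_independent(config)
    return gauss_legendre_integral(lambda th: g(f(np.asarray(th))), 0.0, float(t),
                                   abstol=abstol)


def t_transform(f: Callable, phi: float, config: ModelConfig,
                abstol: float = 1e-12) -> float:
    """T_f(phi): signed integral of 1 / g(f(theta)) from 0 to phi."""
    g = _require_x_independent(config)
    return gauss_legendre_integral(lambda th: 1.0 / g(f(np.asarray(th))), 0.0,
                                   float(phi), abstol=abstol)


def tau_zeta(zeta: Callable, config: ModelConfig) -> float:
    """Fixed-delay image of the threshold delay: tau_zeta = -T_zeta(-delta)."""
    delta = config.mat.delta
    return -t_transform(zeta, -delta, config)


def transformed_rhs_G(state: HistoryPair, config: ModelConfig) -> tuple[float, float]:
    """The functional G of the transformed fixed-delay system on [-delta, 0]."""
    g = _require_x_independent(config)
    stem, mat, d = config.stem, config.mat, config.d
    delta = mat.delta
    u0 = float(state.psi(0.0))
    udel = float(state.psi(-delta))
    G1 = stem.q(u0) * float(state.phi(0.0)) / g(u0)
    if d.is_zero:
        expo = 1.0
    else:
        expo = math.exp(gauss_legendre_integral(
            lambda s: d(mat.x2 - np.asarray(s), state.psi(-np.asarray(s)))
            / g(state.psi(-np.asarray(s))), 0.0, delta, abstol=1e-10))
    G2 = stem.gamma(udel) * float(state.phi(-delta)) / g(udel) * expo \
        - stem.mu * u0 / g(u0)
    return (float(G1), float(G2))


def make_G_functional(config: ModelConfig) -> Callable:
    """G as a drop-in functional for the pseudospectral reduction (h = delta)."""
    _require_x_independent(config)
    return lambda state, cfg: transformed_rhs_G(state, cfg)


# ---------------------------------------------------------------------------
# solution correspondence
# ---------------------------------------------------------------------------


def _monotone_map(sample_t: np.ndarray, rate: Callable) -> tuple[Callable, Callable]:
    """Cumulative integral of a positive rate on a grid, with its inverse.

    Returns (forward, inverse) as monotone interpolants through cumulative
    Gauss-Legendre panels.
    """
    vals = [0.0]
    for a, b in zip(sample_t[:-1], sample_t[1:]):
        vals.append(vals[-1] + gauss_legendre_integral(rate, a, b, abstol=1e-12))
    vals = np.array(vals)
    fwd = PchipInterpolator(sample_t, vals, extrapolate=True)
    inv = PchipInterpolator(vals, sample_t, extrapolate=True)
    return fwd, inv


def transform_solution(path: SolutionPath, direction: str, config: ModelConfig,
                       n_grid: int = 400) -> SolutionPath:
    """Map a solution between the original and the fixed-delay time scales.

    ``forward``: (w, v) on original time -> (omega, u) = (w, v) o Phi_v^{-1};
    ``inverse``: (omega, u) on transformed time -> (w, v) = (omega, u) o T_u^{-1}.
    The inverse transforms are built from monotone interpolation of sampled
    cumulative integrals with local polishing by construction of Pchip
    (the integrand is positive, so both maps are strictly increasing).
    """
    g = _require_x_independent(config)
    t_end = float(path.t[-1])
    lo = -path.h
    ts = np.linspace(lo, t_end, n_grid)
    if direction == "forward":
        rate = lambda t: g(np.maximum(path.v(np.asarray(t)), 0.0))  # noqa: E731
    elif direction == "inverse":
        rate = lambda t: 1.0 / g(np.maximum(path.v(np.asarray(t)), 0.0))  # noqa: E731
    else:
        raise ValueError("direction must be 'forward' or 'inverse'")
    # anchor the cumulative map at t = 0 (both transformations fix the origin)
    fwd_part, _ = _monotone_map(ts, rate)
    offset = float(fwd_part(np.array([0.0]))[0]) if hasattr(fwd_part, "__call__") else 0.0
    fwd = lambda t: fwd_part(t) - offset  # noqa: E731
    phis = fwd(ts)
    inv = PchipInterpolator(phis, ts, extrapolate=True)

    new_t = fwd(path.t)
    new_w = lambda ph: path.w(inv(np.asarray(ph)))  # noqa: E731
    new_v = lambda ph: np.maximum(path.v(inv(np.asarray(ph))), 0.0)  # noqa: E731
    return SolutionPath(t=np.asarray(new_t), w_vals=path.w_vals, v_vals=path.v_vals,
                        w=new_w, v=new_v, h=float(-fwd(np.array([lo]))[0]))


# ---------------------------------------------------------------------------
# eigenvalue correspondence
# ---------------------------------------------------------------------------


def _physical_eigs(config: ModelConfig, eq: Equilibrium, M: int,
                   h, functional, match_tol: float = 1e-3) -> np.ndarray:
    """Leading eigenvalues stable under M -> M + 5 (discretisation artifacts
    move with M; converged characteristic-root approximations do not)."""
    e1 = jacobian_eigenvalues(config, eq, M=M, h=h, functional=functional)
    e2 = jacobian_eigenvalues(config, eq, M=M + 5, h=h, functional=functional)
    keep = [lam for lam in e1
            if np.min(np.abs(e2 - lam)) <= match_tol * (1.0 + abs(lam))]
    return np.array(keep)


def eigenvalue_correspondence(config: ModelConfig, M: int = 25, n_lead: int = 6,
                              eq: Equilibrium | None = None) -> dict:
    """Check z <-> z / g(v) between the two systems' leading roots.

    Computes the Jacobian eigenvalues of the pseudospectral reduction of
    the original SD-DDE and of the transformed fixed-delay system, keeps
    those stable under refining the discretisation (the physical ones),
    rescales the former by 1/g(v), and reports the maximal mismatch over
    up to ``n_lead`` rightmost physical roots.
    """
    g = _require_x_independent(config)
    if eq is None:
        eq = positive_equilibrium(config)
    gv = float(g(eq.v))
    eig_F = _physical_eigs(config, eq, M, None, None)
    eig_G = _physical_eigs(config, eq, M, config.mat.delta,
                           make_G_functional(config))
    scaled = eig_F / gv
    lead = scaled[:min(n_lead, len(scaled))]
    mismatch = [float(np.min(np.abs(eig_G - lam))) for lam in lead]
    return {
        "g_at_equilibrium": gv,
        "leading_scaled_roots": [complex(z) for z in lead],
        "n_compared": len(lead),
        "max_mismatch": max(mismatch),
        "mismatches": mismatch,
        "stability_agrees": bool((eig_F[0].real < 0) == (eig_G[0].real < 0)),
    }
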