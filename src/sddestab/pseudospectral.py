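"""Pseudospectral reduction of the delay system to ordinary differential equations.

The state space of the delay system is a pair of functions on [-h, 0].
Collocation at the M+1 Chebyshev extremal nodes

    theta_j = (h/2) (cos(j pi / M) - 1),    j = 0, ..., M,

replaces each function with its degree-M interpolating polynomial, turning
the abstract evolution equation into 2(M+1) ODEs: the node theta_0 = 0
carries the model functional F applied to the interpolants (including the
threshold-delay machinery evaluated on the polynomial history), and the
remaining nodes carry exact polynomial differentiation via the
differentiation matrix d_kj = l_j'(theta_k).  Constant node vectors built
from equilibria of the delay system are equilibria of the reduced ODEs,
and the Jacobian eigenvalues at such states approximate the characteristic
roots with spectral accuracy in M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium, positive_equilibrium
from .rates import ModelConfig
from .sd_dde_core import HistoryPair, resolve_h, rhs_F

__all__ = [
    "ChebyshevDiscretisation",
    "DiscreteState",
    "cheb_nodes",
    "diff_matrix",
    "interp_eval",
    "make_interpolant",
    "assemble_rhs",
    "discrete_equilibrium",
    "jacobian",
    "jacobian_eigenvalues",
    "filter_physical",
    "integrate_ode",
]


def cheb_nodes(M: int, h: float) -> np.ndarray:
    """Chebyshev extremal nodes on [-h, 0], descending from theta_0 = 0."""
    if M < 1:
        raise ValueError("discretisation index M must be >= 1")
    if h <= 0:
        raise ValueError("interval length h must be positive")
    j = np.arange(M + 1)
    return 0.5 * h * (np.cos(j * np.pi / M) - 1.0)


@dataclass(frozen=True)
class ChebyshevDiscretisation:
    """Nodes, differentiation matrix and barycentric weights for one (M, h)."""

    M: int
    h: float
    nodes: np.ndarray
    D: np.ndarray
    bary_w: np.ndarray

    @classmethod
    def build(cls, M: int, h: float) -> "ChebyshevDiscretisation":
        nodes = cheb_nodes(M, h)
        # barycentric weights for Chebyshev extremal points: (-1)^j, halved at ends
        w = np.ones(M + 1)
        w[1::2] = -1.0
        w[0] *= 0.5
        w[M] *= 0.5
        D = _diff_matrix(M, h)
        return cls(M=M, h=h, nodes=nodes, D=D, bary_w=w)


def _diff_matrix(M: int, h: float) -> np.ndarray:
    """Differentiation matrix on the scaled Chebyshev extremal nodes.

    Standard stable construction on x_j = cos(j pi / M) with the
    negative-sum trick for the diagonal, then scaled by the affine map
    theta = (h/2)(x - 1), i.e. d/dtheta = (2/h) d/dx.
    """
    x = np.cos(np.arange(M + 1) * np.pi / M)
    c = np.ones(M + 1)
    c[0] = c[M] = 2.0
    c *= (-1.0) ** np.arange(M + 1)
    X = x[:, None] - x[None, :]
    np.fill_diagonal(X, 1.0)
    D = np.outer(c, 1.0 / c) / X
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return (2.0 / h) * D


def diff_matrix(disc: ChebyshevDiscretisation) -> np.ndarray:
    """The (M+1)x(M+1) differentiation matrix of the discretisation."""
    return disc.D


def interp_eval(values: np.ndarray, disc: ChebyshevDiscretisation, theta):
    """Barycentric evaluation of the degree-M nodal interpolant at theta.

    Exact at the nodes; theta outside [-h, 0] (beyond a small tolerance)
    raises a domain error.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    th = np.atleast_1d(theta)
    tol = 1e-12 * max(1.0, disc.h)
    if np.any(th > tol) or np.any(th < -disc.h - tol):
        raise ValueError("interpolant evaluated outside [-h, 0]")
    th = np.clip(th, -disc.h, 0.0)
    diff = th[:, None] - disc.nodes[None, :]
    exact = np.abs(diff) < 1e-14 * max(1.0, disc.h)
    out = np.empty(th.shape)
    any_exact = exact.any(axis=1)
    if np.any(any_exact):
        idx = np.argmax(exact, axis=1)
        out[any_exact] = values[idx[any_exact]]
    rest = ~any_exact
    if np.any(rest):
        wd = disc.bary_w[None, :] / diff[rest]
        out[rest] = (wd @ values) / wd.sum(axis=1)
    return float(out[0]) if scalar else out


def make_interpolant(values: np.ndarray, disc: ChebyshevDiscretisation) -> Callable:
    values = np.asarray(values, dtype=float)
    return lambda th: interp_eval(values, disc, th)


@dataclass
class DiscreteState:
    """Nodal values (w_j, v_j) attached to a discretisation."""

    w: np.ndarray
    v: np.ndarray
    disc: ChebyshevDiscretisation

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.w, self.v])

    @classmethod
    def from_vector(cls, u: np.ndarray, disc: ChebyshevDiscretisation) -> "DiscreteState":
        n = disc.M + 1
        return cls(w=np.asarray(u[:n], dtype=float),
                   v=np.asarray(u[n:], dtype=float), disc=disc)

    def history(self) -> HistoryPair:
        """The polynomial history pair represented by the nodal values.

        The mature-cell interpolant is clamped at zero: Jacobian probes
        near the extinction state may oscillate infinitesimally below it.
        """
        psi_raw = make_interpolant(np.maximum(self.v, 0.0), self.disc)
        return HistoryPair(phi=make_interpolant(self.w, self.disc),
                           psi=lambda th: np.maximum(psi_raw(th), 0.0),
                           h=self.disc.h)


def assemble_rhs(state: DiscreteState, config: ModelConfig,
                 functional: Optional[Callable] = None) -> np.ndarray:
    """Right-hand side of the reduced ODE system, in block layout [w; v].

    Rows for theta_0 carry the delay functional applied to the polynomial
    interpolants; interior rows carry the differentiation matrix.
    """
    disc = state.disc
    if functional is None:
        functional = lambda st, cfg: rhs_F(st, cfg, h=disc.h)  # noqa: E731
    f1, f2 = functional(state.history(), config)
    out = np.empty(2 * (disc.M + 1))
    n = disc.M + 1
    out[0] = f1
    out[n] = f2
    out[1:n] = disc.D[1:, :] @ state.w
    out[n + 1:] = disc.D[1:, :] @ state.v
    return out


def discrete_equilibrium(eq: Equilibrium, disc: ChebyshevDiscretisation) -> DiscreteState:
    """All-nodes-constant state (w, ..., w, v, ..., v) from an equilibrium."""
    n = disc.M + 1
    return DiscreteState(w=np.full(n, eq.w), v=np.full(n, eq.v), disc=disc)


def jacobian(state: DiscreteState, config: ModelConfig,
             functional: Optional[Callable] = None,
             rel_step: float = 1e-7) -> np.ndarray:
    """Jacobian of the reduced system at a state.

    The differentiation-matrix rows are linear and enter exactly; only the
    two functional rows are differentiated, by central finite differences
    with relative step ``rel_step`` per coordinate.
    """
    disc = state.disc
    if functional is None:
        functional = lambda st, cfg: rhs_F(st, cfg, h=disc.h)  # noqa: E731
    n = disc.M + 1
    dim = 2 * n
    J = np.zeros((dim, dim))
    J[1:n, :n] = disc.D[1:, :]
    J[n + 1:, n:] = disc.D[1:, :]
    u0 = state.as_vector()
    for i in range(dim):
        step = rel_step * max(1.0, abs(u0[i]))
        up = u0.copy()
        um = u0.copy()
        up[i] += step
        um[i] -= step
        # keep the mature-cell interpolant admissible near v = 0
        if i >= n:
            um[i] = max(um[i], 0.0)
        fp = functional(DiscreteState.from_vector(up, disc).history(), config)
        fm = functional(DiscreteState.from_vector(um, disc).history(), config)
        denom = up[i] - um[i]
        J[0, i] = (fp[0] - fm[0]) / denom
        J[n, i] = (fp[1] - fm[1]) / denom
    return J


def jacobian_eigenvalues(config: ModelConfig, eq: Equilibrium | None = None,
                         M: int = 15, h: Optional[float] = None,
                         functional: Optional[Callable] = None,
                         h_factor: float = 2.0) -> np.ndarray:
    """Eigenvalues of the reduced system's Jacobian at an equilibrium.

    Sorted by descending real part; the rightmost entries approximate the
    characteristic roots of the delay system's linearisation.  By default
    h = h_factor * tau at the equilibrium (the horizon must dominate the
    delay); pass h explicitly to pin the discretisation interval.
    """
    if eq is None:
        eq = positive_equilibrium(config)
    if h is None:
        if math.isfinite(eq.tau_eq) and eq.tau_eq > 0:
            h = h_factor * eq.tau_eq
        else:
            h = resolve_h(config)
    disc = ChebyshevDiscretisation.build(M, h)
    state = discrete_equilibrium(eq, disc)
    J = jacobian(state, config, functional=functional)
    eigs = np.linalg.eigvals(J)
    return eigs[np.argsort(-eigs.real)]


def filter_physical(config: ModelConfig, eq: Equilibrium | None = None,
                    M: int = 15, h: Optional[float] = None,
                    functional: Optional[Callable] = None,
                    match_tol: float = 1e-3, n_check: int = 10) -> list[dict]:
    """Flag discretisation artifacts among the leading eigenvalues.

    An eigenvalue is called physical when recomputing at M+5 reproduces it
    within ``match_tol`` (absolute, on a 1 + |lambda| scale).
    """
    e1 = jacobian_eigenvalues(config, eq, M=M, h=h, functional=functional)
    e2 = jacobian_eigenvalues(config, eq, M=M + 5, h=h, functional=functional)
    out = []
    for lam in e1[:n_check]:
        dist = np.min(np.abs(e2 - lam))
        out.append({"eig": complex(lam), "physical": bool(dist <= match_tol * (1.0 + abs(lam))),
                    "match_dist": float(dist)})
    return out


def integrate_ode(state0: DiscreteState, config: ModelConfig, t_end: float,
                  rtol: float = 1e-8, atol: float = 1e-10,
                  functional: Optional[Callable] = None):
    """Time integration of the reduced ODE system (for simulation cross-checks)."""
    disc = state0.disc

    def rhs(t, u):
        return assemble_rhs(DiscreteState.from_vector(u, disc), config,
                            functional=functional)

    sol = solve_ivp(rhs, (0.0, t_end), state0.as_vector(), rtol=rtol, atol=atol,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"reduced-ODE integration failed: {sol.message}")
    return sol
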