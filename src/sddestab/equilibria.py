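"""Equilibria of the stem-cell maturation model.

The trivial equilibrium (0, 0) always exists.  A unique positive
equilibrium (w, v) exists iff q(0) > 0: v is the root of the monotone net
growth rate q, and w follows from balancing the delayed progenitor outflow
against mature-cell mortality,

    w * gamma(v) g(x2, v) / g(x1, v) * exp(int_0^tau (d - D1 g)) = mu v.

For the built-in rate family q(0) > 0 is equivalent to p > mu_w / (2a - 1),
and the two equilibria exchange stability at that transcritical point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .rates import ModelConfig, StemCellParams
from .sd_dde_core import (HistoryPair, _exponent_integral, maturity_trajectory,
                          resolve_h, rhs_F)

__all__ = [
    "Equilibrium",
    "NoPositiveEquilibrium",
    "trivial_equilibrium",
    "existence_threshold",
    "positive_equilibrium",
]

_RESIDUAL_TOL = 1e-10


class NoPositiveEquilibrium(RuntimeError):
    """Raised when q(0) <= 0, i.e. below the transcritical threshold."""


@dataclass(frozen=True)
class Equilibrium:
    """A constant solution (w, v) with a residual certificate."""

    w: float
    v: float
    kind: str  # "trivial" | "positive"
    residual: float
    tau_eq: float

    def as_dict(self) -> dict:
        return {"w": self.w, "v": self.v, "kind": self.kind,
                "residual": self.residual, "tau_eq": self.tau_eq}


def trivial_equilibrium(config: ModelConfig | None = None) -> Equilibrium:
    """The extinction state (0, 0); residual is identically zero."""
    tau0 = float("nan")
    if config is not None:
        tau0 = maturity_trajectory(lambda th: 0.0 * np.asarray(th), config,
                                   h=resolve_h(config)).tau
    return Equilibrium(w=0.0, v=0.0, kind="trivial", residual=0.0, tau_eq=tau0)


def existence_threshold(params: StemCellParams) -> float:
    """Critical division rate p* = mu_w / (2a - 1).

    The positive equilibrium exists iff p > p* (equivalently q(0) > 0); at
    p = p* it merges with the trivial equilibrium in a transcritical
    bifurcation.
    """
    if params.a <= 0.5:
        raise ValueError("threshold requires a > 0.5")
    return params.mu_w / (2.0 * params.a - 1.0)


def _root_of_q(stem: StemCellParams, v_cap: float = 1e6) -> float:
    """Bracket and polish the unique root of the monotone rate q on [0, inf)."""
    q0 = stem.q(0.0)
    if q0 <= 0.0:
        raise NoPositiveEquilibrium(
            f"q(0) = {q0:.6g} <= 0: no positive equilibrium "
            f"(p <= {existence_threshold(stem):.6g})")
    hi = 1.0
    while stem.q(hi) > 0.0:
        hi *= 2.0
        if hi > v_cap:
            raise RuntimeError("could not bracket the root of q below v = 1e6")
    return brentq(stem.q, 0.0, hi, xtol=1e-14, rtol=1e-15)


def positive_equilibrium(config: ModelConfig, h: float | None = None) -> Equilibrium:
    """The unique positive equilibrium, with a full-residual certificate."""
    stem, mat = config.stem, config.mat
    v = _root_of_q(stem)
    if h is None:
        h = max(resolve_h(config), 2.5 * _tau_at(config, v))
    delay = maturity_trajectory(lambda th: v + 0.0 * np.asarray(th), config, h=h)
    expo = math.exp(_exponent_integral(delay, lambda s: v + 0.0 * np.asarray(s), config))
    w = stem.mu * v * mat.g(mat.x1, v) / (stem.gamma(v) * mat.g(mat.x2, v) * expo)
    state = HistoryPair.constant(w, v, h)
    F1, F2 = rhs_F(state, config, h=h, delay=delay)
    residual = math.hypot(F1, F2)
    if residual > _RESIDUAL_TOL * max(1.0, abs(stem.mu * v)):
        raise RuntimeError(f"equilibrium residual {residual:.3e} above tolerance")
    return Equilibrium(w=float(w), v=float(v), kind="positive",
                       residual=float(residual), tau_eq=delay.tau)


def _tau_at(config: ModelConfig, v: float) -> float:
    """Threshold delay at the constant history v (quadrature of 1/g)."""
    mat = config.mat
    x, wq = np.polynomial.legendre.leggauss(32)
    xs = 0.5 * mat.delta * x + 0.5 * (mat.x1 + mat.x2)
    return 0.5 * mat.delta * float(np.sum(wq / mat.g(xs, v)))
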