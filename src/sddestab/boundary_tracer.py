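"""Numerical stability boundaries in the (mu, p) parameter plane.

For a fixed scenario, the positive equilibrium destabilises when the
rightmost characteristic root crosses the imaginary axis.  This module
locates the crossing division rate p at fixed mortality mu by a sign
search on the rightmost Jacobian eigenvalue of the pseudospectral
reduction, traces the resulting boundary polyline over a mu grid with a
secant predictor, and cross-validates against the closed-form boundary
(fixed-delay case) and the time-transformed fixed-delay system wherever
those apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .analytic_boundary import crossing_p_analytic
from .equilibria import (NoPositiveEquilibrium, existence_threshold,
                         positive_equilibrium)
from .pseudospectral import jacobian_eigenvalues
from .rates import ModelConfig
from .time_transform import make_G_functional

__all__ = [
    "BoundaryTrace",
    "CrossingNotFound",
    "rightmost_root",
    "find_crossing_p",
    "trace_boundary",
    "compare_methods",
    "available_methods",
]


class CrossingNotFound(RuntimeError):
    """No sign change of the rightmost root over the searched p range."""


@dataclass
class BoundaryTrace:
    """Ordered polyline of (mu, p) boundary points with per-point certificates."""

    label: str
    method: str
    mu: list = field(default_factory=list)
    p: list = field(default_factory=list)
    omega: list = field(default_factory=list)
    re_residual: list = field(default_factory=list)
    M: int = 15
    truncated: bool = False

    def as_rows(self):
        return list(zip(self.mu, self.p, self.omega, self.re_residual))


def _method_functional(config: ModelConfig, method: str):
    if method == "pseudospectral":
        return None, None
    if method == "transformed":
        return make_G_functional(config), config.mat.delta
    raise ValueError(f"unknown eigenvalue method {method!r}")


def rightmost_root(mu: float, p: float, config: ModelConfig, M: int = 15,
                   equilibrium: str = "positive",
                   method: str = "pseudospectral") -> complex:
    """Rightmost characteristic-root approximation at (mu, p).

    For the trivial equilibrium the exact value max(q(0), -mu) is returned;
    for the positive equilibrium the rightmost Jacobian eigenvalue of the
    chosen reduction.
    """
    cfg = config.with_(mu=mu, p=p)
    if equilibrium == "trivial":
        return complex(max(cfg.stem.q(0.0), -mu))
    functional, h = _method_functional(cfg, method)
    eq = positive_equilibrium(cfg)
    eigs = jacobian_eigenvalues(cfg, eq, M=M, h=h, functional=functional)
    return complex(eigs[0])


def find_crossing_p(mu: float, config: ModelConfig, M: int = 15,
                    p_range: tuple[float, float] = (None, 50.0),
                    method: str = "pseudospectral",
                    n_scan: int = 12) -> dict:
    """Boundary division rate at fixed mu, by root bracketing in p.

    Scans Re of the rightmost root over p in ``p_range`` (lower end
    defaults to just above the transcritical threshold), brackets the first
    sign change and refines it by Brent's method.  Raises
    ``CrossingNotFound`` when the equilibrium stays stable over the whole
    range -- a genuine outcome for some scenarios.
    """
    p_star = existence_threshold(config.stem)
    p_lo = p_range[0] if p_range[0] is not None else p_star * 1.02
    p_hi = p_range[1]
    if p_lo <= p_star:
        p_lo = p_star * 1.02

    def re_max(p):
        return rightmost_root(mu, p, config, M=M, method=method).real

    ps = np.geomspace(p_lo, p_hi, n_scan)
    vals = [re_max(float(p)) for p in ps]
    bracket = None
    for (pa, va), (pb, vb) in zip(zip(ps, vals), zip(ps[1:], vals[1:])):
        if va < 0.0 <= vb or va <= 0.0 < vb or (va < 0.0 and vb >= 0.0):
            bracket = (float(pa), float(pb))
            break
    if bracket is None:
        raise CrossingNotFound(
            f"no destabilisation for mu={mu} with p in ({p_lo:.4g}, {p_hi:.4g})")
    p_cross = brentq(re_max, bracket[0], bracket[1], xtol=1e-10, rtol=4e-14)
    root = rightmost_root(mu, float(p_cross), config, M=M, method=method)
    return {"p_cross": float(p_cross), "omega": abs(root.imag),
            "re_residual": abs(root.real), "mu": float(mu)}


def trace_boundary(config: ModelConfig, mu_grid, M: int = 15,
                   p_range: tuple[float, float] = (None, 50.0),
                   method: str = "pseudospectral") -> BoundaryTrace:
    """Boundary polyline over a mu grid with a secant predictor in p.

    The bracket for each new mu is centred on the secant prediction from
    the previous two points; on corrector failure the bracket is widened,
    then the point is skipped (flagged) if no crossing exists there.
    """
    trace = BoundaryTrace(label=config.label, method=method, M=M)
    prev: list[tuple[float, float]] = []
    for mu in mu_grid:
        rng = p_range
        if len(prev) >= 2:
            (m1, p1), (m2, p2) = prev[-2], prev[-1]
            pred = p2 + (p2 - p1) * (mu - m2) / (m2 - m1) if m2 != m1 else p2
            if pred > 0:
                lo = max(existence_threshold(config.stem) * 1.02, 0.5 * pred)
                rng = (lo, min(p_range[1], 2.0 * pred + 1.0))
        try:
            res = find_crossing_p(mu, config, M=M, p_range=rng, method=method)
        except CrossingNotFound:
            if rng != p_range:
                try:
                    res = find_crossing_p(mu, config, M=M, p_range=p_range,
                                          method=method)
                except CrossingNotFound:
                    trace.truncated = True
                    continue
            else:
                trace.truncated = True
                continue
        except NoPositiveEquilibrium:
            trace.truncated = True
            continue
        trace.mu.append(res["mu"])
        trace.p.append(res["p_cross"])
        trace.omega.append(res["omega"])
        trace.re_residual.append(res["re_residual"])
        prev.append((res["mu"], res["p_cross"]))
    return trace


def available_methods(config: ModelConfig) -> list[str]:
    """Which of the three boundary routes apply to this configuration."""
    methods = ["pseudospectral"]
    if config.mat.is_x_independent:
        methods.append("transformed")
    if (config.mat.is_constant and config.stem.k_a == 0.0 and config.d.is_zero):
        methods.append("analytic")
    return methods


def compare_methods(config: ModelConfig, mu_values, M: int = 15,
                    p_range: tuple[float, float] = (None, 200.0)) -> dict:
    """Pairwise boundary discrepancies between every applicable method.

    Returns per-method crossing p at each mu and the max pairwise relative
    discrepancy; ``pass`` when the latter is below 1e-3 (or only one method
    applies, in which case the single-method status is reported).
    """
    methods = available_methods(config)
    results: dict[str, list[Optional[float]]] = {m: [] for m in methods}
    for mu in mu_values:
        for meth in methods:
            if meth == "analytic":
                gconst = float(config.mat.g(config.mat.x1, 0.0))
                tau = config.mat.delta / gconst
                p = crossing_p_analytic(mu, tau, config.stem.mu_w, config.stem.a)
            else:
                try:
                    p = find_crossing_p(mu, config, M=M, p_range=p_range,
                                        method=meth)["p_cross"]
                except CrossingNotFound:
                    p = None
            results[meth].append(p)
    max_rel = 0.0
    pairs = {}
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            rels = []
            for p1, p2 in zip(results[m1], results[m2]):
                if p1 is None or p2 is None:
                    if p1 is not p2:
                        rels.append(math.inf)
                    continue
                rels.append(abs(p1 - p2) / max(abs(p1), abs(p2)))
            pairs[f"{m1}|{m2}"] = max(rels) if rels else float("nan")
            if rels:
                max_rel = max(max_rel, pairs[f"{m1}|{m2}"])
    return {
        "methods": methods,
        "crossings": results,
        "pairwise_max_rel": pairs,
        "max_rel_discrepancy": max_rel if len(methods) > 1 else float("nan"),
        "pass": (max_rel < 1e-3) if len(methods) > 1 else None,
        "single_method": len(methods) == 1,
    }
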