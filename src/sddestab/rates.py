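"""Model ingredients for the stem-cell maturation model.

The model couples an unstructured stem-cell compartment ``w`` to an
unstructured mature-cell compartment ``v`` through a maturity-structured
progenitor phase on ``[x1, x2]``.  Everything the dynamical equations need
is collected here:

* stem-cell rates -- the net growth rate ``q(v)`` and the progenitor inflow
  rate ``gamma(v)``, built from a regulated division rate
  ``d_w(v) = p / (1 + k_p v)`` and a regulated fraction of self-renewal
  ``s(v) = a / (1 + k_a v)``;
* the progenitor maturation rate
  ``g(x, v) = g0 + 2 p_u(x)/(1 + k1 v) * (1 - a_u(x)/(1 + k2 v))``
  with maturity profiles ``a_u``, ``p_u`` that may be constant, linear,
  quadratic or a user callable;
* the progenitor net production rate ``d(x, v)`` (zero by default);
* closed-form partial derivatives of all of the above, needed by the
  characteristic equation; and
* the named parameter scenarios used throughout the numerical studies.

All amounts are in cells (arbitrary units), all rates in 1/time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Profile",
    "DProfile",
    "StemCellParams",
    "MaturationParams",
    "ModelConfig",
    "RateDerivatives",
    "eval_q",
    "eval_gamma",
    "eval_g",
    "eval_d",
    "rate_derivatives",
    "scenario",
    "SCENARIO_STEM",
    "SCENARIO_PV",
]

_FD_REL_STEP = 1e-6  # central finite-difference relative step for callables


_V_NEG_TOL = 1e-8  # roundoff slack: interpolated histories may dip below 0


def _check_v(v):
    """Reject genuinely negative v; clamp sub-roundoff negatives to zero."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr < -_V_NEG_TOL):
        raise ValueError("mature-cell amount v must be nonnegative")
    clipped = np.maximum(arr, 0.0)
    return float(clipped) if clipped.ndim == 0 else clipped


# ---------------------------------------------------------------------------
# maturity profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Profile:
    """A maturity-dependent coefficient on [x1, x2].

    Built-in profiles are polynomials of degree <= 2 stored as coefficients
    ``(c0, c1, c2)`` of ``c0 + c1 x + c2 x**2``; derivatives are exact.  An
    arbitrary callable may be supplied instead, in which case derivatives
    fall back to central finite differences (relative step 1e-6).
    """

    coeffs: Optional[tuple] = None
    func: Optional[Callable[[float], float]] = None
    name: str = "constant"

    def __post_init__(self):
        if (self.coeffs is None) == (self.func is None):
            raise ValueError("Profile needs exactly one of coeffs or func")

    @classmethod
    def constant(cls, c: float) -> "Profile":
        return cls(coeffs=(float(c), 0.0, 0.0), name="constant")

    @classmethod
    def linear(cls, c0: float, c1: float) -> "Profile":
        return cls(coeffs=(float(c0), float(c1), 0.0), name="linear")

    @classmethod
    def quadratic(cls, c0: float, c1: float, c2: float) -> "Profile":
        return cls(coeffs=(float(c0), float(c1), float(c2)), name="quadratic")

    @classmethod
    def from_callable(cls, f: Callable[[float], float], name: str = "callable") -> "Profile":
        return cls(func=f, name=name)

    @property
    def is_constant(self) -> bool:
        return self.coeffs is not None and self.coeffs[1] == 0.0 and self.coeffs[2] == 0.0

    def __call__(self, x):
        if self.coeffs is not None:
            c0, c1, c2 = self.coeffs
            return c0 + x * (c1 + c2 * x)
        return self.func(x)

    def deriv(self, x):
        if self.coeffs is not None:
            _, c1, c2 = self.coeffs
            return c1 + 2.0 * c2 * x
        step = _FD_REL_STEP * (1.0 + abs(x))
        return (self.func(x + step) - self.func(x - step)) / (2.0 * step)

    def deriv2(self, x):
        if self.coeffs is not None:
            return 2.0 * self.coeffs[2] + 0.0 * x
        step = (_FD_REL_STEP ** 0.5) * (1.0 + abs(x))
        return (self.func(x + step) - 2.0 * self.func(x) + self.func(x - step)) / step**2


@dataclass(frozen=True)
class DProfile:
    """Progenitor net production rate d(x, v); identically zero by default.

    The default models balanced progenitor self-renewal and death.  A custom
    rate can be supplied as a callable ``d(x, v)``, optionally with exact
    partial derivatives; missing derivatives use central finite differences.
    """

    func: Optional[Callable[[float, float], float]] = None
    d1: Optional[Callable[[float, float], float]] = None
    d2: Optional[Callable[[float, float], float]] = None

    @property
    def is_zero(self) -> bool:
        return self.func is None

    @classmethod
    def zero(cls) -> "DProfile":
        return cls()

    @classmethod
    def constant(cls, c: float) -> "DProfile":
        return cls(func=lambda x, v: c + 0.0 * np.asarray(x) * np.asarray(v),
                   d1=lambda x, v: 0.0 * np.asarray(x),
                   d2=lambda x, v: 0.0 * np.asarray(x))

    def __call__(self, x, v):
        if self.func is None:
            return 0.0 * (np.asarray(x) + np.asarray(v))
        return self.func(x, v)

    def deriv_x(self, x, v):
        if self.func is None:
            return 0.0 * (np.asarray(x) + np.asarray(v))
        if self.d1 is not None:
            return self.d1(x, v)
        step = _FD_REL_STEP * (1.0 + abs(x))
        return (self.func(x + step, v) - self.func(x - step, v)) / (2.0 * step)

    def deriv_v(self, x, v):
        if self.func is None:
            return 0.0 * (np.asarray(x) + np.asarray(v))
        if self.d2 is not None:
            return self.d2(x, v)
        step = _FD_REL_STEP * (1.0 + abs(v))
        return (self.func(x, v + step) - self.func(x, v - step)) / (2.0 * step)


# ---------------------------------------------------------------------------
# stem-cell rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StemCellParams:
    """Stem-cell and mature-cell rate parameters.

    mu    : mature-cell per-capita death rate (1/time, > 0)
    mu_w  : stem-cell mortality rate (1/time, >= 0)
    a     : maximal fraction of self-renewal (dimensionless, > 0.5)
    p     : maximal division rate (1/time, >= 0)
    k_a   : feedback strength of mature cells on self-renewal (>= 0)
    k_p   : feedback strength of mature cells on division (>= 0)
    """

    mu: float
    mu_w: float = 1.0
    a: float = 0.9
    p: float = 2.0
    k_a: float = 0.0
    k_p: float = 0.0

    def __post_init__(self):
        for name in ("mu", "mu_w", "a", "p", "k_a", "k_p"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val}")
            if val < 0:
                raise ValueError(f"{name} must be nonnegative, got {val}")
        if self.mu <= 0:
            raise ValueError("mature-cell death rate mu must be positive")
        if self.a <= 0.5:
            raise ValueError("maximal self-renewal fraction a must exceed 0.5")

    # -- rate functions ----------------------------------------------------

    def s(self, v):
        v = _check_v(v)
        return self.a / (1.0 + self.k_a * v)

    def d_w(self, v):
        v = _check_v(v)
        return self.p / (1.0 + self.k_p * v)

    def q(self, v):
        return (2.0 * self.s(v) - 1.0) * self.d_w(v) - self.mu_w

    def gamma(self, v):
        return 2.0 * (1.0 - self.s(v)) * self.d_w(v)

    # -- closed-form derivatives in v ---------------------------------------

    def s_prime(self, v):
        v = _check_v(v)
        return -self.a * self.k_a / (1.0 + self.k_a * v) ** 2

    def d_w_prime(self, v):
        v = _check_v(v)
        return -self.p * self.k_p / (1.0 + self.k_p * v) ** 2

    def q_prime(self, v):
        return 2.0 * self.s_prime(v) * self.d_w(v) + (2.0 * self.s(v) - 1.0) * self.d_w_prime(v)

    def gamma_prime(self, v):
        return -2.0 * self.s_prime(v) * self.d_w(v) + 2.0 * (1.0 - self.s(v)) * self.d_w_prime(v)


def eval_q(v, params: StemCellParams):
    """Net per-capita growth rate of the stem-cell population."""
    return params.q(v)


def eval_gamma(v, params: StemCellParams):
    """Rate of inflow into the progenitor compartment per stem cell."""
    return params.gamma(v)


# ---------------------------------------------------------------------------
# maturation rate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaturationParams:
    """Progenitor maturation-rate parameters on the maturity interval [x1, x2].

    The rate ``g(x, v) = g0 + 2 p_u(x)/(1+k1 v) * (1 - a_u(x)/(1+k2 v))``
    combines a baseline speed ``g0`` with a division-driven component whose
    feedback on ``v`` can be decreasing (k1 > 0) or increasing (k2 > 0).
    Positivity of g is checked on a grid at construction.
    """

    x1: float = 0.0
    x2: float = 1.0
    g0: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    a_u: Profile = field(default_factory=lambda: Profile.constant(0.0))
    p_u: Profile = field(default_factory=lambda: Profile.constant(0.0))
    v_check_max: float = 100.0

    def __post_init__(self):
        if not self.x2 > self.x1:
            raise ValueError("maturity interval requires x2 > x1")
        for name in ("g0", "k1", "k2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        # positivity of g on a grid over [x1,x2] x [0, v_check_max]
        xs = np.linspace(self.x1, self.x2, 101)
        vs = np.linspace(0.0, self.v_check_max, 101)
        gv = self.g(xs[:, None], vs[None, :])
        if np.any(gv <= 0.0):
            raise ValueError(
                "maturation rate g(x, v) is not positive on "
                f"[{self.x1}, {self.x2}] x [0, {self.v_check_max}]"
            )

    @property
    def delta(self) -> float:
        """Width of the maturity interval, x2 - x1."""
        return self.x2 - self.x1

    @property
    def is_x_independent(self) -> bool:
        """True when D1 g == 0, i.e. both maturity profiles are constant."""
        return (self.p_u.is_constant and self.a_u.is_constant) or (
            self.p_u.is_constant and self.p_u.coeffs[0] == 0.0
        )

    @property
    def is_constant(self) -> bool:
        """True when g is a single constant (no x nor v dependence)."""
        return self.is_x_independent and self.k1 == 0.0 and self.k2 == 0.0

    # -- g and its partial derivatives --------------------------------------

    def g(self, x, v):
        v = _check_v(v)
        A1 = 1.0 / (1.0 + self.k1 * v)
        A2 = 1.0 / (1.0 + self.k2 * v)
        return self.g0 + 2.0 * self.p_u(x) * A1 * (1.0 - self.a_u(x) * A2)

    def D1g(self, x, v):
        v = _check_v(v)
        A1 = 1.0 / (1.0 + self.k1 * v)
        A2 = 1.0 / (1.0 + self.k2 * v)
        P, Pp = self.p_u(x), self.p_u.deriv(x)
        A, Ap = self.a_u(x), self.a_u.deriv(x)
        return 2.0 * Pp * A1 - 2.0 * (Pp * A + P * Ap) * A1 * A2

    def D2g(self, x, v):
        v = _check_v(v)
        A1 = 1.0 / (1.0 + self.k1 * v)
        A2 = 1.0 / (1.0 + self.k2 * v)
        dA1 = -self.k1 * A1**2
        dA2 = -self.k2 * A2**2
        P, A = self.p_u(x), self.a_u(x)
        return 2.0 * P * dA1 - 2.0 * P * A * (dA1 * A2 + A1 * dA2)

    def D1D1g(self, x, v):
        v = _check_v(v)
        A1 = 1.0 / (1.0 + self.k1 * v)
        A2 = 1.0 / (1.0 + self.k2 * v)
        Pp, Ppp = self.p_u.deriv(x), self.p_u.deriv2(x)
        A, Ap, App = self.a_u(x), self.a_u.deriv(x), self.a_u.deriv2(x)
        P = self.p_u(x)
        return 2.0 * Ppp * A1 - 2.0 * (Ppp * A + 2.0 * Pp * Ap + P * App) * A1 * A2

    def D2D1g(self, x, v):
        v = _check_v(v)
        A1 = 1.0 / (1.0 + self.k1 * v)
        A2 = 1.0 / (1.0 + self.k2 * v)
        dA1 = -self.k1 * A1**2
        dA2 = -self.k2 * A2**2
        P, Pp = self.p_u(x), self.p_u.deriv(x)
        A, Ap = self.a_u(x), self.a_u.deriv(x)
        return 2.0 * Pp * dA1 - 2.0 * (Pp * A + P * Ap) * (dA1 * A2 + A1 * dA2)


def eval_g(x, v, params: MaturationParams):
    """Maturation speed g(x, v); raises if the configuration makes it nonpositive."""
    val = params.g(x, v)
    if np.any(np.asarray(val) <= 0.0):
        raise ValueError(f"maturation rate g({x}, {v}) = {val} is not positive")
    return val


# ---------------------------------------------------------------------------
# full model configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """All ingredients of one model instance.

    h is the history horizon: every admissible history lives on [-h, 0] and
    the threshold delay must satisfy tau < h.  When h is None a default
    h = 2 * max tau over constant histories v in [0, v_max] is used
    (resolved lazily by the core module).
    """

    stem: StemCellParams
    mat: MaturationParams
    d: DProfile = field(default_factory=DProfile.zero)
    h: Optional[float] = None
    v_max: float = 10.0
    label: str = ""
    # profiles declared to follow stem-cell parameters across parameter sweeps
    # (the study couples a_u = a and p_u = p unless maturity dependence is
    # specified explicitly)
    track_profiles: frozenset = frozenset()

    def __post_init__(self):
        if self.h is not None and self.h <= 0:
            raise ValueError("history horizon h must be positive")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")

    def with_(self, **kwargs) -> "ModelConfig":
        """Copy with replaced stem-cell fields or top-level fields.

        Maturity profiles listed in ``track_profiles`` are rebuilt so that
        a_u = a and p_u = p stay coupled when those parameters change.
        """
        stem_fields = {"mu", "mu_w", "a", "p", "k_a", "k_p"}
        stem_kw = {k: kwargs.pop(k) for k in list(kwargs) if k in stem_fields}
        cfg = self
        if stem_kw:
            new_stem = replace(cfg.stem, **stem_kw)
            mat_kw = {}
            if "p_u" in cfg.track_profiles and new_stem.p != cfg.stem.p:
                mat_kw["p_u"] = Profile.constant(new_stem.p)
            if "a_u" in cfg.track_profiles and new_stem.a != cfg.stem.a:
                mat_kw["a_u"] = Profile.constant(new_stem.a)
            new_mat = replace(cfg.mat, **mat_kw) if mat_kw else cfg.mat
            cfg = replace(cfg, stem=new_stem, mat=new_mat)
        if kwargs:
            cfg = replace(cfg, **kwargs)
        return cfg


def eval_d(x, v, config: ModelConfig):
    """Progenitor net production rate d(x, v) (zero for the default profile)."""
    return config.d(x, v)


# ---------------------------------------------------------------------------
# derivative bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateDerivatives:
    """Closed-form partial derivatives of all model rates.

    Every field is a callable; names follow positional-derivative notation
    (D1 = derivative in maturity x, D2 = derivative in mature-cell amount v).
    """

    q_prime: Callable
    gamma_prime: Callable
    D1g: Callable
    D2g: Callable
    D1D1g: Callable
    D2D1g: Callable
    D1d: Callable
    D2d: Callable


def rate_derivatives(config: ModelConfig) -> RateDerivatives:
    """Partial derivatives of q, gamma, g and d for one model instance."""
    stem, mat, d = config.stem, config.mat, config.d
    return RateDerivatives(
        q_prime=stem.q_prime,
        gamma_prime=stem.gamma_prime,
        D1g=mat.D1g,
        D2g=mat.D2g,
        D1D1g=mat.D1D1g,
        D2D1g=mat.D2D1g,
        D1d=d.deriv_x,
        D2d=d.deriv_v,
    )


def fd_check_derivatives(config: ModelConfig, v: float, x: float | None = None,
                         rel_step: float = _FD_REL_STEP) -> dict:
    """Central finite-difference values of the same partials, for cross-checks."""
    stem, mat = config.stem, config.mat
    hv = rel_step * (1.0 + abs(v))
    out = {
        "q_prime": (stem.q(v + hv) - stem.q(max(v - hv, 0.0))) / (hv + min(v, hv)),
        "gamma_prime": (stem.gamma(v + hv) - stem.gamma(max(v - hv, 0.0))) / (hv + min(v, hv)),
    }
    if x is not None:
        hx = rel_step * (1.0 + abs(x))
        out["D1g"] = (mat.g(x + hx, v) - mat.g(x - hx, v)) / (2 * hx)
        out["D2g"] = (mat.g(x, v + hv) - mat.g(x, max(v - hv, 0.0))) / (hv + min(v, hv))
        out["D1D1g"] = (mat.D1g(x + hx, v) - mat.D1g(x - hx, v)) / (2 * hx)
        out["D2D1g"] = (mat.D1g(x, v + hv) - mat.D1g(x, max(v - hv, 0.0))) / (hv + min(v, hv))
    return out


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

SCENARIO_STEM = {
    # regulated self-renewal, unregulated division
    "(s)_s": {"k_a": 1.0, "k_p": 0.0},
    # unregulated self-renewal, regulated division
    "(s)_d": {"k_a": 0.0, "k_p": 1.0},
}

SCENARIO_PV = {
    "(pv)_0": {"k1": 0.0, "k2": 0.0},
    "(pv)_1": {"k1": 1.0, "k2": 0.0},
    "(pv)_2": {"k1": 0.0, "k2": 1.0},
}

# maturity-dependent coefficient sets: a_u(x) options per p_u choice
_PX_AU = {
    "(px)_1": {
        "constant": Profile.constant(1.0 / 3.0),
        "linear": Profile.linear(2.0 / 3.0, -2.0 / 3.0),          # 2/3 (1 - x)
        "quadratic": Profile.quadratic(0.1 + 2.8 * 0.25, -2.8, 2.8),  # 0.1 + 2.8 (x - 1/2)^2
    },
    "(px)_2": {
        "constant": Profile.constant(0.9),
        "linear": Profile.linear(0.99, -0.18),
        "quadratic": Profile.quadratic(0.855 - 0.54 * 0.25, 0.54, -0.54),  # 0.855 - 0.54 (x-1/2)^2
    },
}


def _norm_token(tok: str) -> str:
    tok = tok.strip().lower()
    tok = re.sub(r"[(){}\s]", "", tok)  # "(s)_d" -> "s_d"
    return tok


def scenario(label: str, *, mu: float = 1.0, p: float = 2.0, g: float | None = None,
             tau: float | None = None, g0: float | None = None,
             k_a: float | None = None, k_p: float | None = None,
             h: float | None = None, v_max: float = 10.0) -> ModelConfig:
    """Build the named parameter sets of the numerical study.

    ``label`` is a comma-separated combination of tokens:

    * stem-cell regulation: ``(s)_s`` (k_a=1, k_p=0) or ``(s)_d`` (k_a=0, k_p=1);
    * maturation feedback: ``(pv)_0`` (none), ``(pv)_1`` (k1=1), ``(pv)_2`` (k2=1);
    * maturity dependence: ``(px)_1`` (p_u = 0.3) or ``(px)_2`` (p_u = p),
      optionally followed by an ``a_u`` shape token
      ``constant`` | ``linear`` | ``quadratic``.

    Fixed throughout: x1=0, x2=1, mu_w=1, a=0.9.  Without a (px) token the
    profiles are a_u = a, p_u = p (constants), except for ``(pv)_0`` where g
    is a single constant given by ``g`` (or ``tau`` via g = (x2-x1)/tau,
    default g=1).  With a (px) token the baseline g0 defaults to 0.
    """
    tokens = [_norm_token(t) for t in label.split(",") if t.strip()]
    stem_kw = {"mu": mu, "mu_w": 1.0, "a": 0.9, "p": p}
    pv_kw = {"k1": 0.0, "k2": 0.0}
    px_token = None
    shape = None
    stem_token = None
    for tok in tokens:
        if tok in ("s_s", "s_d"):
            stem_token = "(" + tok[0] + ")_" + tok[-1]
            stem_kw.update(SCENARIO_STEM[stem_token])
        elif tok in ("pv_0", "pv_1", "pv_2"):
            pv_kw = dict(SCENARIO_PV["(pv)_" + tok[-1]])
        elif tok in ("px_1", "px_2"):
            px_token = "(px)_" + tok[-1]
        elif tok in ("constant", "linear", "quadratic"):
            shape = tok
        else:
            raise KeyError(f"unknown scenario token {tok!r} in label {label!r}")
    if stem_token is None:
        stem_token = "(s)_d"
        stem_kw.update(SCENARIO_STEM[stem_token])
    if k_a is not None:
        stem_kw["k_a"] = k_a
    if k_p is not None:
        stem_kw["k_p"] = k_p

    x1, x2 = 0.0, 1.0
    if px_token is not None:
        shape = shape or "constant"
        a_u = _PX_AU[px_token][shape]
        p_u = Profile.constant(0.3) if px_token == "(px)_1" else Profile.constant(p)
        track = frozenset() if px_token == "(px)_1" else frozenset({"p_u"})
        base_g0 = 0.0 if g0 is None else g0
    elif pv_kw["k1"] == 0.0 and pv_kw["k2"] == 0.0 and g0 is None:
        # constant maturation rate: g is a free parameter (or fixed via tau)
        if tau is not None:
            g = (x2 - x1) / tau
        g_const = 1.0 if g is None else g
        if g_const <= 0:
            raise ValueError("constant maturation rate must be positive")
        a_u = Profile.constant(0.0)
        p_u = Profile.constant(0.0)
        track = frozenset()
        base_g0 = g_const
    else:
        a_u = Profile.constant(0.9)
        p_u = Profile.constant(p)
        track = frozenset({"p_u", "a_u"})
        base_g0 = 1.0 if g0 is None else g0

    mat = MaturationParams(x1=x1, x2=x2, g0=base_g0, a_u=a_u, p_u=p_u,
                           v_check_max=max(100.0, v_max), **pv_kw)
    stem = StemCellParams(**stem_kw)
    return ModelConfig(stem=stem, mat=mat, d=DProfile.zero(), h=h, v_max=v_max,
                       label=label, track_profiles=track)
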