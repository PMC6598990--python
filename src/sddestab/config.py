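"""Structured text (TOML) configuration files for model instances.

Two styles are accepted.  Scenario style::

    scenario = "(s)_d,(pv)_0"
    [overrides]
    mu = 1.0
    p = 2.0
    tau = 1.5        # fixes the constant maturation rate g = (x2-x1)/tau

Explicit style::

    [stem]
    mu = 1.0
    mu_w = 1.0
    a = 0.9
    p = 2.0
    k_a = 0.0
    k_p = 1.0

    [maturation]
    x1 = 0.0
    x2 = 1.0
    g0 = 0.0
    k1 = 0.0
    k2 = 0.0
    a_u = { kind = "quadratic", coeffs = [0.8, -2.8, 2.8] }
    p_u = { kind = "constant", coeffs = [0.3] }

    [model]
    h = 5.0          # optional; omit for the automatic horizon
    v_max = 10.0
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .rates import (ModelConfig, MaturationParams, Profile, StemCellParams,
                    scenario)

__all__ = ["load_config", "config_from_dict"]

_PROFILE_KINDS = {"constant": 1, "linear": 2, "quadratic": 3}


def _profile_from_spec(spec) -> Profile:
    if isinstance(spec, (int, float)):
        return Profile.constant(float(spec))
    kind = spec.get("kind", "constant")
    coeffs = [float(c) for c in spec.get("coeffs", [0.0])]
    n = _PROFILE_KINDS.get(kind)
    if n is None:
        raise ValueError(f"unknown profile kind {kind!r}")
    if len(coeffs) != n:
        raise ValueError(f"{kind} profile needs {n} coefficients, got {len(coeffs)}")
    coeffs = coeffs + [0.0] * (3 - len(coeffs))
    return Profile(coeffs=tuple(coeffs), name=kind)


def config_from_dict(data: dict) -> ModelConfig:
    """Build a model configuration from parsed TOML data."""
    if "scenario" in data:
        overrides = dict(data.get("overrides", {}))
        return scenario(data["scenario"], **overrides)
    stem = StemCellParams(**{k: float(v) for k, v in data.get("stem", {}).items()})
    mat_data = dict(data.get("maturation", {}))
    a_u = _profile_from_spec(mat_data.pop("a_u", 0.0))
    p_u = _profile_from_spec(mat_data.pop("p_u", 0.0))
    mat = MaturationParams(a_u=a_u, p_u=p_u,
                           **{k: float(v) for k, v in mat_data.items()})
    model = data.get("model", {})
    return ModelConfig(stem=stem, mat=mat,
                       h=model.get("h"), v_max=float(model.get("v_max", 10.0)),
                       label=data.get("label", ""))


def load_config(path: str | Path) -> ModelConfig:
    """Read a model configuration from a TOML file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)
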