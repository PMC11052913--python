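"""Model catalogue: 25 density-based plus 3 association-theory correlations."""

from __future__ import annotations

import json

from .base import (EvaluationError, ModelEnv, ModelSpec, P_REF_MPA, RHO_REF,
                   env_from_arrays, make_env, native_to_y2, y2_to_native)
from .density import density_models
from .association import (association_models, predict_modified_pressure,
                          predict_modified_reduced, predict_rajasekhar_madras)

__all__ = [
    "EvaluationError", "ModelEnv", "ModelSpec", "P_REF_MPA", "RHO_REF",
    "env_from_arrays", "make_env", "native_to_y2", "y2_to_native",
    "density_models", "association_models", "registry", "get_model",
    "catalogue_json", "predict_rajasekhar_madras", "predict_modified_reduced",
    "predict_modified_pressure",
]


def registry(family: str | None = None) -> tuple[ModelSpec, ...]:
    """All registered models, optionally filtered by family."""
    specs = density_models() + association_models()
    if family is not None:
        specs = tuple(s for s in specs if s.family == family)
    return specs


def get_model(key: str) -> ModelSpec:
    for spec in registry():
        if spec.key == key:
            return spec
    raise KeyError(f"no model registered under key {key!r}")


def catalogue_json() -> str:
    """Machine-readable catalogue (name, group, parameter count, formula)."""
    return json.dumps([
        {"key": s.key, "name": s.name, "group": s.group, "family": s.family,
         "n_params": s.n_params, "formula": s.formula,
         "linear_in_params": s.linear_in_params}
        for s in registry()], indent=2)
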