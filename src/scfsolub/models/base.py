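"""Model-catalogue machinery shared by density-based and association models.

Every correlation is described by a :class:`ModelSpec`: a named equation
with an ordered parameter vector, a *native prediction space* (the
left-hand side of its published form, e.g. ``ln S`` for Chrastil or
``T ln(y2 P)`` for Mendez-Santiago-Teja), and, for equations that are
linear in their parameters after the native-space transform, a design
function enabling exact ordinary-least-squares sub-solves.

Unit conventions inside a :class:`ModelEnv`: temperature K, pressure both
bar and MPa, density kg/m^3 plus the reduced and molar (mol/mL) forms.
Reduced variables are always computed from the solvent's critical
constants; the reference pressure is 0.1 MPa and the reference density
700 kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..data import SolubilityDataset, SolventInfo, SoluteInfo

#: Reference pressure (MPa) for pressure-ratio terms.
P_REF_MPA = 0.1
#: Reference density (kg/m^3) for density-offset terms.
RHO_REF = 700.0

#: Native prediction spaces: how the model's left-hand side maps to y2.
SPACES = ("lny2", "y2", "lnS", "S", "Tlny2P", "lny2P_ratio")


class EvaluationError(ArithmeticError):
    """A model produced a non-finite intermediate for given parameters."""

    def __init__(self, model: str, detail: str):
        super().__init__(f"model '{model}': {detail}")
        self.model = model
        self.detail = detail


@dataclass(frozen=True)
class ModelEnv:
    """State variables of a record set, in every unit a model may need."""

    T: np.ndarray          # K
    P_bar: np.ndarray
    P_mpa: np.ndarray
    rho: np.ndarray        # kg/m^3
    T_r: np.ndarray
    P_r: np.ndarray
    rho_r: np.ndarray
    rho_mol_ml: np.ndarray
    m_solvent: float
    m_solute: float
    y2_obs: np.ndarray | None = None


def make_env(dataset: SolubilityDataset) -> ModelEnv:
    a = dataset.arrays()
    return env_from_arrays(a["T"], a["P"], a["rho"], dataset.solvent, dataset.solute,
                           y2_obs=a["y2"])


def env_from_arrays(T, P_bar, rho, solvent: SolventInfo, solute: SoluteInfo,
                    y2_obs=None) -> ModelEnv:
    T = np.asarray(T, float)
    P_bar = np.asarray(P_bar, float)
    rho = np.asarray(rho, float)
    P_mpa = P_bar / 10.0
    return ModelEnv(
        T=T, P_bar=P_bar, P_mpa=P_mpa, rho=rho,
        T_r=T / solvent.t_crit, P_r=P_mpa / solvent.p_crit, rho_r=rho / solvent.rho_crit,
        # kg/m^3 -> mol/mL: (g/L) / (g/mol) / 1000
        rho_mol_ml=rho / (solvent.molar_mass * 1000.0),
        m_solvent=solvent.molar_mass, m_solute=solute.molar_mass,
        y2_obs=None if y2_obs is None else np.asarray(y2_obs, float),
    )


@dataclass(frozen=True)
class ModelSpec:
    """One correlation equation and its metadata.

    ``design(env) -> (X, offset)`` gives the native-space value as
    ``X @ transform(params) + offset`` for models with
    ``linear_in_params``; ``native_fn(params, env)`` overrides it for the
    two genuinely nonlinear forms. ``depends_on`` lists the physical
    state variables (T, P, rho) the equation uses, reduced forms counting
    as their base variable; its size is the Q of the adjusted-R2 formula.
    """

    key: str
    name: str
    group: str                      # "I" | "II" | "III" | "association"
    family: str                     # "density" | "association"
    formula: str
    space: str
    param_names: tuple[str, ...]
    depends_on: frozenset[str]
    linear_in_params: bool = True
    design: Callable[[ModelEnv], tuple[np.ndarray, np.ndarray | float]] | None = None
    native_fn: Callable[[np.ndarray, ModelEnv], np.ndarray] | None = None
    # transform between the published parameters and the linear solve space
    to_linear: Callable[[np.ndarray], np.ndarray] | None = None
    from_linear: Callable[[np.ndarray], np.ndarray] | None = None
    bounds: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"unknown prediction space {self.space!r}")
        if self.design is None and self.native_fn is None:
            raise ValueError(f"model {self.key!r} needs a design or a native_fn")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_bounds(self) -> tuple[tuple[float, float], ...]:
        if self.bounds is not None:
            return self.bounds
        return tuple((-1e6, 1e6) for _ in self.param_names)

    def native(self, params, env: ModelEnv) -> np.ndarray:
        """Evaluate the model's left-hand side in its native space."""
        params = np.asarray(params, float)
        if params.shape != (self.n_params,):
            raise ValueError(f"model {self.key!r} expects {self.n_params} parameters, "
                             f"got shape {params.shape}")
        if self.native_fn is not None:
            return np.asarray(self.native_fn(params, env), float)
        X, offset = self.design(env)
        q = params if self.to_linear is None else self.to_linear(params)
        return X @ q + offset

    def predict_y2(self, params, env: ModelEnv) -> np.ndarray:
        """Predict mole fractions, converting from the native space."""
        v = self.native(params, env)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            y = native_to_y2(self.space, v, env)
        if not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(np.atleast_1d(y))))
            raise EvaluationError(self.key, f"non-finite prediction at point {bad} "
                                            f"(native value {np.atleast_1d(v)[bad]!r})")
        return y


def _y2_from_S(S, env: ModelEnv):
    r = S * env.m_solvent / (env.rho * env.m_solute)
    return r / (1.0 + r)


def native_to_y2(space: str, v, env: ModelEnv):
    """Map a native-space value to mole fraction."""
    if space == "lny2":
        return np.exp(v)
    if space == "y2":
        return v
    if space == "lnS":
        return _y2_from_S(np.exp(v), env)
    if space == "S":
        return _y2_from_S(v, env)
    if space == "Tlny2P":
        return np.exp(v / env.T) / env.P_bar
    if space == "lny2P_ratio":
        return P_REF_MPA * np.exp(v) / env.P_mpa
    raise ValueError(f"unknown prediction space {space!r}")


def y2_to_native(space: str, env: ModelEnv):
    """Observed mole fractions transformed into a model's native space."""
    y2 = env.y2_obs
    if y2 is None:
        raise ValueError("environment carries no observed mole fractions")
    if space == "lny2":
        return np.log(y2)
    if space == "y2":
        return y2.copy()
    S = env.rho * (env.m_solute / env.m_solvent) * y2 / (1.0 - y2)
    if space == "lnS":
        return np.log(S)
    if space == "S":
        return S
    if space == "Tlny2P":
        return env.T * np.log(y2 * env.P_bar)
    if space == "lny2P_ratio":
        return np.log(y2 * env.P_mpa / P_REF_MPA)
    raise ValueError(f"unknown prediction space {space!r}")
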