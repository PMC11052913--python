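"""Association-theory solid-liquid-equilibrium solubility models.

Association theory assumes each solute molecule complexes with kappa
solvent molecules; working through the fugacity balance of the complex
(with the solvent mole fraction taken as 1 for a sparingly soluble
binary system) collapses every molecular quantity - sublimation
pressure, solvation enthalpy, fugacity coefficients, molar volume - into
a handful of lumped constants, leaving

    y2 = (P / P*)^(kappa - 1) * exp(<linear terms in state variables>)

with standard pressure P* = 0.1 MPa. Three variants are implemented:

* ``rajasekhar_madras``:  exp(D1 / T + D2 rho + D3), rho in mol/mL;
* ``assoc_reduced``:      exp(A1 / T_r + A2 rho_r + A3), reduced variables;
* ``assoc_pressure``:     exp(C1 / T + C2 rho + C3 P + C4), rho in mol/mL,
  P in MPa - this nests ``rajasekhar_madras`` exactly at C3 = 0.

The association number kappa is fitted as a continuous parameter in
[-10, 10]: published fits report non-integer and occasionally negative
values, so it is treated as a free shape parameter rather than a
physical stoichiometry.
"""

from __future__ import annotations

import numpy as np

from .base import ModelEnv, ModelSpec, P_REF_MPA


def _log_pressure_ratio(env: ModelEnv) -> np.ndarray:
    return np.log(env.P_mpa / P_REF_MPA)


def _assoc_design(extra_cols):
    """ln y2 = kappa ln(P/P*) + <coeff terms>  - ln(P/P*)  (linear in params)."""

    def design(env: ModelEnv):
        lpp = _log_pressure_ratio(env)
        cols = [lpp] + [f(env) for f in extra_cols] + [np.ones_like(env.T)]
        return np.column_stack(cols), -lpp

    return design


_KAPPA_BOUND = (-10.0, 10.0)
_WIDE = (-1e6, 1e6)

_SPECS = (
    ModelSpec(
        key="rajasekhar_madras", name="Rajasekhar-Madras", group="association",
        family="association",
        formula="y2 = (P/P*)^(kappa-1) exp(D1 / T + D2 rho[mol/mL] + D3)   [P in MPa, P* = 0.1]",
        space="lny2", param_names=("kappa", "D1", "D2", "D3"),
        depends_on=frozenset({"T", "P", "rho"}),
        design=_assoc_design([lambda e: 1.0 / e.T, lambda e: e.rho_mol_ml]),
        bounds=(_KAPPA_BOUND, _WIDE, _WIDE, _WIDE)),
    ModelSpec(
        key="assoc_reduced", name="Modified association (reduced)", group="association",
        family="association",
        formula="y2 = (P/P*)^(kappa-1) exp(A1 / T_r + A2 rho_r + A3)",
        space="lny2", param_names=("kappa", "A1", "A2", "A3"),
        depends_on=frozenset({"T", "P", "rho"}),
        design=_assoc_design([lambda e: 1.0 / e.T_r, lambda e: e.rho_r]),
        bounds=(_KAPPA_BOUND, _WIDE, _WIDE, _WIDE)),
    ModelSpec(
        key="assoc_pressure", name="Modified association (pressure)", group="association",
        family="association",
        formula="y2 = (P/P*)^(kappa-1) exp(C1 / T + C2 rho[mol/mL] + C3 P[MPa] + C4)",
        space="lny2", param_names=("kappa", "C1", "C2", "C3", "C4"),
        depends_on=frozenset({"T", "P", "rho"}),
        design=_assoc_design([lambda e: 1.0 / e.T, lambda e: e.rho_mol_ml,
                              lambda e: e.P_mpa]),
        bounds=(_KAPPA_BOUND, _WIDE, _WIDE, _WIDE, _WIDE)),
)


def association_models() -> tuple[ModelSpec, ...]:
    """The three association-theory specs."""
    return _SPECS


def predict_rajasekhar_madras(params, env: ModelEnv) -> np.ndarray:
    """Evaluate y2 = (P/P*)^(kappa-1) exp(D1/T + D2 rho + D3) directly."""
    return _SPECS[0].predict_y2(params, env)


def predict_modified_reduced(params, env: ModelEnv) -> np.ndarray:
    """Evaluate the reduced-variable modified association model."""
    return _SPECS[1].predict_y2(params, env)


def predict_modified_pressure(params, env: ModelEnv) -> np.ndarray:
    """Evaluate the pressure-extended modified association model."""
    return _SPECS[2].predict_y2(params, env)
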