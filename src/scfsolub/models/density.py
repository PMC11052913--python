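"""The 25 density-based semi-empirical solubility correlations.

Grouped by functional dependence:

* Group I  - density, temperature and pressure (8 models),
* Group II - density and temperature (12 models),
* Group III - pressure and temperature only (5 models).

Each entry is implemented in its canonical published form (fraction bars
and reduced subscripts restored where journal rendering mangles them);
the ``formula`` string on every spec is the authoritative statement of
the form used here. Pressure enters each equation in the unit its
original publication used (bar or MPa, noted in the formula); density in
kg/m^3 unless reduced. Reduced properties use the solvent critical
constants; the reference pressure is 0.1 MPa and the reference density
700 kg/m^3.

All but two models are linear in their parameters after transforming to
the native prediction space, so each carries an exact OLS design. The
exceptions are Mitra-Wilson (a ``d**P`` term) and the implicit Yu
equation, which is solved by its exact closed-form rearrangement
``y2 = (a + bP + cP^2 + dPT + eT + fT^2) / (1 + dPT)``; Yu's initializer
design keeps the published ``d P T (1 - y2)`` column using observed
mole fractions.
"""

from __future__ import annotations

import numpy as np

from .base import ModelEnv, ModelSpec, RHO_REF


def _ones(env: ModelEnv) -> np.ndarray:
    return np.ones_like(env.T)


def _col(*cols) -> np.ndarray:
    return np.column_stack(cols)


_SPECS: list[ModelSpec] = []


def _register(spec: ModelSpec) -> ModelSpec:
    _SPECS.append(spec)
    return spec


def _linear(key, name, group, space, params, depends, formula, design, bounds=None,
            to_linear=None, from_linear=None):
    return _register(ModelSpec(
        key=key, name=name, group=group, family="density", formula=formula,
        space=space, param_names=tuple(params), depends_on=frozenset(depends),
        linear_in_params=True, design=design, bounds=bounds,
        to_linear=to_linear, from_linear=from_linear))


# --------------------------------------------------------------------------
# Group I: f(rho, T, P)
# --------------------------------------------------------------------------

_linear("mendez_teja", "Mendez-Teja", "I", "Tlny2P", "abc", {"T", "P", "rho"},
        "T ln(y2 P[bar]) = a + b rho + c T",
        lambda e: (_col(_ones(e), e.rho, e.T), 0.0))

_linear("bartle", "Bartle et al.", "I", "lny2P_ratio", "abc", {"T", "P", "rho"},
        "ln(y2 P / P_ref) = a + b (rho - rho_ref) + c / T   [P in MPa, P_ref = 0.1 MPa]",
        lambda e: (_col(_ones(e), e.rho - RHO_REF, 1.0 / e.T), 0.0))

_linear("jafari", "Jafari et al.", "I", "lny2", "abcd", {"T", "P", "rho"},
        "ln y2 = a + b P[bar]^2 + c T^2 + d ln(rho)",
        lambda e: (_col(_ones(e), e.P_bar ** 2, e.T ** 2, np.log(e.rho)), 0.0))

_linear("hozhabr", "Hozhabr et al.", "I", "lny2", "abcd", {"T", "P", "rho"},
        "ln y2 = a + b / T + c rho / T + d ln(P[bar])",
        lambda e: (_col(_ones(e), 1.0 / e.T, e.rho / e.T, np.log(e.P_bar)), 0.0))

_linear("keshmiri", "Keshmiri et al.", "I", "lny2", "abcde", {"T", "P", "rho"},
        "ln y2 = a + b / T + c P[bar]^2 + (d + e / T) ln(rho)",
        lambda e: (_col(_ones(e), 1.0 / e.T, e.P_bar ** 2, np.log(e.rho),
                        np.log(e.rho) / e.T), 0.0))

_linear("khansary", "Khansary et al.", "I", "lny2", "abcde", {"T", "P", "rho"},
        "ln y2 = a / T + b P[MPa] + c P[MPa]^2 / T + (d + e P[MPa]) ln(rho)",
        lambda e: (_col(1.0 / e.T, e.P_mpa, e.P_mpa ** 2 / e.T, np.log(e.rho),
                        e.P_mpa * np.log(e.rho)), 0.0))

_linear("jouyban", "Jouyban et al.", "I", "lny2", "abcdef", {"T", "P", "rho"},
        "ln y2 = a + b P[MPa] + c P[MPa]^2 + d P[MPa] T + e T / P[MPa] + f ln(rho)",
        lambda e: (_col(_ones(e), e.P_mpa, e.P_mpa ** 2, e.P_mpa * e.T,
                        e.T / e.P_mpa, np.log(e.rho)), 0.0))

_linear("sodeifian", "Sodeifian et al.", "I", "lny2", "abcdef", {"T", "P", "rho"},
        "ln y2 = a + b P[MPa]^2 / T + c ln(rho T) + d rho ln(rho) + e P[MPa] ln(T) + f rho / T",
        lambda e: (_col(_ones(e), e.P_mpa ** 2 / e.T, np.log(e.rho * e.T),
                        e.rho * np.log(e.rho), e.P_mpa * np.log(e.T), e.rho / e.T), 0.0))

# --------------------------------------------------------------------------
# Group II: f(rho, T)
# --------------------------------------------------------------------------

_linear("kumar_johnston", "Kumar-Johnston", "II", "lny2", "abc", {"T", "rho"},
        "ln y2 = a + b rho + c / T",
        lambda e: (_col(_ones(e), e.rho, 1.0 / e.T), 0.0))

_linear("alwi_garlapati", "Alwi-Garlapati", "II", "lny2", "abc", {"T", "rho"},
        "y2 = (1 / (rho_r T_r)) exp(a + b / T_r + c rho_r)",
        lambda e: (_col(_ones(e), 1.0 / e.T_r, e.rho_r), -np.log(e.rho_r * e.T_r)))

_linear("chrastil", "Chrastil", "II", "lnS", "abc", {"T", "rho"},
        "ln S = a + b ln(rho) + c / T",
        lambda e: (_col(_ones(e), np.log(e.rho), 1.0 / e.T), 0.0))


def _andonova_to_linear(p):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.array([np.log(p[0]), p[1], p[2]])


def _andonova_from_linear(q):
    return np.array([np.exp(q[0]), q[1], q[2]])


_linear("andonova_garlapati", "Andonova-Garlapati", "II", "lny2", "abc", {"T", "rho"},
        "y2 = a rho_r^b T_r^c",
        lambda e: (_col(_ones(e), np.log(e.rho_r), np.log(e.T_r)), 0.0),
        bounds=((1e-30, 1e6), (-1e6, 1e6), (-1e6, 1e6)),
        to_linear=_andonova_to_linear, from_linear=_andonova_from_linear)

_linear("sung_shim", "Sung-Shim", "II", "lny2", "abcd", {"T", "rho"},
        "ln y2 = (a + b / T) ln(rho) + c / T + d",
        lambda e: (_col(np.log(e.rho), np.log(e.rho) / e.T, 1.0 / e.T, _ones(e)), 0.0))

_linear("garlapati_madras", "Garlapati-Madras", "II", "lny2", "abcde", {"T", "rho"},
        "ln y2 = a + (b + c rho) ln(rho) + d / T + e ln(rho T)",
        lambda e: (_col(_ones(e), np.log(e.rho), e.rho * np.log(e.rho), 1.0 / e.T,
                        np.log(e.rho * e.T)), 0.0))

_linear("del_valle_aguilera", "Del Valle-Aguilera", "II", "lny2", "abcd", {"T", "rho"},
        "ln y2 = a + b / T + c / T^2 + d ln(rho)",
        lambda e: (_col(_ones(e), 1.0 / e.T, 1.0 / e.T ** 2, np.log(e.rho)), 0.0))

_linear("bian", "Bian et al.", "II", "lny2", "abcde", {"T", "rho"},
        "ln y2 = a + b / T + c rho / T + (d + e rho) ln(rho)",
        lambda e: (_col(_ones(e), 1.0 / e.T, e.rho / e.T, np.log(e.rho),
                        e.rho * np.log(e.rho)), 0.0))

_linear("adachi_lu", "Adachi-Lu", "II", "lny2", "abcde", {"T", "rho"},
        "ln y2 = a + (b + c rho + d rho^2) ln(rho) + e / T",
        lambda e: (_col(_ones(e), np.log(e.rho), e.rho * np.log(e.rho),
                        e.rho ** 2 * np.log(e.rho), 1.0 / e.T), 0.0))

_linear("sparks", "Sparks et al.", "II", "lnS", "abcdef", {"T", "rho"},
        "S = rho_r^(a + b rho_r + c ln T_r) exp(d + e / T_r + f / T_r^2)",
        lambda e: (_col(np.log(e.rho_r), e.rho_r * np.log(e.rho_r),
                        np.log(e.T_r) * np.log(e.rho_r), _ones(e), 1.0 / e.T_r,
                        1.0 / e.T_r ** 2), 0.0))

_linear("si_moussa", "Si-Moussa et al.", "II", "lny2", "abcdef", {"T", "rho"},
        "ln y2 = a + b rho + c rho^2 + d rho / T + e T / rho + f ln(rho)",
        lambda e: (_col(_ones(e), e.rho, e.rho ** 2, e.rho / e.T, e.T / e.rho,
                        np.log(e.rho)), 0.0))

_linear("belghait", "Belghait et al.", "II", "lny2", "abcdefgh", {"T", "rho"},
        "ln y2 = a + b rho + c rho^2 + d rho / T + e / T + f / T^2 + g ln(rho) + h T",
        lambda e: (_col(_ones(e), e.rho, e.rho ** 2, e.rho / e.T, 1.0 / e.T,
                        1.0 / e.T ** 2, np.log(e.rho), e.T), 0.0))

# --------------------------------------------------------------------------
# Group III: f(P, T)
# --------------------------------------------------------------------------

_linear("reddy", "Reddy et al.", "III", "lny2", "abcde", {"T", "P"},
        "ln y2 = (a + b P_r) T_r^2 + (c + d P_r) T_r + e",
        lambda e: (_col(e.T_r ** 2, e.P_r * e.T_r ** 2, e.T_r, e.P_r * e.T_r,
                        _ones(e)), 0.0))


# The fourth term is read as d*P rather than an exponential d**P: fitted
# d is negative on the reference dataset (an impossible base for d**P)
# and the d*P reading reproduces the published parameter magnitudes.
_linear("mitra_wilson", "Mitra-Wilson", "III", "lnS", "abcde", {"T", "P"},
        "ln S = a ln(P[bar]) + b T + c P[bar] T + d P[bar] + e",
        lambda e: (_col(np.log(e.P_bar), e.T, e.P_bar * e.T, e.P_bar, _ones(e)), 0.0))

_linear("reddy_garlapati", "Reddy-Garlapati", "III", "y2", "abcdef", {"T", "P"},
        "y2 = (a + b P_r + c P_r^2) T_r + (d + e P_r + f P_r^2)",
        lambda e: (_col(e.T_r, e.P_r * e.T_r, e.P_r ** 2 * e.T_r, _ones(e), e.P_r,
                        e.P_r ** 2), 0.0))

_linear("gordillo", "Gordillo et al.", "III", "lny2", "abcdef", {"T", "P"},
        "ln y2 = a + b P[MPa] + c P[MPa]^2 + d P[MPa] T + e T + f T^2",
        lambda e: (_col(_ones(e), e.P_mpa, e.P_mpa ** 2, e.P_mpa * e.T, e.T,
                        e.T ** 2), 0.0))


def _yu_native(params, env: ModelEnv):
    a, b, c, d, e, f = params
    P, T = env.P_bar, env.T
    rhs = a + b * P + c * P ** 2 + d * P * T + e * T + f * T ** 2
    return rhs / (1.0 + d * P * T)


def _yu_design(env: ModelEnv):
    if env.y2_obs is None:
        raise ValueError("Yu initializer design needs observed mole fractions")
    P, T = env.P_bar, env.T
    return (_col(np.ones_like(T), P, P ** 2, P * T * (1.0 - env.y2_obs), T, T ** 2), 0.0)


_register(ModelSpec(
    key="yu", name="Yu et al.", group="III", family="density",
    formula="y2 (1 + d P[bar] T) = a + b P + c P^2 + d P T + e T + f T^2  (closed-form solve)",
    space="y2", param_names=("a", "b", "c", "d", "e", "f"),
    depends_on=frozenset({"T", "P"}), linear_in_params=True,
    design=_yu_design, native_fn=_yu_native))


def density_models() -> tuple[ModelSpec, ...]:
    """All 25 density-based specs, registry order (Group I, II, III)."""
    return tuple(_SPECS)
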