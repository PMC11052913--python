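"""Enthalpy extraction and data diagnostics (self-consistency, crossover).

The 1/T coefficient of the density-based correlations carries an
enthalpy: for Chrastil and Kumar-Johnston it is the *total* enthalpy of
the dissolution process (vaporization plus solvation),
``dH_tot = -c * R``; for Bartle, whose density term is referenced to
700 kg/m^3, it approximates the vaporization enthalpy alone,
``dH_vap = -c * R``. The solvation enthalpy follows by difference,
``dH_sol = mean(dH_tot) - dH_vap`` - negative (exothermic) for a
solvent-solute complexing system; the report stores the signed value and
exposes the magnitude, which is how such tables usually print it.

The self-consistency test plots all isotherms in a model's linearizing
coordinates (e.g. ``T ln(y2 P)`` minus the fitted temperature term
against density): self-consistent data collapse onto one straight line
across every isotherm. The crossover diagnostic finds the pressure range
where solubility isotherms intersect - below it the density effect of
temperature dominates, above it the solute vapor pressure does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import R_GAS, SolubilityDataset, ValidationError
from .fitting import FitResult, deterministic_fit, r_squared
from .models import get_model, make_env
from .models.base import ModelEnv, P_REF_MPA, RHO_REF, y2_to_native

#: Models whose 1/T coefficient is an enthalpy and whose native space
#: linearizes: symbol of the 1/T (or T) coefficient per model key.
_LINEARIZING_MODELS = ("chrastil", "kumar_johnston", "bartle", "mendez_teja")


@dataclass(frozen=True)
class EnthalpyReport:
    """Total, vaporization and solvation enthalpies, kJ/mol.

    ``dh_sol`` is signed (negative = exothermic solvation); use
    ``dh_sol_magnitude`` for the conventionally printed positive value.
    """

    dh_tot_chrastil: float
    dh_tot_kumar_johnston: float
    dh_vap: float
    dh_sol: float
    gas_constant: float = R_GAS

    @property
    def dh_tot_mean(self) -> float:
        return 0.5 * (self.dh_tot_chrastil + self.dh_tot_kumar_johnston)

    @property
    def dh_sol_magnitude(self) -> float:
        return abs(self.dh_sol)


def enthalpy_from_coefficient(c_over_T: float) -> float:
    """dH (kJ/mol) from a fitted 1/T coefficient: dH = -c * R / 1000."""
    return -c_over_T * R_GAS / 1000.0


def enthalpies_from_fits(chrastil: FitResult, kumar_johnston: FitResult,
                         bartle: FitResult) -> EnthalpyReport:
    """Assemble the enthalpy report from three fitted models."""
    def c_of(result: FitResult, key: str) -> float:
        spec = get_model(key)
        if result.model != key:
            raise ValidationError(f"enthalpies_from_fits: expected a {key!r} fit, "
                                  f"got {result.model!r}")
        return result.coefficient("c", spec)

    dh_chr = enthalpy_from_coefficient(c_of(chrastil, "chrastil"))
    dh_kj = enthalpy_from_coefficient(c_of(kumar_johnston, "kumar_johnston"))
    dh_vap = enthalpy_from_coefficient(c_of(bartle, "bartle"))
    return EnthalpyReport(dh_tot_chrastil=dh_chr, dh_tot_kumar_johnston=dh_kj,
                          dh_vap=dh_vap, dh_sol=0.5 * (dh_chr + dh_kj) - dh_vap)


def enthalpies(dataset: SolubilityDataset) -> EnthalpyReport:
    """Fit Chrastil, Kumar-Johnston and Bartle and extract enthalpies.

    Uses the deterministic single-start fit (exact linear solution refined
    against the AARD objective in mole-fraction space), so repeated calls
    are bit-identical.
    """
    return enthalpies_from_fits(
        deterministic_fit(get_model("chrastil"), dataset),
        deterministic_fit(get_model("kumar_johnston"), dataset),
        deterministic_fit(get_model("bartle"), dataset))


# ---------------------------------------------------------------------------
# Self-consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelfConsistencyResult:
    """Pooled-line collapse diagnostic in a model's linearizing coordinates."""

    model: str
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    r2: float
    residuals: np.ndarray


def _linearizing_coordinates(model: str, env: ModelEnv, c: float):
    """(x, y) such that self-consistent data satisfy y ~ a + slope * x."""
    if model == "chrastil":
        return np.log(env.rho), y2_to_native("lnS", env) - c / env.T
    if model == "kumar_johnston":
        return env.rho, y2_to_native("lny2", env) - c / env.T
    if model == "bartle":
        return env.rho - RHO_REF, y2_to_native("lny2P_ratio", env) - c / env.T
    if model == "mendez_teja":
        return env.rho, y2_to_native("Tlny2P", env) - c * env.T
    raise ValidationError(f"self_consistency: unsupported model {model!r}; "
                          f"choose one of {_LINEARIZING_MODELS}")


def self_consistency(dataset: SolubilityDataset, model: str,
                     fit_result: FitResult | None = None) -> SelfConsistencyResult:
    """Collapse all isotherms onto one line after removing the fitted T term.

    Requires at least two isotherms. Returns the pooled OLS line, its R2
    and the per-point residuals; an R2 near 1 means the dataset is
    self-consistent under the chosen correlation.
    """
    if len(dataset.temperatures) < 2:
        raise ValidationError("self_consistency: diagnostic needs >= 2 isotherms")
    if model not in _LINEARIZING_MODELS:
        # raise with the supported list
        _linearizing_coordinates(model, make_env(dataset), 0.0)
    result = fit_result or deterministic_fit(get_model(model), dataset)
    c = result.coefficient("c", get_model(model))
    env = make_env(dataset)
    x, y = _linearizing_coordinates(model, env, c)
    X = np.column_stack([np.ones_like(x), x])
    (intercept, slope), *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = intercept + slope * x
    return SelfConsistencyResult(model=model, x=x, y=y, slope=float(slope),
                                 intercept=float(intercept),
                                 r2=r_squared(y, fitted), residuals=y - fitted)


# ---------------------------------------------------------------------------
# Crossover pressure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossoverResult:
    """Isotherm-pair intersection pressures and their envelope (bar)."""

    intersections: tuple[tuple[float, float, float], ...]  # (T_i, T_j, P_bar)
    band: tuple[float, float] | None
    degenerate_pairs: tuple[tuple[float, float], ...]
    skipped_pairs: tuple[tuple[float, float], ...]


def crossover(dataset: SolubilityDataset, n_grid: int = 2001) -> CrossoverResult:
    """Locate pairwise isotherm intersections of ln(y2) vs P.

    Each isotherm is interpolated piecewise-linearly in (P, ln y2) - no
    splines, which would invite spurious crossings on short isotherms.
    Pairs with non-overlapping pressure ranges are skipped; pairs that
    coincide everywhere are reported as degenerate. The band is the
    (min, max) envelope of all intersection pressures.
    """
    isotherms = dataset.isotherms()
    temps = sorted(isotherms)
    if len(temps) < 2:
        raise ValidationError("crossover: need >= 2 isotherms")
    curves = {}
    for T in temps:
        recs = sorted(isotherms[T], key=lambda r: r.P)
        if len(recs) < 3:
            raise ValidationError(f"crossover: isotherm {T} K has fewer than 3 points")
        curves[T] = (np.array([r.P for r in recs]), np.log([r.y2 for r in recs]))

    intersections: list[tuple[float, float, float]] = []
    degenerate: list[tuple[float, float]] = []
    skipped: list[tuple[float, float]] = []
    for i, Ti in enumerate(temps):
        for Tj in temps[i + 1:]:
            Pi, yi = curves[Ti]
            Pj, yj = curves[Tj]
            lo, hi = max(Pi.min(), Pj.min()), min(Pi.max(), Pj.max())
            if lo >= hi:
                skipped.append((Ti, Tj))
                continue
            grid = np.linspace(lo, hi, n_grid)
            diff = np.interp(grid, Pi, yi) - np.interp(grid, Pj, yj)
            if np.allclose(diff, 0.0, atol=1e-12):
                degenerate.append((Ti, Tj))
                continue
            sign = np.sign(diff)
            for k in np.nonzero(np.diff(sign) != 0)[0]:
                x0, x1, f0, f1 = grid[k], grid[k + 1], diff[k], diff[k + 1]
                p_cross = x0 if f0 == f1 else x0 - f0 * (x1 - x0) / (f1 - f0)
                intersections.append((Ti, Tj, float(p_cross)))
    band = None
    if intersections:
        pressures = [p for *_, p in intersections]
        band = (min(pressures), max(pressures))
    return CrossoverResult(intersections=tuple(intersections), band=band,
                           degenerate_pairs=tuple(degenerate),
                           skipped_pairs=tuple(skipped))
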