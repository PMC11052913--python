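"""Synthetic solubility datasets with the structure the analysis assumes.

A simulated dataset mirrors the design of an isothermal solubility
campaign: a temperature-by-pressure grid, a monotone solvent-density
surface rho(T, P), mole fractions generated from any registered
correlation, and multiplicative lognormal measurement noise
``y2 = model(T, P, rho) * exp(eps)`` with ``eps ~ N(0, sigma^2)`` -
multiplicative because replicate scatter in such measurements is roughly
constant in relative terms, and lognormal so positivity is preserved.

Densities come from bilinear interpolation of the bundled experimental
rho(T, P) table (or a user-supplied one); extrapolation outside the
table is refused rather than guessed, which avoids smuggling in an
equation of state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .data import (CO2, REGORAFENIB, SolubilityDataset, SolubilityRecord,
                   SoluteInfo, SolventInfo, ValidationError, reg_dataset)
from .fitting import FitConfig, fit
from .models import get_model
from .models.base import env_from_arrays


class GenerationError(RuntimeError):
    """The generating model is non-finite at a grid point."""


def density_interpolator(table: pd.DataFrame | None = None):
    """Bilinear rho(T, P) from a gridded table; refuses extrapolation.

    ``table`` needs columns T_K, P_bar, rho_kg_m3 forming a complete
    rectangular grid; defaults to the bundled experimental table, whose
    24 nodes are reproduced exactly.
    """
    if table is None:
        table = reg_dataset().to_frame()[["T_K", "P_bar", "rho_kg_m3"]]
    pivot = table.pivot(index="T_K", columns="P_bar", values="rho_kg_m3")
    if pivot.isna().any().any():
        raise ValidationError("density_interpolator: table is not a complete T x P grid")
    interp = RegularGridInterpolator(
        (pivot.index.to_numpy(float), pivot.columns.to_numpy(float)),
        pivot.to_numpy(float), method="linear", bounds_error=True)

    def rho(T, P):
        t, p = np.broadcast_arrays(np.asarray(T, float), np.asarray(P, float))
        out = interp(np.column_stack([np.atleast_1d(t).ravel(), np.atleast_1d(p).ravel()]))
        if np.ndim(T) == 0 and np.ndim(P) == 0:
            return float(out[0])
        return out.reshape(t.shape)

    return rho


@dataclass(frozen=True)
class SimulationConfig:
    """Generating model, truth, grid, noise level and seed.

    Defaults mirror the experimental design: 4 temperatures x 6 pressures
    with 5 % relative noise, the scatter level seen in replicate
    measurements.
    """

    model: str = "chrastil"
    params: tuple[float, ...] = ()
    temperatures: tuple[float, ...] = (308.0, 318.0, 328.0, 338.0)
    pressures: tuple[float, ...] = (120.0, 150.0, 180.0, 210.0, 240.0, 270.0)
    sigma: float = 0.05
    seed: int = 0
    density_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("SimulationConfig: sigma must be >= 0")
        if not self.temperatures or not self.pressures:
            raise ValidationError("SimulationConfig: grid must be non-empty")


def simulate(config: SimulationConfig, solute: SoluteInfo = REGORAFENIB,
             solvent: SolventInfo = CO2) -> SolubilityDataset:
    """Generate a dataset from a registered model on a T x P grid.

    Seed-reproducible; records carry the exact density used for
    generation.
    """
    spec = get_model(config.model)
    rho_of = density_interpolator(config.density_table)
    rng = np.random.default_rng(config.seed)
    T_grid, P_grid = [], []
    for T in config.temperatures:
        for P in config.pressures:
            T_grid.append(T)
            P_grid.append(P)
    T_arr = np.array(T_grid, float)
    P_arr = np.array(P_grid, float)
    rho_arr = np.array([rho_of(t, p) for t, p in zip(T_arr, P_arr)], float)
    env = env_from_arrays(T_arr, P_arr, rho_arr, solvent, solute)
    try:
        y_clean = spec.predict_y2(np.asarray(config.params, float), env)
    except ArithmeticError as exc:
        raise GenerationError(f"simulate: {exc}") from exc
    if np.any(~np.isfinite(y_clean)) or np.any(y_clean <= 0) or np.any(y_clean >= 1):
        bad = int(np.argmax(~((y_clean > 0) & (y_clean < 1) & np.isfinite(y_clean))))
        raise GenerationError(
            f"simulate: model {config.model!r} gives unusable mole fraction "
            f"{y_clean[bad]!r} at T={T_arr[bad]} K, P={P_arr[bad]} bar")
    noise = np.exp(config.sigma * rng.standard_normal(y_clean.size)) if config.sigma else 1.0
    y_noisy = y_clean * noise
    records = tuple(
        SolubilityRecord(T=t, P=p, rho=r, y2=y)
        for t, p, r, y in zip(T_arr, P_arr, rho_arr, y_noisy))
    return SolubilityDataset(records=records, solute=solute, solvent=solvent)


@dataclass(frozen=True)
class RecoveryResult:
    """Per-parameter bias/RMSE across replicates plus the AARD distribution."""

    model: str
    n_replicates: int
    table: pd.DataFrame          # param, truth, rel_bias, rel_rmse, median_abs_rel_error
    aard: np.ndarray
    failures: tuple[int, ...]


def recovery_study(config: SimulationConfig, n_replicates: int,
                   fit_config: FitConfig | None = None) -> RecoveryResult:
    """Simulate-fit loop quantifying parameter identifiability.

    Replicate r uses seed ``config.seed + r``. Failed fits are recorded,
    not fatal. Relative errors are with respect to the generating truth.
    """
    if n_replicates < 1:
        raise ValidationError("recovery_study: n_replicates must be >= 1")
    spec = get_model(config.model)
    truth = np.asarray(config.params, float)
    fit_config = fit_config or FitConfig(n_starts=1)
    estimates, aards, failures = [], [], []
    for r in range(n_replicates):
        ds = simulate(SimulationConfig(
            model=config.model, params=config.params,
            temperatures=config.temperatures, pressures=config.pressures,
            sigma=config.sigma, seed=config.seed + r,
            density_table=config.density_table))
        try:
            res = fit(spec, ds, fit_config)
        except Exception:  # noqa: BLE001 - recorded, not fatal
            failures.append(r)
            continue
        estimates.append(res.params)
        aards.append(res.aard)
    est = np.array(estimates, float)
    rows = []
    for j, (sym, true_val) in enumerate(zip(spec.param_names, truth)):
        rel = (est[:, j] - true_val) / true_val if len(est) else np.array([])
        rows.append({"param": sym, "truth": true_val,
                     "rel_bias": float(np.mean(rel)) if rel.size else np.nan,
                     "rel_rmse": float(np.sqrt(np.mean(rel ** 2))) if rel.size else np.nan,
                     "median_abs_rel_error": float(np.median(np.abs(rel))) if rel.size else np.nan})
    return RecoveryResult(model=config.model, n_replicates=n_replicates,
                          table=pd.DataFrame(rows), aard=np.array(aards, float),
                          failures=tuple(failures))
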