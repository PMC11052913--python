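"""Solubility data model, I/O, and sampling-to-solubility conversions.

Equilibrium solubility of a solid drug in supercritical CO2 is measured by
flushing a saturated sampling loop into a collection vial and assaying the
collected solute. The measured vial concentration converts to a mole
fraction ``y2`` through the mole balance of the loop, and mole fraction
converts to a volumetric solubility ``S`` (g solute per litre of solvent)
through the solvent density.

Canonical storage units: temperature in K, pressure in bar, density in
kg/m^3 (numerically equal to g/L), ``y2`` dimensionless, ``S`` in g/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

DATASET_COLUMNS = ("T_K", "P_bar", "rho_kg_m3", "y2")
OPTIONAL_COLUMNS = ("S_gL", "sd", "U")


class ValidationError(ValueError):
    """An invariant of the data model is violated."""


class ParseError(ValueError):
    """A delimited input file cannot be interpreted."""


def _require_positive(obj: str, **fields: float) -> None:
    for name, value in fields.items():
        if value is None or not math.isfinite(value) or value <= 0:
            raise ValidationError(f"{obj}: field '{name}' must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class SolventInfo:
    """Supercritical solvent: molar mass and critical constants.

    ``p_crit`` is in MPa, ``rho_crit`` in kg/m^3, ``t_crit`` in K.
    """

    molar_mass: float
    t_crit: float
    p_crit: float
    rho_crit: float

    def __post_init__(self) -> None:
        _require_positive("SolventInfo", molar_mass=self.molar_mass, t_crit=self.t_crit,
                          p_crit=self.p_crit, rho_crit=self.rho_crit)


@dataclass(frozen=True)
class SoluteInfo:
    """Solid solute: name, molar mass (g/mol), optional UV peak (nm)."""

    name: str
    molar_mass: float
    lambda_max: float | None = None

    def __post_init__(self) -> None:
        _require_positive("SoluteInfo", molar_mass=self.molar_mass)


#: Carbon dioxide: M = 44.01 g/mol, Tc = 304.12 K, Pc = 7.39 MPa, rho_c = 467.6 kg/m^3.
CO2 = SolventInfo(molar_mass=44.01, t_crit=304.12, p_crit=7.39, rho_crit=467.6)

#: Regorafenib monohydrate, M = 500.83 g/mol, UV assay at 275 nm.
REGORAFENIB = SoluteInfo(name="regorafenib monohydrate", molar_mass=500.83, lambda_max=275.0)


@dataclass(frozen=True)
class SolubilityRecord:
    """One isothermal-isobaric equilibrium measurement.

    T in K, P in bar, rho (solvent density) in kg/m^3, y2 the solute mole
    fraction in the supercritical phase. ``S`` (g/L), the standard
    deviation ``sd`` of y2 and the expanded uncertainty ``U`` of y2 are
    optional as in published tables.
    """

    T: float
    P: float
    rho: float
    y2: float
    S: float | None = None
    sd: float | None = None
    U: float | None = None

    def __post_init__(self) -> None:
        _require_positive("SolubilityRecord", T=self.T, P=self.P, rho=self.rho)
        if not (0.0 < self.y2 < 1.0):
            raise ValidationError(
                f"SolubilityRecord: field 'y2' must be a mole fraction in (0, 1), got {self.y2!r}")
        if self.S is not None and self.S <= 0:
            raise ValidationError(f"SolubilityRecord: field 'S' must be positive, got {self.S!r}")


@dataclass(frozen=True)
class SamplingSetup:
    """Sampling-loop geometry and assay result.

    loop_volume (L) holds saturated solvent; collection_volume (L) is the
    vial the loop is flushed into; concentration (g/L) is the assayed
    solute concentration in the vial.
    """

    loop_volume: float
    collection_volume: float
    concentration: float

    def __post_init__(self) -> None:
        _require_positive("SamplingSetup", loop_volume=self.loop_volume,
                          collection_volume=self.collection_volume)
        if self.concentration < 0:
            raise ValidationError(
                f"SamplingSetup: field 'concentration' must be >= 0, got {self.concentration!r}")


@dataclass(frozen=True)
class SolubilityDataset:
    """An ordered collection of records plus solute/solvent metadata.

    (T, P) pairs are unique; records group into isotherms by exact
    temperature equality.
    """

    records: tuple[SolubilityRecord, ...]
    solute: SoluteInfo
    solvent: SolventInfo

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError("SolubilityDataset: at least one record required")
        seen = set()
        for rec in self.records:
            key = (rec.T, rec.P)
            if key in seen:
                raise ValidationError(f"SolubilityDataset: duplicate (T, P) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> tuple[float, ...]:
        out: list[float] = []
        for rec in self.records:
            if rec.T not in out:
                out.append(rec.T)
        return tuple(out)

    def isotherms(self) -> dict[float, tuple[SolubilityRecord, ...]]:
        groups: dict[float, list[SolubilityRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.T, []).append(rec)
        return {T: tuple(v) for T, v in groups.items()}

    def arrays(self) -> dict[str, np.ndarray]:
        """Column arrays in storage units (row order preserved)."""
        return {
            "T": np.array([r.T for r in self.records], float),
            "P": np.array([r.P for r in self.records], float),
            "rho": np.array([r.rho for r in self.records], float),
            "y2": np.array([r.y2 for r in self.records], float),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({"T_K": r.T, "P_bar": r.P, "rho_kg_m3": r.rho, "y2": r.y2,
                         "S_gL": r.S, "sd": r.sd, "U": r.U})
        df = pd.DataFrame(rows)
        if df[list(OPTIONAL_COLUMNS)].isna().all().all():
            df = df.drop(columns=list(OPTIONAL_COLUMNS))
        return df

    def subset(self, temperature: float) -> "SolubilityDataset":
        recs = tuple(r for r in self.records if r.T == temperature)
        return replace(self, records=recs)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def mole_fraction_from_sampling(setup: SamplingSetup, rho: float,
                                m_solvent: float, m_solute: float) -> float:
    """Mole fraction of solute from a loop-sampling measurement.

    n_solute = C * V_vial / M_solute, n_solvent = V_loop * rho / M_solvent
    (rho in g/L, numerically kg/m^3), and y2 = n_solute / (n_solvent + n_solute).
    """
    if rho <= 0 or setup.loop_volume <= 0:
        raise ValidationError("mole_fraction_from_sampling: density and loop volume must be positive")
    _require_positive("mole_fraction_from_sampling", m_solvent=m_solvent, m_solute=m_solute)
    n_solute = setup.concentration * setup.collection_volume / m_solute
    n_solvent = setup.loop_volume * rho / m_solvent
    return n_solute / (n_solvent + n_solute)


def solubility_gL_from_y2(rho, y2, m_solvent: float, m_solute: float):
    """Volumetric solubility S (g/L) from mole fraction.

    S = rho * (M_solute / M_solvent) * y2 / (1 - y2), rho in kg/m^3 == g/L.
    Accepts scalars or arrays.
    """
    y2 = np.asarray(y2, float) if np.ndim(y2) else float(y2)
    if np.any(np.asarray(y2) >= 1.0) or np.any(np.asarray(y2) < 0.0):
        raise ValidationError("solubility_gL_from_y2: y2 must lie in [0, 1)")
    return rho * (m_solute / m_solvent) * y2 / (1.0 - y2)


def y2_from_solubility_gL(rho, S, m_solvent: float, m_solute: float):
    """Inverse of :func:`solubility_gL_from_y2` (exact round trip)."""
    r = np.asarray(S, float) * m_solvent / (np.asarray(rho, float) * m_solute)
    out = r / (1.0 + r)
    return float(out) if np.ndim(out) == 0 else out


def expanded_uncertainty(sensitivities: Sequence[tuple[float, float]],
                         y: float, k: float = 2.0) -> float:
    """Expanded uncertainty U of a derived quantity y.

    ``sensitivities`` is a list of (P_i, u(x_i)/x_i) pairs of sensitivity
    coefficient and relative standard uncertainty. The combined relative
    uncertainty is the quadrature sum sqrt(sum (P_i u_i)^2) and
    U = k * u_combined * y. Coverage factor k = 2 corresponds to ~95 %
    confidence.
    """
    if len(sensitivities) == 0:
        raise ValidationError("expanded_uncertainty: empty sensitivity list")
    if k <= 0:
        raise ValidationError("expanded_uncertainty: coverage factor must be positive")
    total = 0.0
    for p, u in sensitivities:
        if u < 0:
            raise ValidationError("expanded_uncertainty: relative uncertainties must be >= 0")
        total += (p * u) ** 2
    return k * math.sqrt(total) * y


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(path, solute: SoluteInfo, solvent: SolventInfo) -> SolubilityDataset:
    """Read a comma-separated solubility table.

    Required header columns: T_K, P_bar, rho_kg_m3, y2. Optional: S_gL,
    sd, U. Row order is preserved; every row is validated against the
    record invariants and errors name the offending line or field.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as a parse error
        raise ParseError(f"load_dataset: cannot parse {path!r}: {exc}") from exc
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"load_dataset: missing required columns {missing} in {path!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        kwargs = {}
        for col, attr in (("S_gL", "S"), ("sd", "sd"), ("U", "U")):
            if col in df.columns:
                val = getattr(row, col)
                kwargs[attr] = None if pd.isna(val) else float(val)
        try:
            records.append(SolubilityRecord(T=float(row.T_K), P=float(row.P_bar),
                                            rho=float(row.rho_kg_m3), y2=float(row.y2), **kwargs))
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise ValidationError(f"line {i}: {exc}") from exc
            raise ParseError(f"load_dataset: malformed row at line {i}: {exc}") from exc
    return SolubilityDataset(records=tuple(records), solute=solute, solvent=solvent)


def save_dataset(dataset: SolubilityDataset, path) -> None:
    """Write the CSV dialect read by :func:`load_dataset` (round-trip safe)."""
    dataset.to_frame().to_csv(path, index=False)


def reg_dataset() -> SolubilityDataset:
    """The bundled regorafenib-monohydrate / ScCO2 equilibrium table.

    24 records on a 4-temperature (308-338 K) by 6-pressure (120-270 bar)
    grid, with NIST CO2 densities, measured mole fractions, their standard
    deviations and expanded uncertainties (k = 2), and the published g/L
    solubility column (informational; see :func:`recomputed_solubility`).
    """
    ref = resources.files("scfsolub.fixtures").joinpath("reg_scco2.csv")
    with resources.as_file(ref) as path:
        return load_dataset(path, solute=REGORAFENIB, solvent=CO2)


def recomputed_solubility(dataset: SolubilityDataset) -> pd.DataFrame:
    """Recompute S (g/L) from y2 and compare with the stored column.

    The bundled table's S column is internally inconsistent with the
    monohydrate molar mass at the printed y2 precision; the recomputed
    value is the authoritative one and the relative gap is reported per
    record rather than silently reconciled.
    """
    rows = []
    for r in dataset.records:
        s_calc = solubility_gL_from_y2(r.rho, r.y2, dataset.solvent.molar_mass,
                                       dataset.solute.molar_mass)
        gap = None if r.S is None else (s_calc - r.S) / r.S
        rows.append({"T_K": r.T, "P_bar": r.P, "S_stored_gL": r.S,
                     "S_recomputed_gL": s_calc, "relative_gap": gap})
    return pd.DataFrame(rows)
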