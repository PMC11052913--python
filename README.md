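# scfsolub

Correlation toolkit for the solubility of solid drugs in supercritical
carbon dioxide (ScCO₂), built around a 24-point equilibrium dataset for
the kinase inhibitor **regorafenib monohydrate** (M = 500.83 g/mol)
measured at 308–338 K and 120–270 bar.

Micronization processes built on supercritical CO₂ (RESS, SAS and
relatives) need the equilibrium mole fraction y₂(T, P) of the drug in the
fluid phase, and process models need a compact correlation of it.
This package implements the standard correlation battery for one
drug–CO₂ binary system:

* **25 density-based semi-empirical models** in three groups —
  f(ρ, T, P) (Méndez-Santiago–Teja, Bartle, Jouyban, …), f(ρ, T)
  (Chrastil `ln S = a + b ln ρ + c/T`, Kumar–Johnston, Adachi–Lu, …) and
  f(P, T) (Gordillo, Reddy, Yu, …);
* **3 association-theory models** derived from solid–liquid-equilibrium
  fugacity balances, of the form
  `y₂ = (P/P*)^(κ−1) exp(⋯)` with standard pressure P* = 0.1 MPa and a
  free association number κ;
* **multistart fitting** minimizing the average absolute relative
  deviation `AARD(%) = (100/N) Σ |y₂ᶜᵃˡ − y₂ᵉˣᵖ| / y₂ᵉˣᵖ` in
  mole-fraction space (exact OLS in each model's native log space as the
  anchor start), with a five-statistic scorecard (AARD, R², adjusted R²,
  SSE, RMSE);
* **thermodynamic diagnostics**: total/vaporization/solvation enthalpies
  from the fitted 1/T coefficients (ΔH = −c·R), the isotherm
  crossover-pressure band, and single-line self-consistency collapses;
* a **synthetic-data generator** reproducing the 4 × 6 (T, P) design with
  multiplicative lognormal noise, for parameter-recovery studies.

## Worked example

```python
from scfsolub import FitConfig, fit, get_model, reg_dataset, enthalpies, crossover

ds = reg_dataset()                      # 24 records, 4 isotherms
best = fit(get_model("gordillo"), ds, FitConfig(n_starts=64, seed=1))
print(best.aard)                        # 13.22  (% AARD, best density-based group)

rep = enthalpies(ds)
print(rep.dh_tot_mean, rep.dh_vap, rep.dh_sol)
# 41.35  60.22  -18.87   (kJ/mol: total, vaporization, solvation)

print(crossover(ds).band)               # (191.2, 199.0)  bar
```

The Gordillo pressure–temperature polynomial correlates the data to
13.2 % AARD — the best of the 25 density-based forms (Reddy's
reduced-variable model is close at 13.3 %). The enthalpy block says
dissolving the drug costs ≈ 41 kJ/mol in total; since vaporizing it alone
would cost ≈ 60 kJ/mol, solvation by CO₂ recovers ≈ 19 kJ/mol
(exothermic). All isotherms cross between 191 and 199 bar: below that
pressure solubility falls with temperature (the density effect wins),
above it it rises (vapor pressure wins).

The numbered scripts under `analysis/` run the full study and write
tables to `results/`:

| script | what it does |
|---|---|
| `01_dataset_overview.py` | table structure, monotonicity, g/L-column audit |
| `02_density_model_battery.py` | all 25 density-based fits + group averages |
| `03_association_models.py` | the 3 association-theory fits |
| `04_thermo_diagnostics.py` | enthalpies, crossover band, self-consistency |
| `05_parameter_recovery.py` | noise study on the experimental design |

A `scfsolub` console script exposes the same steps
(`scfsolub fit --models all`, `scfsolub enthalpy`, `scfsolub crossover`,
`scfsolub simulate`, `scfsolub reproduce`, …).

## Layout

```
src/scfsolub/        library: data model, model registry, fitting, thermo,
                     simulation, reporting, CLI
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property, end-to-end)
docs/methods.md      models, assumptions, numerical choices, limitations
```
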