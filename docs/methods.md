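# Methods

## The data model

One record is an isothermal–isobaric equilibrium point (T [K], P [bar],
ρ [kg/m³], y₂), optionally with a g/L solubility, the replicate standard
deviation of y₂ and its expanded uncertainty (coverage factor k = 2). A
dataset adds the solute (molar mass) and the solvent (molar mass plus
critical constants T_c = 304.12 K, P_c = 7.39 MPa, ρ_c = 467.6 kg/m³ for
CO₂). Densities are *inputs*: they come from the measurement campaign's
reference table, and this package deliberately contains no equation of
state.

Sampling conversions: with a loop of volume V₁ flushed into a vial of
volume V_vial at assayed concentration C, the solute and solvent mole
numbers are n₂ = C·V_vial/M₂ and n₁ = V₁·ρ/M₁ (ρ in g/L ≡ kg/m³), giving
y₂ = n₂/(n₁+n₂). Volumetric solubility is
S = ρ·(M₂/M₁)·y₂/(1−y₂), inverted exactly for the reverse direction.

The bundled regorafenib table's printed g/L column disagrees with its own
y₂ column by 1–6 % when recomputed through the monohydrate molar mass
(`analysis/01` quantifies this; the values are closer to the anhydrous
mass or to unrounded mole fractions). The package stores the printed
column as informational and treats y₂ as the authoritative observable —
`recomputed_solubility` reports the gap rather than guessing the intent.
Likewise the table's smallest entry is kept as printed (3.1 × 10⁻⁷) even
where the source abstract quotes an unrounded 3.06 × 10⁻⁷.

Uncertainty propagation takes user-supplied sensitivity coefficients
(P_i, u(x_i)/x_i) and forms U = k·y·√Σ(P_i·u_i)²; the sensitivities are
not derived symbolically because the measurement chain (absorbance →
concentration → mole balance) is not part of this package.

## The model catalogue

Every correlation is a `ModelSpec`: a native prediction space (ln y₂,
y₂, ln S, S, T·ln(y₂P) or ln(y₂P/P_ref)), an ordered parameter vector,
the set of physical state variables it depends on, and — for the 27 of
28 forms that are linear in their parameters after the native transform —
an exact OLS design. The `formula` string on each spec is the
authoritative statement of the implemented form.

Journal rendering of stacked fractions is unreliable, so each equation
was restored to a canonical reading and, where possible, validated by
back-substituting the source study's printed parameter values into the
candidate form and checking that it reproduces ln y₂ at spot state
points. That procedure fixed, in particular:

* **Reddy et al.** as `ln y₂ = (a + b·P_r)·T_r² + (c + d·P_r)·T_r + e`
  (the printed "T²" must be T_r², and the left side is the logarithm:
  the printed parameters then reproduce ln y₂ to ≈ 0.02 at the extreme
  state points, while the non-log reading gives physically impossible
  values);
* per-model pressure units (MPa for Gordillo, Jouyban, Khansary,
  Sodeifian, Bartle and the association models; bar elsewhere);
* **Mitra–Wilson** as `ln S = a·lnP + b·T + c·P·T + d·P + e`. The
  exponential reading d^P is untenable: published fits report negative
  d, and on the reference data d^P plateaus at ≈ 30 % AARD while the
  linear reading reaches 14 % with coefficient magnitudes matching the
  published row.
* **Sparks et al.** as
  `S = ρ_r^(a + b·ρ_r + c·ln T_r) · exp(d + e/T_r + f/T_r²)`, the
  canonical reduced-variable form nearest the garbled rendering.

The **Yu et al.** equation is implicit in y₂; it is solved by the exact
algebraic rearrangement `y₂ = (a + bP + cP² + dPT + eT + fT²)/(1 + dPT)`.
Its OLS initializer uses the published form with the *observed* y₂ in the
`d·PT(1−y₂)` column — observed values are allowed in initializers but
never in predictions.

The three association models share the structure
`y₂ = (P/P*)^(κ−1)·exp(linear terms)` with P* = 0.1 MPa, P in MPa and
density in mol/mL (or reduced). All molecular quantities of the
underlying fugacity derivation (sublimation pressure, solvation
enthalpy, fugacity coefficients, molar volume) are lumped into the
fitted constants, exactly as the working equations absorb them; no
standalone types exist for them. κ is a continuous free parameter
bounded to [−10, 10] because published fits include non-integer and
negative values — it is a shape parameter here, not a stoichiometry.
Setting the pressure coefficient of the extended model to zero recovers
the four-parameter form exactly (a nesting identity the tests assert).

## Fitting

Default objective: AARD formed on mole fractions, because that is the
statistic used to rank such models; SSE on y₂ is available for
sensitivity analysis. Residuals are always formed in y₂ space, not the
model's native log space — a log-space OLS is *not* the AARD optimum,
and the difference matters: on the reference data the log-space Chrastil
slope gives ΔH_tot ≈ 34.8 kJ/mol, whereas the AARD-refined fit gives
≈ 41.4 kJ/mol and reproduces the published coefficients. For this reason
the enthalpy pipeline uses the AARD-refined (still deterministic) fits.

Multistart procedure, deterministic given the seed:

1. start 1 is the exact OLS solution in the native space (clipped to
   bounds); up to 8 further starts jitter it multiplicatively (±30 %);
2. remaining starts are Latin-hypercube draws over the bounds
   intersected with a ±100 sampling box (coefficients of well-scaled
   correlations live inside it; the nominal ±10⁶ bounds only cap the
   local solver);
3. every start is refined by trust-region least squares on relative
   residuals (a smooth surrogate of AARD), then the three best
   candidates are polished by adaptive Nelder–Mead on the exact
   objective (cap 4000 iterations);
4. ties break by lexicographically smallest parameter vector.

The contract is *best local optimum found*, not global optimality. In
practice the OLS anchor dominates: headline optima move by < 0.02
percentage points across seeds.

Scorecard conventions: SSE = Σ(y₂ᵉˣᵖ−y₂ᶜᵃˡ)²; RMSE = √SSE so the two
printed columns are definitionally consistent (conventional √(SSE/N) is
exposed as `rmse_mean`); R² uses the standard total-sum-of-squares
denominator (the nonstandard variant with a predicted-value denominator
is exposed separately and used nowhere); adjusted
R² = |R² − Q(1−R²)/(N−Q−1)| with **Q = number of independent state
variables** of the model (2 for Chrastil, 3 for Méndez-Santiago–Teja),
not its parameter count.

## Thermodynamic diagnostics

ΔH_tot = −c·R from the Chrastil and Kumar–Johnston 1/T coefficients,
ΔH_vap = −c·R from Bartle's, and ΔH_sol = mean(ΔH_tot) − ΔH_vap. The
solvation term is stored signed (negative: exothermic) with the
magnitude exposed for printing. On the reference data:
ΔH_tot ≈ 41.3/41.4, ΔH_vap ≈ 60.2, ΔH_sol ≈ −18.9 kJ/mol.

Self-consistency: all records are transformed into a model's linearizing
coordinates after removing the fitted temperature term (e.g. Chrastil:
x = ln ρ, y = ln S − c/T; Méndez-Santiago–Teja: x = ρ,
y = T·ln(y₂P) − c·T), one line is fit through all isotherms pooled, and
the pooled R² scores the collapse. On the reference data the
density-referenced coordinates (Bartle 0.946, Méndez-Santiago–Teja
0.946) collapse slightly better than Chrastil/Kumar–Johnston (0.92).

Crossover: isotherms are interpolated piecewise-linearly in (P, ln y₂) —
deliberately not with splines, which manufacture spurious crossings on
6-point isotherms — and every isotherm pair is scanned for sign changes
of the difference on a 2001-point grid, with exact linear root-finding
inside the bracketing interval. Identical isotherms are flagged
degenerate; non-overlapping pressure ranges are skipped with a note. On
the reference data all six pairs cross in 191–199 bar.

## Synthetic data

The generator emulates the measurement design: a T × P grid (default the
experimental 4 × 6), densities bilinearly interpolated from the bundled
ρ(T, P) table (exact at its 24 nodes, extrapolation refused), mole
fractions from any registered model, and multiplicative lognormal noise
y₂ ← y₂·exp(ε), ε ~ N(0, σ²). Defaults: σ = 0.05, matching the roughly
constant ≈ 2–5 % relative replicate scatter of the measurements;
multiplicative because that scatter is relative, lognormal so positivity
is preserved.

What it does *not* emulate: assay-chain systematic error, density
uncertainty, temperature/pressure jitter, or any correlation between
noise at neighbouring state points. Passing recovery tests therefore
show that the *estimation machinery* is unbiased and identifiable under
the stated noise model on this design — not that real measurements obey
that model.

The recovery study (simulate → fit over seeds `seed + r`) reports
per-parameter relative bias and RMSE. At σ = 0.05 with 20 replicates the
five representative well-identified models (Chrastil, Kumar–Johnston,
Bartle, Méndez-Santiago–Teja, reduced association) keep median
parameter errors under 10 %. Heavily parameterized forms (e.g. 8-term
Belghait, or forms with 1/T and 1/T² together) are *not* identifiable on
a 24-point grid in parameter space — their designs are
numerically rank-marginal — even though their fitted surfaces reproduce
the data; noiseless-recovery tests therefore assert recovery of the
generating *surface* at solver tolerance for every model, and of the
*parameters* only for well-conditioned ones.

## Numerical choices and degenerate inputs

* Linear solves use `lstsq`; rank is checked on the column-normalized
  design (tolerance 10⁻¹⁰) so raw unit scales do not trigger false
  degeneracy.
* Non-finite model output raises an evaluation error naming the model
  and offending point; inside fitting it becomes a large penalty so bad
  Latin-hypercube starts die quietly.
* Fits require strictly more data points than parameters; the adjusted
  R² requires N > Q + 1.
* Conversions between ln S space and y₂ are exact (round trip asserted
  to 10⁻¹² relative).
* Default parameter bounds ±10⁶ with per-model overrides (κ ∈ [−10, 10];
  the Andonova prefactor a > 0, solved linearly in ln a).

## Limitations

* Binary systems only; no cosolvent terms (the association derivation
  assumes solvent mole fraction ≈ 1).
* Densities must be supplied; no equation of state is included.
* The battery's published 15-compound generalization is out of scope;
  only the regorafenib system ships as data.
* Several Group I/II source renderings remain genuinely ambiguous; the
  chosen canonical readings are documented per model, and comparisons
  against published per-model AARDs are only made for the forms whose
  reading could be validated against printed parameters.
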