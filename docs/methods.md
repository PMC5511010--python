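# Methods

`chapbind` models the equilibrium binding of an Hsp70 chaperone (DnaK) to a
small, marginally stable client protein and the NMR-derived quantities used
to characterise that interaction: titration speciation profiles,
stoichiometry calls from peak-intensity maxima, relative affinities and
free-energy differences, side-chain rotamer populations, diffusion decays,
magnetization-exchange bounds, and two-state folding kinetics.

## Binding models

The client exchanges between a native state `N` and an unfolded state `U`
with folding constant `K_UN = [N]/[U]`; only `U` binds chaperone `K`. With
`K_UN = 22.7` (35 °C) the unfolded state carries `1/(1 + K_UN) = 4.2%` of
the free client. Two schemes are implemented:

* **linear** (sequential): `U + K ⇌ UK` (Kd1), `UK + K ⇌ UK2` (Kd2);
* **square** (two independent sites A, B): `U + K ⇌ UKA` (Kd1),
  `U + K ⇌ UKB` (Kd2), with either arm binding a second chaperone to give
  `UKAB`; opposite arms share constants, so `[UKAB] = K1·K2·[U][K]²`.

Mass balance in either scheme reduces to a cubic in the free chaperone
concentration `x = [K]`:

```
a x³ + b x² + c x + d = 0,   a = K1·K2,  d = −(1 + K_UN)·K_T
linear:  b = K1 + K1·K2·(2 N_T − K_T),      c = 1 + K_UN + K1·(N_T − K_T)
square:  b = K1 + K2 + K1·K2·(2 N_T − K_T), c = 1 + K_UN + (K1 + K2)·(N_T − K_T)
```

with association constants `K1 = 1/Kd1`, `K2 = 1/Kd2` and totals `N_T`
(client) and `K_T` (chaperone). All concentrations are molar end to end; a
disabled step is expressed as `Kd = +inf → K = 0`.

**Root selection.** The mass-balance residual
`g(x) = x + bound(x) − K_T` is strictly increasing on `[0, K_T]` with
`g(0) ≤ 0 ≤ g(K_T)`, so exactly one physical root exists. The production
path enumerates the real roots of the cubic (`numpy.roots`), keeps the one
inside `[0, K_T]` (tolerance `1e-12·K_T`), and polishes it with Newton
steps on the cubic; if floating-point noise leaves no admissible root it
falls back to the independent oracle. The oracle
(`solve_free_chaperone_oracle`) brackets `g` on `[0, K_T]` and solves with
Brent's method at machine-precision tolerances; it exists purely for
cross-validation and is never the production path. Degenerate inputs
(`K_T = 0`, `N_T = 0`, no binding) are handled analytically to avoid 0/0
in the coefficients.

**Numerical limits.** The two paths agree to 1e-10 relative except in one
conditioning-limited corner: when binding is so tight that the free
chaperone is ~1e-10 of `K_T`, cancellation in evaluating `g` (error
~eps·K_T) caps the oracle's achievable relative accuracy. Comparisons
therefore carry an absolute floor of `1e-15·K_T` — machine precision of
the oracle's bracket. For `K_T < 1e-30 M` (far below any physical
concentration) the oracle uses the exact linearisation of `g`, which is
accurate to double precision there. Mass balances hold to 1e-9 relative
everywhere.

## Titration protocol

The serial volume-replacement protocol removes a volume fraction `f` of
the sample and replaces it with chaperone stock: `N_T' = N_T(1−f)`,
`K_T' = K_T(1−f) + f·K_stock`. Volume is constant, the client dilutes
geometrically, and the state obeys the conserved mixing line

```
K_T/K_stock + N_T/N_T0 = 1
```

which makes `(N_T, K_T)` at a given ratio `K_T/N_T` independent of the
step sequence. `plan_protocol` inverts the update exactly to hit requested
ratios (`f = (ρ·N_T − K_T)/(K_stock − K_T + ρ·N_T)`); since `K_T` never
reaches `K_stock`, every finite ratio above the current one is reachable
with `f < 1`, and only decreasing targets are rejected. Defaults follow
the experimental conditions: `N_T0 = 0.6 mM`, `K_stock = 2.1 mM`, target
ratios {0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0} (the
experimental ratio list is not published; this grid spans the measured
range and is configurable). A dense-grid mode evaluates the model on the
continuous-replacement limit of the same mixing line
(`N_T = N_T0·e^{−s}`, `K_T = K_stock·(1 − e^{−s})`), giving smooth
profiles so maxima can be located to better than the experimental point
spacing; 401 points over ratio 0–4 by default.

## Stoichiometry fingerprints and the dilution subtlety

In the tight-binding regime the **population** of a 1:1 complex (its
fraction of total client) peaks at ratio `K_T/N_T = 1` — the
stoichiometric equivalence point — while the 2:1 complex saturates beyond
ratio 2. Because the client dilutes along the mixing line (~22% by ratio
1 at these concentrations), the two fingerprints appear in different
observables:

* the raw **concentration** of the 1:1 complex peaks at ratio ≈ 0.8
  (dilution pulls the maximum below 1), while its population peaks at
  1.000;
* the **population** of the 2:1 complex rises monotonically (no interior
  maximum), while its concentration peaks at ratio ≈ 2.00 precisely
  because dilution overtakes saturation past the 2:1 equivalence point.

`SpeciesProfile` exposes both series. The headline checks use the 1:1
population maximum and the 2:1 concentration maximum; both land within
0.01–0.04 of ratios 1 and 2 across `Kd1, Kd2 ∈ {1e-9, 1e-8, 1e-7} M` and
both schemes. `classify_stoichiometry` operates on measured intensities
(∝ concentration): the ≈ 0.2 dilution shift of 1:1 maxima is absorbed by
the 0.25 decision margin around the candidate ratios {1, 2}; maxima at a
grid boundary, or farther than the margin from both candidates, are
called ambiguous. `profile_maximum` refines the maximal sample by
three-point quadratic interpolation (robust at ~10-point experimental
density; ties report the lower ratio).

## Relative affinities

Two 1:1 complexes drawing on the same free `U` and `K` pools satisfy
`[UK']/[UK] = Kd1/Kd1'`, so intensity ratios at the common profile maximum
are inverse Kd ratios: `kd_rel = I_ref/I_i` with the most intense (tightest)
mode as reference. Free-energy differences follow as
`ΔΔG = R·T·ln(kd_rel)` with `R = 1.9872e-3 kcal·mol⁻¹·K⁻¹` and
`T = 308.15 K` by default. The measured intensity pattern 1 : 0.4 : 0.05
gives `kd_rel` = 1 : 2.5 : 20 and ΔΔG = 0 : 0.56 : 1.83 kcal/mol; published
analyses of the same pattern quote 2.6 and 20.1 (0.6 and 1.8 kcal/mol),
the small difference reflecting unrounded intensities that are not
printed. Differential relaxation between bound states is **not** corrected
for: a 6.1 Hz ¹H linewidth spread over the constant-time HMQC transfers
(two periods of `1/(2J)`, total `1/J = 8 ms` at `¹J_CH = 125 Hz`) costs
`1 − exp(−π·Δν·T) = 14%`, small enough to read intensities as
concentrations; the generator's per-conformer attenuation can inject such
a bias to quantify its effect.

## Auxiliary spectroscopic calculations

* **Rotamer populations.** Ile ¹³Cδ1 shifts interpolate linearly between
  pure-rotamer references, `p_trans = (δ_obs − δ_g)/(δ_t − δ_g)` clamped
  to [0, 1]; defaults `δ_trans = 14.8`, `δ_gauche− = 9.3 ppm` (the
  standard limits for shift-based χ2 estimation), required configuration
  rather than hard-coded truth.
* **Diffusion.** `I = I0·exp(−d·G²)` is fitted by log-linear least squares
  seeded nonlinear refinement; exact to 1e-9 on noiseless input, `d`
  recovered within 5% (median) at 2% noise over 12 gradient points in
  4–60 G/cm.
* **Magnetization exchange.** Symmetric equal-population two-site exchange
  with uniform R1: the crosspeak fraction of total longitudinal signal is
  `(1 − exp(−2·k_ex·t_mix))/2`; R1 damps both peaks equally and cancels.
  Validated against the matrix exponential of the 2×2 master equation to
  1e-9. Non-observation of crosspeaks at mixing time `t_mix` with
  detection floor `θ` (default 0.05, configurable; no measured value
  exists) bounds the off-rate by `k = −ln(1 − 2θ)/(2·t_mix)`: 0.176 s⁻¹
  at 300 ms, consistent with a sub-0.3 s⁻¹ off-rate. Site populations and
  R1 values of the real system are unknown; the symmetric model is a
  documented stand-in whose reported ratio does not depend on R1.
* **Folding kinetics.** Two-state `U ⇌ N` is solved in closed form (the
  exact integral of the rate equation, cross-checked against `solve_ivp`
  to 1e-9); `fit_single_exponential` fits `A·(1 − e^{−λt}) + C` and
  returns `λ = k_fold + k_unfold`. An irreversible trajectory at
  `k_fold = 1/(2.9 ms)` fits to 345 s⁻¹. The full chaperone-cycle kinetic
  network is out of scope.

## Synthetic data generator

Intensities are species concentration × per-conformer response factor ×
attenuation × cumulative per-step loss `(1 − loss)^step` × multiplicative
Gaussian noise `(1 + ε)`, `ε ~ N(0, sd)`. Multiplicative noise reflects
peak-height error at a constant spectral noise floor when peaks are well
above it; negative draws are clipped to zero with a warning. The per-step
loss emulates slow sample aggregation (default 0). All generators are
pure functions of (parameters, seed). What the generator does **not**
emulate: lineshapes and peak overlap, baseline and phasing artefacts,
exchange broadening, and chaperone self-oligomerization — passing
round-trip tests therefore demonstrate correctness of the inference logic
under the stated observation model, not robustness to every artefact of
real spectra.

## Problem sizes and defaults

Dense grids use 401 points (maxima stable to < 0.01 in ratio vs 4001);
round-trip suites use 100 seeds at 1% noise; solver cross-validation uses
1000 random parameter draws spanning `Kd ∈ [1e-12, 1e-2] M` and totals in
`[0, 5e-3] M`. Temperature default 308.15 K. Concentrations are molar in
the core; the CLI accepts mM to match the wet-lab protocol.

## Known limitations

* No absolute Kd estimation and no quantitative model selection between
  the linear and square schemes (the data distinguish them only
  qualitatively).
* Chaperone binding to the native state is assumed absent.
* Chaperone self-oligomerization (relevant for ADP-state DnaK) is not
  modelled.
* The rotamer mapping is a two-state linear interpolation; it inherits
  the accuracy of the reference shifts supplied.
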