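# Methods

## Growth model

The model describes the coalescence-driven growth stage of
nanoprecipitation after solvent exchange is complete. Its assumptions:
particles are spheres that merge pairwise; their relative motion is purely
Brownian (no shear- or sedimentation-driven collisions); mixing is fast
compared to growth, so from t = 0 the system is a suspension of primary
particles of diameter D_h0 in the aqueous continuous phase. Under these
assumptions every encounter of two equal spheres removes one particle:

    dc_p/dt = -K h c_p²,   K = 4π (2D)(2R) = (8/3) k_B T / μ,

size-independent because the Stokes–Einstein diffusivity D = k_B T/(6πμR)
cancels the radius. With mass conservation c_p D_h³ = c_p0 D_h0³ this is
equivalent to the diameter ODE

    dD_h/dt = (8/9) (k_B T/μ) c_p0 D_h0³ / D_h² · h,

whose h = 1 solution is the closed form D_h(t) = D_h0 (1 + t/τ_cs)^{1/3}
with τ_cs = (3/8) μ/(c_p0 k_B T). The 8/9 coefficient is the one
consistent with that closed form and the number balance; the library also
exposes an `as_printed` mode with coefficient 8/3 (a form sometimes quoted
for this ODE) for auditing — it grows faster and does not match the closed
form, so it is never the default. All internal computation is SI; I/O uses
nm, ms, g/L, mPa·s and g/cm³ with exact conversion factors, and flag/key
names carry unit suffixes to keep the conversion layer auditable.

The model is monodisperse and mean-field: it tracks the mean diameter, not
a population balance. That is the main structural simplification, and why
PDI is estimated indirectly (below).

### Defaults

| parameter | default | units | meaning |
|---|---|---|---|
| μ | 0.932 | mPa·s | continuous-phase (water) viscosity at 300 K |
| T | 300 | K | process temperature |
| ρ | 1.145 | g/cm³ | polymer (PCL) density |
| D_h0 | 41.0 | nm | primary-particle diameter |
| t | 16.0 | ms | effective growth time |
| dilution_factor | 1 | — | nominal → post-mixing concentration rescale |

D_h0 and t are the model's two free parameters, obtained by fitting;
the defaults are a reference fit for a PCL/THF–water system. The nominal
concentration is the organic-phase value; any constant organic:aqueous
dilution is absorbed by the fitted t (or set explicitly via
`dilution_factor`).

## Finite coalescence time

Two merging droplets pass through a transient dumbbell shape, described in
polar coordinates (angle from the line of centres, so θ = π/2 is the neck)
by r²(θ) = D_h0² b c(b) (1 − b sin²θ), b ∈ [0, 1]. The volume factor c(b)
is defined by requiring the revolved solid to hold the volume of the two
initial spheres; the defining integral is elementary
(c(b) = (2I(b))^{-2/3}/b with
I(b) = 1/2 + (3(1−b)/4)[1 + ((1−b)/√b) asinh(√(b/(1−b)))]), giving the
exact limits c(1) = 1 (touching spheres) and b c(b) → 2^{-4/3} (one merged
sphere). Tests validate the closed form against numerical quadrature to
1e-8.

Merging progress is tracked by the neck ratio correlation

    L/D_h0 = min(1, 0.1436 ln τ + 0.5347),

with τ the dimensionless time between successive collisions, modelled as
τ = k_τ / c_p0² (collision frequency ∝ c_p0² for binary collisions). The
correlation is additionally floored at 0 — a negative size factor is
unphysical at extreme τ. Note a geometric inconsistency that is documented
rather than patched: the shape model's neck ratio L/D_h0 = √(b c(b)(1−b))
never exceeds 2^{-2/3} ≈ 0.63, while the correlation saturates at 1. The
correlation is treated as the operative rule (its saturation at 1 encodes
"coalescence completes"), the shape equations as descriptive utilities.

The corrected final diameter is the closed-form prediction multiplied by
the neck factor. This composition reproduces the observed behaviour:
identical to the ideal law at low concentration (τ above the saturation
threshold ≈25.5), and decreasing at high concentration, with a maximum in
between. k_τ is fixed by requiring that maximum to sit at a chosen
concentration (default 20 g/L): on the unclamped branch the product
D(c)·φ(c) is stationary where φ* = 2·0.1436/(c · d ln D/dc), which is
solved exactly and then verified by an argmax scan (tolerance 1e-3
relative). Calibration fails with a diagnostic scan if the required neck
factor falls outside (0, 1) — e.g. when growth at the set point is too
weak to produce an interior maximum.

## Surfactant surface blocking

Surfactant molecules adsorb onto particle surfaces and block coalescence.
Coverage is counted with the cross-section (disc) convention,
A = c_p π D_h²/4 and A_block = c_s,att π a²/4 — the π/4 cancels in the
ratio, and any systematic misfit is absorbed by the effective footprint
diameter a. The collision efficiency is linear in free surface,
h = 1 − A_block/A (0 at full coverage); forms beyond linear are not
identifiable from available data and are not implemented. Growth and
adsorption share h:

    dc_s,att/dt = (2/3)(k_B T/μ)(D_h/D_s)(c_s,0 − c_s,att) c_p h.

Adsorption is typically much faster than growth, so the coupled system is
stiff; it is integrated with LSODA (rtol 1e-9, state-scaled atol) whenever
surfactant is present and with DOP853 (rtol 1e-10) otherwise, where the
closed form serves as the oracle. An integration event records the arrest
time at which h reaches 0; the trajectory is flat afterwards since both
derivatives vanish. Repository defaults a = D_s = 3 nm and surfactant
molar mass 12 600 g/mol (an F-127-like triblock) are engineering choices,
user-overridable and fittable — they are not measured constants.
Micellization above the CMC (which would reduce free surfactant at high
concentration) is not modelled; at high c_s,0 the model therefore
overstates adsorption somewhat, though the qualitative saturation of size
reduction is reproduced regardless.

## PDI estimate

DLS reports a cumulant polydispersity index; the model has no intrinsic
polydispersity, so PDI is estimated by treating the growth time as
distributed — mixing history gives different fluid elements different
effective growth times. The time distribution (uniform on
[t(1−δ), t(1+δ)], or lognormal with sigma δ; default uniform, δ = 0.3) is
pushed through the forward model on a fixed 64-node Gaussian quadrature
grid and PDI = variance/mean² of the resulting number-weighted diameter
distribution. For small δ a delta-method expansion of the closed form
gives PDI ≈ (δ²/27)(x/(1+x))² with x = t/τ_cs; the estimator matches this
within 1% for δ ≤ 0.05 (tested). A finite-coalescence factor is
concentration-dependent but time-independent, so it cancels exactly in
variance/mean² and does not affect the estimate; surfactant coupling does
affect it, because adsorption flattens D(t) and narrows the distribution.

This estimator is deliberately modest: with δ = 0.3 it yields PDI of order
10⁻³–10⁻², an order of magnitude below typical DLS cumulant PDIs
(0.1–0.3). It captures relative trends (more surfactant → narrower; wider
time spread → broader), not the absolute DLS scale, which also contains
instrument and inversion contributions outside this model. Design targets
on PDI should therefore be specified on the model's own scale; a DLS-scale
PDI target is reported as a structured infeasibility rather than silently
mismatched.

## Fitting and inverse design

`fit_growth_params` minimizes Σ w_i (D_model(c_i) − D_obs,i)² over
(D_h0, t) with positivity bounds (trf solver, xtol/ftol/gtol 1e-14), from
a deterministic 4×4 log-spaced start grid (D_h0 from 1 nm up to the
smallest observed diameter; t from 0.1 to 1000 ms), tie-broken by lowest
SSE then lowest t. Optional 1/sd weighting. Standard errors come from the
Gauss–Newton curvature at the optimum. Records are sorted by
concentration before fitting so the result is bit-identical under input
permutation. Identifiability: t is tightly determined by the
high-concentration slope, D_h0 only by the low-concentration intercept, so
single noisy series determine D_h0 loosely (curvature stderr ≈8% at
triplicate 2 nm noise) while the median over many replicate series is
unbiased to well under 1%.

Inversion for a target diameter uses the exact closed-form rearrangement
when no correction or surfactant is active (round-trip exact to 1e-9
relative); otherwise bracketed Brent root-finding on the forward model.
Under the finite-coalescence correction the curve is unimodal: the
achievable maximum is located first, targets above it raise a structured
infeasibility carrying that maximum, and the ascending
(lower-concentration) root is returned otherwise. Full design nests this
inversion inside a Brent solve on surfactant concentration matching the
PDI target; since surfactant only narrows the distribution, PDI targets
above the zero-surfactant value (or below the value at the surfactant cap,
default 10 g/L) return non-converged results naming the binding
constraint.

## Synthetic data

The generator emulates triplicate DLS concentration series: per
concentration, replicate diameters are drawn Normal(model mean, sd) with a
1 nm physical floor, and per-concentration mean and sample SD are
reported. Defaults are the reference conditions: truth (41.0 nm, 16.0 ms),
ten concentrations spanning 1–50 g/L, triplicates, 2 nm noise. All
randomness flows from one integer seed through
`numpy.random.default_rng`, making outputs bit-reproducible and
platform-independent (golden-value tested). What it does not emulate:
intensity-weighting and cumulant inversion of real DLS,
concentration-dependent noise, instrument drift, or aggregation events —
so passing recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to real DLS artefacts.

## Problem sizes and numerical choices

The Monte-Carlo recovery study uses 100 replicate series of 10
concentrations with a 16-start fit each (~6 s total); ODE-equivalence
checks use 20 seeded random parameter sets at solver rtol 1e-10 against
the closed form (agreement better than 1e-6 relative, typically 1e-8);
shape-volume conservation is checked on a 25-point b-grid against
adaptive quadrature at 1e-8. Degenerate inputs are defined, not errors:
c = 0 or t = 0 return D_h0; c_p0 = 0 yields an infinite coalescence
timescale ("no coalescence") and an infinite inter-collision time
(correction factor exactly 1).

## Known limitations

- Mean-field and monodisperse: no population balance, no aggregate
  morphology; fibrous or very large particles violate the sphericity
  assumption.
- The fitted t is an effective time conflating mixing and growth; it and
  any constant dilution are not separately identifiable from a single
  concentration series.
- The neck correlation vs shape-model normalization inconsistency noted
  above.
- PDI magnitude is not on the DLS cumulant scale (see above).
- No micellization, desorption, or electrostatic (zeta-potential/DLVO)
  stabilization modelling.
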