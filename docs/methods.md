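# Methods

## Lattice geometry

A design point is (surface type, Lx, Ly, Lz, t, θ, H, D): a TPMS family, the
per-axis unit-cell sizes (mm), the shell thickness (mm), a rotation about the
X axis (degrees), and the cylindrical envelope's height and outer diameter
(mm). The level sets are the standard trigonometric approximations

* Gyroid: sin X cos Y + sin Y cos Z + sin Z cos X
* Schwarz Diamond: sin X sin Y sin Z + sin X cos Y cos Z + cos X sin Y cos Z
  + cos X cos Y sin Z
* Split-P: 1.1 (sin 2X sin Z cos Y + sin 2Y sin X cos Z + sin 2Z sin Y cos X)
  − 0.2 (cos 2X cos 2Y + cos 2Y cos 2Z + cos 2Z cos 2X)
  − 0.4 (cos 2X + cos 2Y + cos 2Z)

with X = 2πx′/Lx etc., where p′ is the point after rotation about X by θ.
Split-P coefficient conventions vary across the literature and commercial
kernels; the adopted coefficients are exposed (`SPLIT_P_COEFFS`) so
alternates can be swapped, and absolute RD/SA values for Split-P should be
read with that caveat.

**Shell solid.** A "sheet" lattice of metric thickness t is the set
|φ(p)| / ‖∇φ(p)‖ ≤ t/2 — the first-order (gradient-normalized) distance to
the level set — intersected with the envelope x² + y² ≤ (D/2)², 0 ≤ z ≤ H.
A raw field band |φ| ≤ c would give spatially varying wall thickness because
‖∇φ‖ varies along the surface; normalizing by the gradient makes t a true
length. Gradients use central differences with step 10⁻³ · min(L); where
‖∇φ‖ < 10⁻⁶ (isolated critical points) membership falls back to the bounded
band |φ| ≤ π t / min(L), the field change over a distance t at the nominal
slope 2π/min(L) — this never divides by zero and affects a measure-zero set.

**Descriptors.** The solid is sampled at voxel centers on a grid covering
the envelope. RD (%) is the occupied fraction of in-envelope voxels — this
makes the degenerate full solid read exactly 100 % and cancels the
staircase bias of the cylindrical boundary. Porosity is 100 − RD by
construction. The surface mesh is the marching-cubes zero level of
max(shell distance − t/2, envelope distance), so it includes the cylindrical
and planar cut faces of the trimmed shell; surface area is the mesh area,
and SA/VR divides by the *solid* (material) volume, the scaffold convention.
Default voxel pitch is 0.05 mm (≤ t/4 for the thinnest 0.2 mm shell); the
pitch is validated against t/2 (error) and t/4 (warning). Test designs use
H ≤ 8 mm, D ≤ 5 mm at 0.1 mm pitch so grids stay desktop-scale; at that
pitch RD changes by < 1 % under pitch halving and sphere/box isosurface
areas match closed forms within 2 %.

## Design space

The factorial levels are: three surface types; cell sizes {3, 4} mm per
axis; thickness {0.2, 0.3, 0.4} mm; rotation {0, 30, 60}°; heights
{8, 10, 15, 20} mm; diameters {5, 10, 15, 20} mm. The height and diameter
level sets are a reconstruction: only their ranges (8–20, 5–20 mm) are fixed
externally, and these four-point grids are the choice that makes every
bookkeeping count (3456 enumerated; 3024 after the filter; per-type
72/504/432) come out exactly. Keeping H/D ≤ 2 discards slender columns
prone to buckling under compression. Size classes: small (H ≤ 8 and
D ≤ 8 mm), large (H > 15 or D > 15 mm), medium as the complement — the
complement rule avoids the gaps a literal interval rule would leave
(e.g. H = 10, D = 5 mm), and precedence is small, large, medium.

Features for modelling: the seven numeric parameters are z-scored with the
training-set mean/std; surface type becomes a three-column one-hot block
(gyroid, diamond, split_p), appended unscaled — 10 features total. The
fitted scaler is persisted with the model so new designs are encoded
identically.

## Mechanical metrics

Engineering stress divides force by the envelope cross-section π(D/2)², not
the material area — the cellular-solids convention, which keeps lattice
stress comparable across RD. Strain is displacement over initial height.
U is the curve maximum; EA integrates σ dε (trapezoid, with linear
interpolation at the limit crossing) to ε = 0.5, giving MJ/m³; a curve
ending early is integrated to its end and flagged. The elastic modulus is
the least-squares slope over the samples whose stress lies in 10–40 % of U
on the rising branch (robust to plateau onset; window configurable); yield
is the 0.2 %-offset intersection, falling back (flagged) to the first local
maximum when the offset line never crosses; plateau stress averages
ε ∈ [0.2, 0.4], standard for cellular solids.

The Johnson–Cook failure strain
ε_f = (d₁ + d₂ e^{d₃η})(1 + d₄·rate)(1 + d₅·temp) is implemented as a
formula with the compression-calibrated Ti6Al4V constants d₁ = 0.005,
d₂ = 0.55, d₃ = −0.25, d₄ = d₅ = 0 as defaults (ε_f = 0.555 at η = 0,
→ 0.005 as η → ∞). No damage-evolution FEA is implemented; the Ti6Al4V
elastic constants and the (mass-scaled) density 10 750 kg/m³ are carried as
metadata only.

## Synthetic response generator

The generator replaces commercial explicit-dynamics FEA so the pipeline is
testable offline. It emulates, per design:

* **RD (%)**: 100 · c_type · t · mean(1/L) — a thin sheet of thickness t
  whose area per unit volume scales inversely with cell size. The effective
  coefficients {gyroid 2.2, diamond 2.5, split_p 2.8} were chosen once so
  the factorial space lands in the reported trabecular window (median
  ≈ 19–21 %, maximum ≈ 35–40 %); they fold in the area lost to the
  cylindrical trim, which is why they sit below the ideal periodic
  surface-area constants.
* **SA/VR (1/mm)**: (2/t) · (0.9 + 0.1 · 3.5 · mean(1/L)) — two faces per
  sheet of thickness t, mildly modulated by cell size.
* **U (MPa)**: k_type · σ₀ · (RD/100)^n · (1 − 0.05 θ/90)(1 + 0.03 (H/D − 1)),
  a Gibson–Ashby power law with σ₀ = 1400 MPa, n = 1.5 (bending-dominated
  sheet lattices) and type multipliers {1.0, 1.1, 0.85}. The scale puts the
  bulk of the space at 100–150 MPa with a ≈ 350 MPa tail, matching the
  reported distributions.
* **EA (MJ/m³)**: the integral of an idealized bilinear curve — linear rise
  to the plateau σ_p = 0.75 · U at ε = 0.02, constant to ε = 0.5 — times a
  type multiplier; median ≈ 47 MJ/m³.

All four targets receive independent multiplicative lognormal noise with
coefficient of variation 0.02 (unit mean), seeded; outputs are bit-for-bit
reproducible per seed. What passing tests show: the pipeline recovers
*this* constructed, smooth, power-law world. Real FEA data add contact
nonlinearity, buckling-mode switches and mesh sensitivity that the emulator
deliberately omits, so surrogate accuracies here do not transfer to real
data; the paper-level claim being checked is structural (the chain runs,
thickness dominates U, fronts populate the RD window).

## Surrogate

A feed-forward network with hidden layers (128, 64, 32), ReLU (the
activation is not externally fixed; ReLU is the default for this depth),
linear 4-unit output, Adam at lr 10⁻³, MSE loss, batch 32, 150 epochs, no
early stopping, no k-fold — evaluation is on the single held-out 20 %
(floor convention: 3024 → 2419/605). Targets are z-scored for training so
the four outputs (percent, 1/mm, MPa, MJ/m³) weigh comparably in the loss,
and inverse-transformed for reporting; a zero-variance target is predicted
as its constant. The backend is scikit-learn's MLPRegressor driven one
epoch at a time to record train/validation loss histories. Determinism
holds per seed within a BLAS configuration. On the synthetic study
(n = 3024, cv 0.02) held-out R² ≥ 0.99 per target with validation loss
tracking training loss (no divergence).

## NSGA-II

A from-scratch implementation: vectorized fast non-dominated sort (verified
against an O(n³) brute-force partition), crowding distance with infinite
boundaries and range-normalized interior gaps, binary tournaments on
(rank, crowding) over two shuffled pairings per generation, bounded SBX
(η_c = 15, pair probability 0.9, per-variable rate 0.5, per-variable child
swap), bounded polynomial mutation (η_m = 20, rate 1/d), and (μ+λ) elitist
truncation. Initialization is Latin-hypercube. Offspring duplicating an
existing decision vector are perturbed once more to keep the pool diverse.
Population 100, 50 generations. Zero-width bounds (a size group where a
variable takes one value) leave that variable fixed.

Per size group the seven numeric variables are optimized as continuous
values within the group's observed min/max (no snapping to the factorial
grid); the categorical surface type is handled by running the optimizer
once per type and merging the three fronts through a final non-dominated
sort — SBX on a categorical code is not meaningful. Predicted RD is
attached to every survivor and the biologically motivated window
RD ∈ [20, 40] % is applied as an inclusive post-hoc filter, never as an
objective or penalty. Front sizes before/after filtering are bookkeeping
outputs, not targets.

On the ZDT1 benchmark (30 variables) this implementation reaches a mean
front distance of ≈ 0.08–0.09 at 50 generations and ≈ 0.013 at 100; at a
5 000-evaluation budget the crowding-driven phase still carries a uniform
convergence deficit (the auxiliary variables average ≈ 0.018 instead of 0),
which is characteristic of the canonical algorithm rather than of this
implementation.

## Sensitivity and attribution

OFAT curves vary one feature over its observed range (evenly spaced grid,
or the levels for categoricals) with the others at training means. Shapley
values use the interventional (marginal) convention: a feature absent from
a coalition is replaced by its value in background rows (default: 100
training rows drawn with a fixed seed), and the coalition worth is the mean
prediction over the hybrids. The exact estimator enumerates all 2^k
coalitions (capped at k = 13) and satisfies efficiency by construction; the
sampled estimator averages marginal contributions over random permutations
and reports Monte-Carlo standard errors (unbiased; agrees with exact within
3 SE on toys). Attribution applies uniformly to any predictor through a
plain callable — the neural surrogate by default; a random forest can be
substituted via scikit-learn if tree-based attributions are wanted.
One-hot indicator columns are attributed as separate features, passed
through to the model unscaled.

## Pipeline problem sizes

The end-to-end run uses the full 3024-design space, 150 training epochs,
and nine optimizer runs (3 types × 3 size groups) at population 100 for 50
generations. Attribution summaries sample 12 designs per group against a
50-row background with 20 permutations each — enough to rank features
stably (thickness first for U in every group across seeds) while keeping
the whole chain around ten seconds on one CPU.

## Known limitations

* Absolute RD/SA values depend on the level-set conventions (notably
  Split-P) and on the voxel/isosurface discretization; they are convergent
  estimates, not CAD-kernel measurements.
* The synthetic generator is a smooth stand-in; conclusions about real
  Ti6Al4V lattices require retraining on measured or simulated data.
* The surrogate is specific to the three TPMS families and the swept
  parameter ranges; it extrapolates poorly outside the factorial box.
* Whether the measured surface area should include the trimmed cylindrical
  cut faces is a modelling choice; they are included here.
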