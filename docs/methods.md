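# Methods

This note records the models implemented in `iremap`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic studies
do and do not demonstrate.

## Geometry and discretization

All maps live on a square, cell-centered grid: by default 64 × 64 pixels
over a 30 mm field of view (pixel 0.469 mm), matching a small-animal MREIT
acquisition. Pixel (row, col) has its center at ((col+0.5)h, (row+0.5)h)
with the origin at the lower-left corner; arrays are row-major (y, x).
The imaging slice is treated as 2D: the needle electrodes run perpendicular
to it (parallel to the scanner's main field), so their cross-sections are
disks held at the applied potential. Electrode pixels are those whose
center falls inside the disk, with a guaranteed minimum of one pixel.

A known coarse-grid limitation: a 0.5 mm electrode maps to 1–2 Dirichlet
pixels whose *effective* lattice radius is well below 0.25 mm, so the
total driven current at 64 × 64 is ~30% below the grid-converged value
(256 × 256 and 384 × 384 agree to ~1%). All quantitative claims in the
test suite are therefore same-grid consistency statements; grid-refinement
is checked only at resolved scales.

## Forward problem

The potential solves the 2D continuity equation div(σ grad u) = 0 with
Dirichlet values on the electrode pixels and insulating (zero-flux) outer
boundaries. Discretization is 5-point finite volumes with **harmonic**
averaging of σ at cell faces, which keeps normal current continuous across
conductivity jumps. The sparse system is solved directly; the relative
residual (~1e-15) is checked against a 1e-8 tolerance. Fields follow from
central differences: E = −grad u, J = σE.

Verified against two closed forms: a plate-capacitor configuration
(uniform field, exact to ~1e-13) and the two-line-source potential
(I/2πσ)·ln(r_b/r_a), matched to ~1% on a 256² grid with the electrodes far
from the boundary, with the source strength I measured from the discrete
divergence of J rather than fitted.

## Measurement model (CDI)

The MR phase accumulated during current injection is φ = γ·Bz·tc with
γ = 2.675×10⁸ rad s⁻¹ T⁻¹ and tc the current-on encoding time. The
default tc = 400 µs reads the pulse train as four 100 µs pulses per shot
(the 700 µs burst contains four pulses at 5 kHz); this is an
interpretation, recorded here, since only the burst structure is public.
No phase unwrapping is implemented: synthesis raises if |φ| exceeds π.

Ampere's law with only Bz measurable gives the standard single-component
inversion jx = (1/µ0)∂Bz/∂y, jy = −(1/µ0)∂Bz/∂x (central differences,
one-sided at edges; optional Gaussian pre-smoothing, default off).

**Why Bz is synthesized as a stream function.** The raw 2D Biot-Savart
kernel (implemented in `biot_savart_bz`, exact for source-free currents
such as a straight wire) maps any current pattern to the field of its
*solenoidal* part only. An electrode-driven potential flow is
irrotational, so its kernel image is essentially zero and no Ampere
inversion could recover it — physically, the in-plane source/sink flow by
itself is not a closed circuit. The single-Bz inversion instead *assumes*
Bz/µ0 is the stream function ψ of the in-plane current (jx = ∂ψ/∂y,
jy = −∂ψ/∂x). `synthesize_bz` therefore generates exactly that field: an
analytic source/sink (dipole-flow) term (I/2π)·arg((w−w_a)/(w−w_b)), whose
multivaluedness is confined to a branch cut on the short segment between
the electrodes, plus a path-integrated divergence-free remainder; the
dipole term enters through its discrete curl so it cancels exactly under
the central-difference inversion, and the rows crossed by the branch cut
are re-integrated vertically from clean rows on either side. The
round-trip error (synthesize → invert vs the forward J) is ~4.7% relative
L2 over the interior of the homogeneous two-point phantom — interior
meaning outside a 2-pixel dilation of the electrode pixels and the 2-pixel
domain border where only one-sided differences exist. Pixels on the
inter-electrode segment are irrecoverable in principle (the cut must live
somewhere); for gaps ≲2.5 mm they fall inside the electrode-adjacent
exclusion zone.

Measurement noise in the pipeline is Gaussian on Bz with
std = max|Bz|/SNR. The phase encode/decode leg is an exact inverse pair
and is unit-tested; under the 2D line-current idealization a 700 V drive
yields |φ| ≫ π at tc = 400 µs, so the default pipeline applies noise in
the Bz domain (equivalent for linear Gaussian noise) rather than
synthesizing a wrapped phase.

## Conductivity reconstruction (J-substitution)

Iterate: (1) solve the potential on the current σ estimate with the known
electrode potentials (700 V default) as Dirichlet data; (2) update
σ ← |J_measured|/|grad u| pointwise, flooring |grad u| at 1e-9 V/m and
clamping σ to [1e-4, 1e2] S/m; (3) stop when the relative L2 update falls
below 1e-4 or the iteration cap (50) is reached, returning a convergence
log either way. Under Dirichlet drive the simulated electrode-to-electrode
voltage equals the applied voltage identically; the renormalization factor
is computed and logged each iteration for the record.

Electrode pixels have no usable |grad u|; they are refilled each iteration
from the mean of their immediately adjacent ring. Two properties of this
choice matter: pinning them at the initial guess inserts a resistive skin
that makes the whole iteration diverge, and averaging over a wider ring
mixes tissue compartments and biases the near-electrode solve by ~10%.

With ideal (forward-model) current data the homogeneous phantom is
recovered exactly in 2 iterations and the two-region phantom's
compartment means to a fraction of a percent in <50 iterations. With
measured (Bz-chain) data the iteration reaches its fixed point in ~100
iterations and that fixed point is biased: the differentiation noise floor
inflates |J| where little current flows, pulling the background mean up by
tens of percent, and near-electrode pixels carry the residual synthesis
artifacts. This is a property of the single-Bz measurement model at this
resolution, not of the solver; the pipeline reports it rather than hiding
it. A 2-pixel electrode-adjacent annulus is excluded from all quantitative
error metrics (near-singular current density). `fill_electrode_region`
can inpaint that annulus from nearest valid neighbors for display, but it
is not applied before area extraction: at this acquisition scale the
ablation zone largely coincides with the annulus and filling erases it.

## Cell-death model

Survival is logistic in the local field magnitude:
S(E; N, tp) = 1/(1 + exp((E − Ec)/k)), D = 1 − S, evaluated in kV/cm (the
units of the published constants); V/m maps convert at the module
boundary. The bundled parameter table carries the in-vitro constants for
the treatment protocol N = 8, tp = 100 µs: Ec = 2.344 kV/cm,
k = 0.2677 kV/cm. Lookup is exact-match on (N, tp) and fails loudly with
the available keys; users can extend the table from CSV. The predicted
ablation region at level p is the inclusive super-level set {D ≥ p} — the
inclusive comparison keeps the boundary case D ≡ p non-empty — with no
connected-component filtering by default (areas, not component counts, are
the endpoint); a largest-component option exists for histology-like
comparisons.

## Agreement statistics

For each candidate level, predicted areas (A_IRE) are regressed on
reference areas (A_HE) by ordinary least squares with intercept (a
through-origin flag and a predictor-swap flag cover the alternative
conventions), and Bland-Altman analysis of the differences A_IRE − A_HE
reports the mean difference, the n−1 sample SD, limits of agreement
mean ± 1.96 SD, and the Pearson correlation of difference versus pairwise
mean (proportional-bias check; flagged not-computable when degenerate).
The working level maximizes R², ties broken by smaller |mean difference|;
on a complete tie — quantized area curves can make adjacent levels
identical — the lowest level wins, i.e. the largest predicted coverage,
the conservative choice for treatment monitoring.

## Synthetic cohort and what the studies show

The default study generates nine treated-tumor cases: elliptical tumors of
radius 2.2 ± 0.4 mm (≈40 mm³-equivalent cross-section), tumor conductivity
0.4 S/m in 0.2 S/m background — the paperless defaults; tumor and tissue
conductivities are assumptions, not measurements — electrode gaps evenly
spaced over 1.2–3.3 mm, 700 V, 8 × 100 µs at 5 kHz. Optional smooth
log-normal heterogeneity (Gaussian-filtered white noise, exponentiated,
rescaled to a target coefficient of variation, mean-preserving) emulates
the ~20% conductivity variability of real tumors. Reference areas are the
true-field p = 0.2 super-level areas plus Gaussian area noise
(SD 0.1 mm²), standing in for histology.

The level-selection validation uses a known construction: predicted area
curves from the true-field death maps, so that at p = 0.2 prediction and
reference coincide up to the injected noise. There the selection finds
p = 0.2 in ≈100% of replicates and the noise-free regression is exactly
slope 1, R² 1. This validates the statistics and selection machinery at
study scale. It does *not* show that the measurement chain reproduces
areas that well: the full Bz-route pipeline, run on the same cohort,
reaches slope ≈ 1.1 and R² ≈ 0.7–0.8 at p = 0.2, limited by ±1–2 pixel
area artifacts near the electrodes — the p = 0.2 lesion is only 6–16
pixels at this resolution. Real acquisitions differ further: 3D current
paths, slice averaging, susceptibility artifacts and physiological
conductivity dynamics are all outside this model.

## Numerical conventions

- Single top-level seed; per-case and per-stage seeds spawned
  deterministically (`numpy.random.SeedSequence`). Identical config + seed
  reproduces every output byte-for-byte.
- Pixel size is never inferred: NIfTI carries it in the header, TIFF/CSV
  require a JSON sidecar; maps carry a kind/unit tag that is verified on
  read, and NaNs are rejected with their locations.
- Unit policy: SI internally (V/m, A/m², T, S/m); kV/cm only at the
  survival-model boundary and in summaries; areas in mm².
- Problem sizes used in tests and the acceptance script: 64 × 64 for all
  chain checks (the acquisition matrix), 256² for closed-form solver
  validation, nine cases × 100 replicates for the cohort study.
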