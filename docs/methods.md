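# Methods

This note documents the models implemented in `qsmphantom`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
phantom does and does not emulate.

## Susceptibility model

The ground-truth volume susceptibility is composed per tissue class as

    χ_t(r) = χ̄_t + a_t (R2*(r) − R̄2*_t) + b_t (R1(r) − R̄1_t)        [ppm]

with `a_t`, `b_t` in ppm·s against rates in s⁻¹. The rationale: iron and
myelin drive χ, R1 and R2\* jointly and approximately linearly, so
modulating χ̄ with the relaxation-rate deviations produces anatomically
plausible χ texture that cannot be predicted from magnitude contrast alone.
The two shipped coefficient tables (`chi_model1.csv`, `chi_model2.csv`)
assign every one of the 16 classes a mean χ (air +9.2 ppm, bone −2.1 ppm,
calcification −3.3 ppm in model 1, deep-gray nuclei +0.04…+0.15 ppm) and
per-tissue `a`, `b`; bone, air, muscle and fat are piecewise constant
(`a = b = 0`). `tissue_chi_map` accepts an optional deviation clamp
(`dev_clip`) that bounds the rate deviations before they enter the law —
the synthetic counterpart of relaxometry-threshold boundary corrections on
segmented data. It is off by default because the generator's rate maps are
constructed so that no clamping is needed (below).

Partial voluming: binary brain-tissue masks are smoothed with a 3-D
Gaussian (FWHM 1.2 voxels, image-space kernel truncated at 4σ, zero-padded
edges — the masks are compactly supported), veins and non-brain masks pass
through binary, and the per-voxel probabilities are renormalised to sum to
one. The composed map is `χ(r) = Σ_t P_t(r) χ_t(r)`; uncovered voxels get
the air value.

Near air–tissue interfaces the measured R2\* is inflated by static-field
gradients, so the composition is blended towards an `a = 0` variant: the
low-pass-filtered (Gaussian, FWHM 5 mm — configurable; the filter scale only
needs to separate background-gradient structure from texture) forward-field
gradient magnitude gates a linear blend with thresholds `g_lo = 0.08` and
`g_hi = 0.3` ppm/mm. The two printed thresholds are adopted in the only
monotone ordering.

The brain-only ("local") variant sets χ to zero outside the brain mask and
demeans it inside — the ground truth for a simulation with perfect
background-field correction. The operation is idempotent.

## Synthetic head generator

The generator replaces an acquired multi-parametric data set with a seeded,
download-free head: nested ellipsoids for scalp fat, muscle, skull bone and
subarachnoid CSF, a cortical gray-matter shell around a white-matter
ellipsoid, two ventricles, thalami, the six deep-gray nuclei used by the
linearity metric (caudate, globus pallidus, putamen, red nucleus, dentate
nucleus, substantia nigra), vein cylinders of 1–2 voxel radius, one
2-voxel-radius calcification, and air cavities (sinus, ear canals) carved
into the skull base. Geometry scales with the grid (default 128³ at 1 mm);
vein and calcification radii are absolute voxel counts since those
structures live near the voxel scale. The calcification radius of 2 voxels
keeps its χ energy comparable to, not larger than, the rest of the brain —
its ~−95 ppm·mm³ moment is the same order as published head-phantom values —
while still being the dominant point perturber.

Relaxation-rate means are tissue-typical 7 T values (cortical GM T2\* 33 ms,
globus pallidus 14 ms, WM T1 1100 ms, cortical GM T1 1900 ms, etc.).
Texture is a latent Gaussian random field (white noise smoothed to a 3-voxel
correlation length, clipped at ±3 SD) shared between R1 and R2\*, because in
tissue a common perturber concentration drives both rates. The R2\*
amplitude is 2% of the mean; the per-tissue R1 amplitude is solved from the
susceptibility law so the resulting χ texture has ≈0.008 ppm SD — with
independent rate textures at these coefficient magnitudes the χ spread would
be unphysically large. Blood and calcification get near-zero rate texture
(their `b` terms are too small to balance an R2\*-driven χ texture, matching
their near-piecewise-constant treatment). The latent fields are demeaned
per label, so every label mean equals its design value exactly regardless of
where the label sits in the random field.

Two constructions make the composition well behaved at tissue interfaces,
where a tissue's law would otherwise be evaluated on a foreign compartment's
rates:

1. **Coefficient-weighted rate mixing.** At boundary voxels the rate maps
   are partial-volume mixtures of the per-tissue textured rates with weights
   `P_t·|a_t|` (for R2\*) and `P_t·b_t` (for R1). With these weights the
   deviation terms of the composed χ cancel identically for any number of
   overlapping tissues, so the interface value reduces to the pure
   partial-volume mix `Σ_t P_t χ̄_t` — the behaviour acquired data shows
   when the coefficients are fitted to the same maps. Plain-probability
   mixing would leave rim artifacts of several tenths of a ppm wherever
   neighbouring tissues have dissimilar coefficients.
2. **Pure-tissue reference means.** The generator sets `R̄_t` from the
   pre-mixing per-tissue fields (for generated phantoms these are known
   exactly). Label means of the mixed maps are contaminated by the rims and
   would bias every interior voxel of small nuclei. For user-supplied data,
   `build_tissue_model` keeps the conventional definition — the mean over
   the binary label mask.

M0 is a per-tissue base value (zero in air and the calcification core, 0.05
in bone) with a 5% very-smooth multiplicative modulation. FA is 0.6 ± 0.1
inside white matter and 0.05 elsewhere; the fiber orientation is a smooth
random unit-vector field, θ its angle to B0 (third axis by default).

What the generator does **not** emulate: cortical folding, true vascular
trees, B1/receive bias, physiological noise, anisotropic voxels. Tests that
pass on this phantom therefore validate the *processing physics* —
unwrapping, background removal, inversion conditioning, partial-volume and
no-signal behaviour — not anatomical robustness of segmentation-driven
methods.

## Forward simulation

The frequency shift is computed in k-space with the Lorentz-corrected unit
dipole `D(k) = 1/3 − k_z²/|k|²`, `D(0) = 0`. The zero-frequency convention
makes the simulated field zero-mean over the padded volume; the absolute
field offset is not an observable, so all field comparisons in the tests are
offset-free. The volume is zero-padded by a factor 2 per axis before the
product and cropped back, suppressing circular-convolution aliasing. For
compactly supported sources doubling the padding changes the brain-interior
field by <0.1%; for the whole-head phantom the air background (χ = 9.2 ppm)
extends to the volume edge, so the problem is inherently FOV-truncated and
pad-2 vs pad-4 differ by a few percent — a property of the problem, not of
the solver.

Shimming is emulated by subtracting the least-squares fit of products of
per-axis Legendre polynomials up to total order 3 over the brain mask. The
optional white-matter microstructure term subtracts
`5·(sin²θ − 2/3)·FA/0.59 + 3` rad/s inside the WM mask (TE-independent,
stored pre-TE-multiplication). The printed form of this correction is
ambiguous in grouping; the default parsing zeroes the anisotropy term at
the magic angle, and a literal left-to-right parsing is selectable — neither
is asserted as ground truth.

The spoiled-GRE signal uses the steady-state expression with a seeded
random 3-D polynomial transceiver phase (total order 2, rescaled to exactly
2π peak-to-peak over the brain). Noise is i.i.d. complex Gaussian with per-
channel σ = max|S₁|/peakSNR (first-echo peak; configurable). Lower-
resolution acquisition is a centred crop of the fftshifted spectrum (DC
sample preserved, mean-preserving rescale), applied to the complex data.
The downsampled ground-truth χ — and only it — is cleaned of Gibbs ringing
by local subvoxel shifts: per axis, each sample considers 41 shifts in
[−0.5, 0.5], scored by the smaller of the left/right total variation
excluding the sample's own adjacent differences (a genuine edge must not
count as oscillation), and the winning shifted value is linearly
interpolated back; samples whose baseline oscillation is below 2% of the
line's largest jump are left untouched, which makes the operation a
near-identity on smooth data and near-idempotent. Axes are processed
independently and averaged.

## Phase processing

Unwrapping is spatial, quality-guided (reliability-sorted region handling,
via scikit-image), applied to inter-echo phase differences — these vary far
less than absolute phase — then integrated across echoes on top of the
unwrapped first echo. The global 2π ambiguity is fixed at the
highest-magnitude voxel. The frequency is a per-voxel weighted line fit
`phase(TE) = φ0 + 2π f·TE` with weights `TE²|S|²` (inverse-variance for
magnitude-weighted phase noise; `|S|²` and uniform are selectable — the
choice is irrelevant for noiseless data and for two echoes). Voxels with no
signal are flagged and set to zero frequency.

Unwrapping inevitably fails around the no-signal calcification, producing
frequency spikes at near-multiples of 1/ΔTE; `repair_field_outliers`
replaces flagged voxels and voxels deviating from their 3×3×3 median by more
than 0.3/ΔTE Hz with the median value. With strong background fields the
outermost mask layers near air cavities are equally unreliable, and the
processing mask is eroded first (3 voxels by default in whole-head runs) —
the standard practice for boundary-phase unreliability.

Background removal solves Laplace's equation on the interior of the
(1-voxel-eroded) mask with Dirichlet values from the measured field, using
the 7-point finite-difference Laplacian and conjugate gradients (the system
is symmetric positive definite; relative tolerance 1e-6, at most 10⁴
iterations, failure raises with the residual). The harmonic solution is the
background estimate; the returned local field is zero outside the mask and
zero-mean over it. LBV error is inherently boundary-concentrated: the local
field's own boundary values are absorbed into the background estimate.

## Inversions and metrics

TKD divides by `D` where `|D| > t` and clamps the inverse filter to
`1/(t·sign D)` elsewhere (the sign-preserving variant; several TKD variants
exist). Closed-form L2 computes `χ(k) = D·F/(D² + λ|G|²)` with the
first-difference gradient spectrum `|G|² = Σ 4 sin²(π k_i)`. Both are linear
operators and invert on the unpadded grid, as applied to measured data.

The metric suite follows the challenge definitions; all RMSE-type scores
are ×100, normalised by the demeaned ground-truth norm over the same mask
(consistent with whole-brain nRMSE values quoted as percentages).
Detrending fits recon against truth with an intercept but compensates only
the slope (configurable to through-origin); the deep-gray linearity metric
uses through-origin regression of the six region means on the prescribed
means (configurable to intercept form). The calcification streak ROI is a
hollow rectangular prism built from the bounding box: inner boundary 2
voxels beyond the box, outer boundary 6 voxels beyond the inner, intersected
with the brain mask. The moment integrates χ over the calcification dilated
by 2 voxels — robust in no-signal regions where voxel-wise comparison is
meaningless. A non-positive detrending slope is flagged and the score
computed without detrending.

## Problem sizes and determinism

The shipped tests and the acceptance script run the full phantom at 128³
(1 mm), its downsampled counterpart at 64³ (2 mm), and use 96³ for the
analytic-sphere oracle and 48³ for smoke tests; these sizes resolve all
structures (smallest nucleus radius 4 voxels) while keeping a complete run
in minutes. Every stochastic stage (phantom texture, transceiver phase,
noise) is driven by an explicit seed, and reruns are bit-identical.

## Known limitations

- The whole-head field depends on the FOV truncation of the air background
  (see above); background-field magnitudes near the sinuses are therefore
  geometry- and FOV-dependent.
- Veins are straight cylinders; partial-volume phase effects at vessels are
  reproduced (biased field estimates after downsampling), but oxygenation
  gradients and flow are not modelled.
- The microstructure term is a first-order, TE-independent approximation;
  hollow-cylinder TE-dependent models and susceptibility anisotropy are out
  of scope.
- Flow, respiration-driven B0 fluctuation, gradient-recalled distortions and
  chemical shift/exchange are deliberately not simulated.
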