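# Methods

## Signal model

Each voxel is modeled as a non-exchanging three-pool mixture of free (CSF),
hindered (extra-axonal) and restricted (intra-axonal) water,

    E(b) = A_f exp(-b D_csf) + A_h exp(-b ĝᵀ D_h ĝ) + A_r Σ_k π_k E_ax(q⊥, R_k),

with all attenuations normalized to 1 at b = 0. The restricted pool is a
population of parallel impermeable cylinders. Perpendicular to the
cylinder axis the attenuation follows the Gaussian phase form

    E_ax(q⊥, R) = exp(-q⊥² R²),

valid in the regime where the measured decay is insensitive to the
gradient pulse duration; `R` is interpreted as the cylinder (axon)
diameter, with a configuration switch (`DiameterGrid(radius_interpretation=True)`)
for the radius convention. Parallel to the axis the intra-axonal water is
Gaussian with a fixed diffusivity D∥ (default 1.7e-3 mm²/s). The
decomposition per volume uses the fiber axis v: cos θ = |ĝ·v|,
q⊥ = q sin θ, b∥ = b cos²θ.

Units are fixed internally: b in s/mm², diffusivities in mm²/s, q in
rad/µm, diameters in µm, coordinates in mm, Δ/δ in ms. With these choices
q²R² is dimensionless and q = γδg and b = q²(Δ − δ/3) convert exactly at
the I/O boundary (γ defaults to the proton value 2.6752218744e8 rad s⁻¹ T⁻¹).

## The tensor prior

A weighted log-linear least-squares tensor is fitted per voxel on shells
with b ≤ 1500 s/mm² (one ordinary pass on log-signal, then one weighted
pass with squared predicted signal as weights; no robust reweighting, so
the fit is deterministic). The high-b shells are excluded because their
decay is visibly non-monoexponential. The tensor supplies

* the fiber axis v (principal eigenvector; sign fixed so the first
  nonzero component is non-negative, making outputs reproducible),
* the FA gate: below FA = 0.05 the axis is considered undefined and a
  gradient-frame fallback axis is used, flagged in `fit_flags`,
* the mean-diffusivity map exported as the extra-axonal diffusivity.

Eigenvalues are clamped at 1e-7 mm²/s and clamping is counted.

## Why the hindered predictor is a fixed-shape prior

Within this model class a cylindrically symmetric hindered tensor sharing
the intra-axonal parallel diffusivity is *exactly* equal to one of the
restricted predictors: exp(-b(D∥cos²θ + D_r sin²θ)) coincides with the
cylinder column at R* = sqrt(D_r (Δ − δ/3)). Two consequences drive the
design:

1. The composite per-voxel tensor cannot serve as the hindered predictor.
   Its radial eigenvalue absorbs restricted decay, so the resulting column
   either swallows essentially the whole measured signal (leaving the
   spectrum to fit residual noise) or pushes hindered water into spurious
   small-diameter weights. On noise-free single-diameter phantoms this
   produced eMAD errors of 1.5–7 µm and undefined eMAD at small
   diameters — the inversion is unidentifiable in that configuration.
2. The hindered predictor is therefore a *prior*: an axially symmetric
   tensor about the DTI axis with fixed physiological eigenvalues,
   axial 1.7e-3 and radial 0.5e-3 mm²/s by default (both configurable in
   `fit_dataset`). Only the axis is estimated per voxel.

The exact twin column still exists (R* ≈ 4.45 µm for the default radial
diffusivity on the HCP timing), so compartment separation ultimately rests
on solver behavior: the active-set NNLS resolves the exact tie in favor of
the hindered column (it carries no smoothness penalty and wins the
gradient tie deterministically), but under noise a smooth bump of spectrum
weight near R* can substitute for the hindered column cheaply. This is why
compartment fractions are weakly identified at clinical SNR while eMAD
degrades gracefully (a mid-caliber bias, ~15% median at SNR 30 for 8–12 µm
axons); it is a property of the Gaussian-cylinder model, not of the
solver.

## Inversion

The per-voxel problem is

    min_w ||A w − y||² + λ² ||L w||²,  w ≥ 0,

with A the n_volumes × (K+2) library (CSF, hindered, K = 160 diameters
from 0.1 to 16.0 µm in 0.1 µm steps), y the signal divided by its mean
over b0 volumes, and L the second-difference operator over the restricted
columns only — the smoothness prior applies to the diameter distribution,
not to the compartment fractions. The problem is solved exactly as plain
NNLS on the augmented system [A; λL], which is deterministic and yields
bit-identical results for identical inputs. Fractions are obtained by
normalizing the solution to unit sum (post-hoc, rather than an equality
constraint in the solver; at the reported tolerance the two are
equivalent). eMAD = Σπ_k R_k / Σπ_k; a volume-weighted variant
(π_k R_k² weights) is available. Voxels with restricted fraction below
0.05 report eMAD as NaN, which keeps noise-driven diameters out of CSF.

λ defaults to 0.1 × the largest singular value of the restricted block,
recomputed per voxel so the scale tracks the library conditioning; a
generalized-cross-validation selector is provided (`gcv_lambda`) but is
not the default, keeping runs deterministic and fast. Noise-free
validation runs use λ = 0: regularization exists to stabilize noisy fits,
and at the default λ a noise-free spectrum spike is deliberately smoothed
(up to ~1 µm of bias), which is the prior working as designed. Broad
(gamma) spectra are the opposite case: many exact unregularized
representations exist, and only the smoothed fit recovers their mean
stably (to ~0.3 µm on the callosal phantom at the defaults).

## Phantoms

The generator produces data with exactly the statistical structure the
model assumes: noise-free signals are fraction-weighted sums of the same
predictor columns the fitting library builds (single-diameter spectra, or
gamma ADDs discretized and renormalized on the grid — the gamma family
following the AxCaliber lineage), with Rician noise
|S + n₁ + i n₂|, n ~ N(0, S₀/SNR), applied at a stated b0 SNR. S₀ = 1000
arbitrary units. All randomness flows from one integer seed.

Default white-matter regions use A_r = A_h = 0.5 and the model's own
hindered and intra-axonal constants, i.e. the phantom emulates tissue that
satisfies the fitting model's assumptions. Passing tests on these phantoms
therefore demonstrate correct inversion of the model, *not* robustness to
real-tissue deviations from it: orientation dispersion, exchange,
non-Gaussian extra-axonal diffusion, a hindered tensor different from the
prior, and gradient-duration dependence of the restricted signal are all
absent from the generator by construction.

Acquisition presets mirror three published multi-shell protocols
(shells 250–5000 s/mm², Δ/δ = 60/15.5; 1000–4000, 45/15; HCP 1000–3000,
43.1/10.6 ms) with deterministic golden-spiral direction sets sized to the
protocols' direction counts (22/62/90 per shell). The direction count is
load-bearing: with only ~30 directions per shell the tensor fit of the
(non-monoexponential) mixture carries a systematic ~0.4° axis bias that
alone costs up to 0.7 µm of eMAD at large diameters; at 90 per shell the
bias is negligible.

The callosal phantom is a midsagittal slab whose five sections carry gamma
ADDs with means genu 3, anterior/mid/posterior body 6/7/6, splenium
3.5 µm — synthetic choices emulating the well-known "small genu/splenium,
large body" caliber pattern, not measured values — with left–right fibers.

## Streamline and connectome layer

Streamline ADD is the mean eMAD over the streamline's *unique* traversed
voxel set (nearest-voxel lookup through the inverse affine; revisits count
once, removing step-length bias), ignoring voxels with undefined eMAD.
Edges bin streamlines by endpoint atlas labels (nearest labeled voxel
within 2 mm, since bare nearest-voxel misses gray-matter borders); edge
weight is the mean ADD of connecting streamlines, with NaN-ADD streamlines
counted but excluded from the average. Self-connections stay on the
diagonal and are excluded from node means. Group averaging pools defined
subject values per edge and applies median-absolute-deviation exclusion at
2.5 robust (1.4826-scaled) units; when MAD = 0 only values equal to the
median are kept. Average-ADD maps drop streamline values below 0.3 µm.

The Witelson-style split assigns each callosal voxel a section by its
fractional anterior–posterior position, boundaries at 1/3, 1/2, 2/3, 4/5,
intervals half-open closed on the anterior side (boundary voxels go
posterior). The AP axis is read from the affine (+y = anterior) unless
given. Section statistics: one-way repeated-measures ANOVA over the five
sections and all ten paired t-tests with Bonferroni correction (p × 10,
capped at 1); identical columns short-circuit to F = 0, p = 1 rather than
a 0/0 ratio.

## Validation problem sizes

The shipped validation uses single-voxel noise-free phantoms per diameter
(2–14 µm), 200-voxel volumes per diameter at SNR 30, and twenty
2×40×2-voxel callosal subjects at SNR 30 — sizes chosen so the complete
suite runs in well under a minute of fitting time on one CPU while keeping
every per-voxel problem at the full protocol dimension (278 volumes × 162
columns for the HCP preset).

## Known limitations

* Compartment fractions are weakly identified at clinical SNR (see the
  twin-column analysis above); eMAD is the robust output.
* A single fiber axis per voxel: in crossing-fiber regions the ADD is
  estimated along the dominant DTI direction only.
* Diameters below ~5 µm compress toward the grid floor at realistic SNR —
  the protocol's sensitivity floor, not a solver failure; diameters near
  the grid ceiling are limited by the gradient amplitude through q_max.
* The hindered prior's fixed eigenvalues are a modeling assumption; real
  tissue whose extra-axonal tensor differs will bias fractions first and
  eMAD second.
* No gradient-duration (van Gelderen full-series) dependence, dispersion,
  exchange or tortuosity terms; the model is deliberately minimal.
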