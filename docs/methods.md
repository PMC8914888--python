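# Methods

`dnqsm` implements a desk-scale quantitative susceptibility mapping (QSM)
analysis of the cerebellar dentate nuclei: a forward-simulated multi-echo
gradient-echo (GRE) acquisition, the reconstruction chain from complex
echoes to referenced susceptibility maps, dentate volume-of-interest (VOI)
morphometry, and the group-level statistics used in dentate iron studies.
Because no real cohort ships with the package, every stage is exercised on
synthetic phantoms whose ground truth is known exactly; this note records
the models, the defaults and why they were chosen, and what the synthetic
results do and do not establish.

## Forward model

**Dipole physics.** A susceptibility distribution χ (stored in ppb)
perturbs the Larmor frequency by

    f(r) = f0 · F⁻¹[ D(k) · F[χ] ],   D(k) = 1/3 − k_z²/|k|²,  D(0) := 0,

with `f0 = 127.728 MHz` (3 T × 42.576 MHz/T) and B0 along the z grid axis
by default. The k-grid is built per axis with `fftfreq(n, d=voxel_size)`,
so anisotropic voxels enter explicitly. Setting D(0)=0 removes the
undefined k=0 term and pins the arbitrary global offset; consequently the
simulated field has zero mean over the grid. The FFT model is validated
against the closed-form external field of a uniformly magnetized sphere
(max relative error < 2% outside 1.5 radii on a 64³ grid; the residual is
periodic-image aliasing).

**Dentate phantom.** Each hemisphere's dentate is a thin corrugated
ellipsoidal shell, open at the dorsal pole (half-angle 40°), mirrored about
the mid-sagittal plane. The shell surface is u = 1 + (A/r(θ,φ))·sin(mθ)·
sin(mφ) in normalized ellipsoidal coordinates (amplitude A = 0.4 mm, m = 6
cycles); wall thickness 1 mm. The wall carries 100 ppb, the enclosed white
matter 20 ppb, surrounding tissue 0 ppb, and a small CSF pocket (radius
1.2 mm, R2* = 5 s⁻¹) sits at each shell centre. Ground-truth DN_sil is the
shell; ground-truth DN_bulk is the filled convex hull of the shell minus
CSF. R2* is piecewise constant (wall 40, interior 25, tissue 20, CSF
5 s⁻¹). No quantitative dentate atlas is emulated — only the features the
analysis depends on (thin corrugated wall, enclosed WM, CSF contamination,
left/right symmetry).

The default grid is 112³ at 0.5 mm (the acquisition's voxel size) with a
brain ellipsoid of 24/24/22 mm radii and shell radii 5.2/6.6/5.6 mm at
±7 mm from the midline. Geometry rationale: the dentate must sit several
millimetres — at least the largest SHARP kernel radius (5 mm) — inside the
brain-mask boundary, as it does in real anatomy; on smaller test grids
where the shell approaches the mask edge, the V-SHARP boundary ring
attenuates the dentate field (measured slope ≈ 0.64–0.73) and biases the
recovered χ far beyond what is seen at realistic depth. The shell size is
at the generous end of dentate volumes so that the silhouette-to-bulk
construction (hull + erosion at 0.5 mm) is well resolved.

**Background field and signal.** The background is harmonic inside the
brain by construction: an order-2 harmonic polynomial (basis x, y, z, xy,
xz, yz, x²−y², y²−z²) plus point dipoles placed outside the brain mask.
The complex signal per echo is S(TE) = s0·exp(−R2*·TE)·exp(i(φ0 + 2π f
TE)) plus i.i.d. complex Gaussian noise (single-coil model); phases are
stored wrapped to (−π, π], half-open at −π. Default echo times are the
four-echo protocol 6.47/17.23/27.99/38.75 ms. Not modelled: parallel-
imaging and partial-Fourier artefacts, motion, flow, coil combination.

**Cohorts.** A two-group design draws per-subject wall χ (group mean
shifted by +39 ppb in patients, between-subject sd 28 ppb), dentate volume
(patients scaled ×0.78, 10% lognormal jitter, plus a 0.4 mm³ per cm³ TIV
component), TIV ~ N(1550, 140²) cm³, ages uniform on 31.6–68.3 years, and
a clinical severity score (SARA, 0–40) generated for patients as a linear
model in standardized volume (negative weight), χ and age with sd-3 noise;
controls get near-zero scores. These magnitudes match published dentate
QSM group contrasts in degenerative ataxia, so the simulated effects are of
realistic size — but the cohort is idealized: no segmentation error, no
registration error, no site effects, and the SARA model is linear by fiat.
Passing statistics on these cohorts demonstrates calibration and power
mechanics, not clinical validity.

## Reconstruction

The chain is denoise → unwrap → combine → SHARP → invert → reference.

* **Denoising** — total-variation smoothing of the real and imaginary
  channels per echo (`strength` = TV weight, 0 = identity). The original
  protocol's spatially adaptive non-local means has no published
  parameters; TV is a documented edge-preserving stand-in and is off by
  default (the synthetic SNR regime does not need it).
* **Unwrapping** — reliability-sorted region unwrapping
  (`skimage.restoration.unwrap_phase`, the Herraez/Abdul-Rahman "best
  path" family), applied per echo inside the brain mask. Each connected
  mask component carries an arbitrary global 2π·k offset, which cancels in
  the frequency-combination step for consistent echoes.
* **Echo combination** — per-echo frequency f_i = φ_i/(2π·TE_i), averaged
  with weights ∝ (magnitude·TE)², the SNR-optimal weighting for a
  mono-exponential GRE signal. A temporal-consistency pass first adds the
  integer number of 2π turns to each echo that best matches the prediction
  from earlier echoes.
* **SHARP (V-SHARP dialect)** — spherical-mean-value (SMV) filtering with
  kernel radii 1–10 voxels: at each voxel the largest sphere that fits
  inside the brain mask is used; the filtered field is deconvolved by the
  largest-radius kernel in k-space, zeroing components where
  |1 − P_R(k)| < 0.01 (the high-pass regularization). The reliability mask
  is the brain eroded by the smallest radius. Harmonic fields are
  eigenfunctions of the SMV operator and are annihilated (measured
  suppression > 99.9% RMS); internal fields are preserved up to the
  high-pass effect. Known limitation: in the ring where smaller kernels
  were used, the single-kernel deconvolution under-restores smooth field
  components — an inherent property of this dialect (radius-matched and
  conjugate-gradient composite-operator deconvolution were evaluated and
  performed worse; the null space of the variable-radius operator contains
  locally harmonic fields, so no single-pass scheme can do better there).
* **Dipole inversion** — k-space division with regularization of the zero
  cone. Default: Tikhonov, χ = F⁻¹[D/(D²+λ)·F[f/f0]] with λ = 1e-5.
  Thresholded k-space division (TKD) is available (`method="tkd"`,
  threshold 0.2). The default and λ were chosen for quantitative fidelity
  of VOI means at the noise levels the phantom models: measured mean-χ
  bias over the true dentate bulk is −4% noiseless and at SNR 40, whereas
  TKD at the conventional 0.2 threshold under-estimates by 15–18% (its
  well-known amplitude bias); λ much below 1e-5 buys no accuracy (the
  residual bias is field-support truncation at the brain boundary, not
  regularization) and amplifies noise.
* **Referencing** — the map is shifted to zero mean susceptibility over
  brain tissue inside the reliability mask, and all values are reported in
  ppb relative to that reference.
* **R2\*** — per-voxel weighted least squares of log|S| on TE with weights
  |S|² ; R2* = −slope, clipped at zero; voxels with any zero magnitude are
  NaN. Noiseless decays are recovered to machine precision; at SNR 50 the
  Rician-floor bias at these echo times is < 5%.

## Dentate VOIs

DN_sil (in a real study: the manually traced silhouette) is taken from the
phantom's ground-truth shell. DN_bulk is derived per hemisphere as:
Delaunay convex hull of the silhouette voxel centers → rasterization
(voxel centre inside or on the hull; boundary-inclusive, verified exactly
against a brute-force half-space test) → one binary erosion with the full
3×3×3 box (out-of-grid neighbours count as background) → removal of voxels
with R2* < 15 s⁻¹ (CSF). The erode-then-filter order follows the
construction's published description; the rasterization rule and the order
were free choices and are fixed here. Hemisphere labels are assigned by
component centroid relative to the brain-mask mid-sagittal plane, with
majority vote and a warning for straddling components. An externally
edited mask can override the automatic DN_bulk, mirroring manual
correction.

Metrics per VOI: volume = voxel count × voxel volume, summed over
hemispheres; mean χ over all VOI voxels; susceptibility mass χ_mass =
(volume in cm³) × (mean χ in ppb), a proxy for total (not concentration
of) iron. The identity χ_mass = volume/1000 · mean χ holds exactly by
construction and is asserted for every computed metric.

## Group statistics

* **Residualization** — volumes are regressed on TIV in controls only
  (v(TIV)); residuals volume − v(TIV) are computed for all subjects and
  standardized by the whole sample's residual sd (sample sd, ddof = 1 — the
  n−1 convention was an open choice and is fixed here).
* **ANCOVA** — OLS of the metric on group + age (type-III F for the group
  term; with the balanced matched design type I and III coincide). Effect
  size: partial η² = SS_effect/(SS_effect + SS_error). Implemented over
  `statsmodels`; cross-checked against `pingouin` in the tests. Type-I
  error is calibrated empirically (5% nominal, measured within [3%, 7%]
  over 2000 null simulations at n = 16 per group).
* **Post hoc** — pairwise tests with Sidak adjustment
  p_adj = 1 − (1−p)^m.
* **Clinical correlations** — "Spearman controlling for age" is read as
  partial correlation on ranks: rank-transform x, y and age, partial out
  the age ranks, t-approximation on n − 3 df.
* **Reliability** — two-way mixed-effects ICC, single-rater consistency
  form ICC(3,1) = (MS_subj − MS_err)/(MS_subj + (k−1)·MS_err); the
  absolute-agreement variant is available via a flag.
* **Descriptives** — Welch (unequal-variance) t-tests for demographics.

## Voxelwise statistics

Susceptibility maps are smoothed with a 1 mm FWHM Gaussian (σ =
FWHM/(2√(2 ln 2)) per axis, converted to voxels) and compared voxelwise
inside a dentate analysis mask with the GLM dep ~ group + age. Inference
uses threshold-free cluster enhancement, TFCE(v) = Σ_h e(h,v)^E · h^H · dh
with E = 0.5, H = 2, 26-connectivity, and dh = max(stat)/n_steps
(n_steps = 100 by default; the null calibration uses 50 steps, which
changes the integral by < 2% while halving cost). Family-wise error is
controlled by the permutation distribution of the maximum TFCE statistic;
age is handled by Freedman–Lane residual permutation (fit the age-only
model, permute its residuals, re-add the fitted part, recompute the full
GLM). Inference is one-sided per contrast, with the opposite contrast run
separately (the red/blue convention of voxelwise difference maps); only
the positive part of the t-map is enhanced inside the permutation loop.
Corrected p-values have floor 1/(n_perm + 1). The realized FWE under the
null measures 3.5% at nominal 5% (200 datasets × 200 permutations, 16³
grids, n = 8 per group) — permutation max-statistic tests are slightly
conservative at this permutation count.

Score–map associations (e.g. SARA) use the same machinery with the score
as regressor; the age-residualized score is permuted.

## Orchestration

`run_pipeline` executes simulate → reconstruct → voi → stats → voxelwise
from one validated configuration. Every stage writes its outputs with
SHA-256 checksums into a JSON run report; re-runs skip stages whose
outputs are intact unless forced, and a corrupted file triggers
recomputation. One global seed is expanded into independent per-stage
seeds via `numpy.random.SeedSequence([seed, stage_index])`, so stages can
be re-run in isolation while the end-to-end run stays bit-reproducible
(same config + seed ⇒ identical cohort and metric tables). The bundled
demo configuration uses 6 subjects per group on a 48³ grid with reduced
SHARP radii — sized for orchestration and smoke-testing, not for
quantitative accuracy (at 48³ the dentate sits near the mask boundary, so
reconstructed χ is uniformly attenuated; group contrasts survive).

## Numerical choices and degenerate inputs

Phase convention (−π, π] with −π mapped to +π; spherical SMV kernels
rasterized by voxel-centre-in-radius and normalized to unit sum; FFT
convolution with periodic wrap accepted because the phantom keeps sources
away from the grid edge; hull membership uses `Delaunay.find_simplex` with
a 1e-9 inclusive tolerance, matched by the brute-force oracle; ties in
hemisphere assignment go to the right; empty VOIs yield NaN metrics with a
warning rather than an error; single-echo frequency estimation returns
φ/(2πTE) with a warning; constant inputs to correlations and sd-zero
standardization raise.

## Limitations

The phantom's brain is a bare ellipsoid (no skull, sinuses or veins), the
noise is single-coil Gaussian, and the geometry compresses a head into a
56 mm field of view. SHARP fidelity near the mask boundary is
intrinsically limited (see above), so absolute χ in structures close to
the brain edge is biased low; the dentate default sits deep enough that
this bias is ≈ −4%. No spatial normalization, Jacobian modulation or
whole-cerebellum morphometry is implemented; the voxelwise analysis is
mask-restricted by design. Statistical calibration is demonstrated for
the simulated designs only.
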