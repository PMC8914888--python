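# dnqsm — quantitative susceptibility mapping of the dentate nuclei

`dnqsm` is a self-contained pipeline for studying iron-related
susceptibility changes of the cerebellar dentate nuclei with quantitative
susceptibility mapping (QSM). It is aimed at method developers and
neuroimaging statisticians who need the full analysis chain — from
multi-echo gradient-echo (GRE) complex data to dentate volumes-of-interest
(VOIs) and group statistics — with exact ground truth for every stage.
Since clinical dentate cohorts are rarely shareable, the package includes a
first-class synthetic-data module: corrugated dentate-shell phantoms with
known susceptibility, harmonic background fields, realistic multi-echo
signal synthesis, and two-group cohorts with controllable effect sizes.

## What it computes

**Reconstruction.** The susceptibility χ (in ppb) is related to the
measured Larmor-frequency shift f by the dipole convolution
f = f0 · F⁻¹[D(k)·F[χ]] with D(k) = 1/3 − k_z²/|k|². The chain inverts
this: 3D best-path phase unwrapping per echo, division by 2π·TE_i and
SNR-weighted echo combination, SHARP background removal (spherical-mean
kernels of radius 1–10 voxels, high-pass regularization 0.01), regularized
dipole inversion (Tikhonov default, TKD available), zero-referencing to
mean brain tissue, and log-linear R2* mapping.

**Morphometry.** From the traced dentate silhouette DN_sil, the iron-rich
bulk DN_bulk is built per hemisphere as the rasterized Delaunay convex
hull, eroded with a 3×3×3 box, with CSF voxels (R2* < 15 s⁻¹) removed.
Per subject the package reports volume (mm³), mean χ (ppb) and the
susceptibility mass χ_mass = volume(cm³) · mean χ (ppb·cm³).

**Statistics.** Head-size correction residualizes volumes against the
control-only v(TIV) regression; group effects are tested with ANCOVA
(group + age) and partial η², Sidak-adjusted post hocs, age-controlled
Spearman correlations with clinical severity (SARA), and two-way
mixed-effects ICC for rater reliability. Voxelwise comparisons use 1 mm
Gaussian smoothing, a per-voxel GLM, threshold-free cluster enhancement
(TFCE) and family-wise error control by permutation of the maximum
statistic (Freedman–Lane).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from dnqsm.phantom import PhantomSpec, make_dentate_phantom, synthesize_echoes
from dnqsm.recon import reconstruct_chi, fit_r2star
from dnqsm.voi import build_dn_bulk, voi_metrics

spec = PhantomSpec(noise_sigma=0.025)          # SNR 40
truth = make_dentate_phantom(spec)
s0 = np.where(truth.brain_mask, spec.s0, 0.0)
echoes = synthesize_echoes(truth.field_true_hz, s0, truth.r2star_true,
                           noise_sigma=spec.noise_sigma, seed=spec.seed,
                           voxel_size_mm=spec.voxel_size_mm)

chi, tissue, _ = reconstruct_chi(echoes, truth.brain_mask)
r2star = fit_r2star(echoes, truth.brain_mask)

dn_bulk = build_dn_bulk(truth.dn_sil_true, r2star)
m_sil = voi_metrics(chi, truth.dn_sil_true)
m_bulk = voi_metrics(chi, dn_bulk)
print(f"DN_sil:  volume {m_sil.volume_mm3:7.1f} mm^3   "
      f"mean chi {m_sil.mean_chi_ppb:5.1f} ppb   "
      f"chi_mass {m_sil.chi_mass_ppb_cm3:5.1f} ppb*cm^3")
print(f"DN_bulk: volume {m_bulk.volume_mm3:7.1f} mm^3   "
      f"mean chi {m_bulk.mean_chi_ppb:5.1f} ppb   "
      f"chi_mass {m_bulk.chi_mass_ppb_cm3:5.1f} ppb*cm^3")
```

Output:

```
DN_sil:  volume   744.5 mm^3   mean chi  96.2 ppb   chi_mass  71.6 ppb*cm^3
DN_bulk: volume  1376.0 mm^3   mean chi  26.3 ppb   chi_mass  36.3 ppb*cm^3
```

The silhouette wall was simulated at 100 ppb and is recovered at 96.2 ppb
after referencing to mean brain tissue — the combined effect of inversion
regularization and the reference offset. DN_bulk is larger in volume but
lower in mean χ: the box erosion that stabilizes the hull also trims the
thin high-χ wall, so the bulk average is dominated by the enclosed white
matter (20 ppb in this phantom). The mean reconstructed χ over the
*ground-truth* bulk is 44.7 ppb against a true 46.3 ppb (−3.4%).

A full cohort run (simulate → reconstruct → voi → stats → voxelwise) is
one command:

```bash
dnqsm run --demo --workdir demo_run --seed 1
```

which writes per-subject NIfTI volumes, `voi_metrics.tsv`, a JSON/text
statistics report and voxelwise t/TFCE/p maps, with per-stage checksums in
`report.json` (intact stages are skipped on re-runs).

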