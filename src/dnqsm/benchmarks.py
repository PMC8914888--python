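"""Self-contained validation benchmarks for the whole pipeline.

Each function regenerates its inputs from scratch (phantoms, simulated
cohorts, noise) and measures one quantitative property of the
implementation against an independent oracle: closed-form physics,
brute-force geometry, or Monte-Carlo calibration.  They power both the
validation test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from dnqsm.containers import ChiMap, DNMask, EchoSeries, FrequencyMap, R2StarMap
from dnqsm.phantom import (
    PhantomSpec,
    CohortSpec,
    analytic_sphere_field,
    forward_field,
    make_cohort,
    make_dentate_phantom,
    make_sphere_chi,
    synthesize_echoes,
)
from dnqsm.recon import (
    SharpConfig,
    fit_r2star,
    reconstruct_chi,
    sharp_remove_background,
    unwrap_phase_3d,
)
from dnqsm.stats import ancova, residualize, sidak_adjust
from dnqsm.voi import build_dn_bulk, rasterize_hull, voi_metrics
from dnqsm.voxelwise import TfceConfig, permutation_fwe, tfce_enhance

__all__ = [
    "sphere_dipole_accuracy",
    "unwrap_ramp_accuracy",
    "sharp_performance",
    "chi_recovery",
    "r2star_accuracy",
    "bulk_geometry",
    "chi_mass_identity",
    "residualization_calibration",
    "ancova_type1_rate",
    "sidak_worked_value",
    "tfce_accuracy",
    "fwe_null_calibration",
]


def _spawn(seed: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


# -- forward physics -------------------------------------------------------

def sphere_dipole_accuracy() -> dict:
    """FFT dipole field of a uniform sphere vs the closed-form solution.

    64³ grid at 0.5 mm; the error is the maximum deviation in the shell
    1.5a <= r <= 3a, normalized by the peak analytic field there.
    """
    shape, v, a = (64, 64, 64), 0.5, 3.0
    chi = make_sphere_chi(shape, v, (0, 0, 0), a, 100.0)
    f = forward_field(chi, v)
    fa = analytic_sphere_field(shape, v, (0, 0, 0), a, 100.0)
    ax = (np.arange(64) - 31.5) * v
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(gx**2 + gy**2 + gz**2)
    region = (r >= 1.5 * a) & (r <= 3.0 * a)
    err = np.abs(f - fa)[region].max() / np.abs(fa)[region].max()
    return {"max_rel_err_pct": 100.0 * err, "n": int(region.sum())}


def unwrap_ramp_accuracy() -> dict:
    """Recovery of a wrapped 6π linear ramp, modulo one global 2π·k."""
    ramp = np.linspace(0, 6 * np.pi, 32)[:, None, None] * np.ones((32, 16, 16))
    wrapped = np.angle(np.exp(1j * ramp))
    out = unwrap_phase_3d(wrapped)
    offset = out - ramp
    k = np.round(offset.flat[0] / (2 * np.pi))
    resid = np.abs(offset - 2 * np.pi * k)
    return {"max_err_rad": float(resid.max()), "n": int(ramp.size)}


def sharp_performance() -> dict:
    """Harmonic-background suppression and internal-field fidelity of SHARP.

    64³ brain ellipsoid; the background is an order-2 harmonic polynomial
    plus two external point dipoles, the internal field comes from a compact
    spherical source at the brain centre.  Both are processed separately with
    the default 10-radius configuration.
    """
    shape, v = (64, 64, 64), 1.0
    ax = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    brain = (gx / 26.0) ** 2 + (gy / 26.0) ** 2 + (gz / 24.0) ** 2 <= 1.0
    # harmonic background: polynomial + external dipole sources
    bg = 0.05 * gx + (gx**2 - gy**2) / 250.0 + 0.03 * gy * gz / 10.0
    for pos, m in (((30.0, 28.0, 26.0), 3.0e4), ((-29.0, -28.0, -25.0), -2.5e4)):
        dx, dy, dz = gx - pos[0], gy - pos[1], gz - pos[2]
        r2 = np.maximum(dx**2 + dy**2 + dz**2, 1.0)
        bg += m * (3.0 * dz**2 / r2 - 1.0) / r2**1.5
    internal = forward_field(make_sphere_chi(shape, v, (0, 0, 0), 4.0, 100.0), v)

    cfg = SharpConfig()
    t_bg = sharp_remove_background(FrequencyMap(bg, brain, v), brain, cfg)
    t_int = sharp_remove_background(FrequencyMap(internal, brain, v), brain, cfg)
    rel = t_bg.reliability_mask
    supp = 1.0 - np.sqrt(np.mean(t_bg.data_hz[rel] ** 2) / np.mean(bg[rel] ** 2))
    corr = np.corrcoef(t_int.data_hz[rel], internal[rel])[0, 1]
    return {
        "background_suppression_pct": 100.0 * float(supp),
        "internal_field_corr": float(corr),
        "n": int(rel.sum()),
    }


# -- reconstruction --------------------------------------------------------

def chi_recovery(seed: int = 0) -> dict:
    """End-to-end susceptibility recovery on the default dentate phantom.

    The full chain (synthesis → unwrap → combine → SHARP → inversion →
    referencing) is run noiseless and at SNR 40; the error is the relative
    deviation of the mean reconstructed χ over the true DN_bulk from the
    (identically referenced) ground truth.
    """
    gt = make_dentate_phantom(PhantomSpec())
    brain = gt.brain_mask
    bulk = gt.dn_bulk_true.mask
    s0 = np.where(brain, 1.0, 0.0)
    out = {}
    for label, sigma in (("noiseless", 0.0), ("snr40", 1.0 / 40.0)):
        ech = synthesize_echoes(gt.field_true_hz, s0, gt.r2star_true,
                                noise_sigma=sigma, seed=seed, voxel_size_mm=0.5)
        chi, tissue, _ = reconstruct_chi(ech, brain)
        rel = tissue.reliability_mask
        truth = gt.chi.data_ppb - gt.chi.data_ppb[rel].mean()
        err = chi.data_ppb[bulk].mean() / truth[bulk].mean() - 1.0
        out[f"{label}_err_pct"] = 100.0 * float(err)
    out["n"] = int(bulk.sum())
    return out


def r2star_accuracy(seed: int = 0) -> dict:
    """R2* fitting: exactness on noiseless decay, bias at SNR 50."""
    tes = np.array([0.00647, 0.01723, 0.02799, 0.03875])
    mags = np.exp(-20.0 * tes)[:, None, None, None] * np.ones((4, 5, 5, 5))
    ech = EchoSeries(mags, np.zeros_like(mags), tes, 1.0)
    exact_err = float(np.abs(fit_r2star(ech).data - 20.0).max())

    rng = np.random.default_rng(seed)
    n = 1000
    sig = np.exp(-15.0 * tes)[:, None]
    noisy = np.abs(sig + (rng.standard_normal((4, n))
                          + 1j * rng.standard_normal((4, n))) / 50.0)
    ech = EchoSeries(noisy.reshape(4, n, 1, 1), np.zeros((4, n, 1, 1)), tes, 1.0)
    bias = (np.nanmean(fit_r2star(ech).data) - 15.0) / 15.0
    return {"noiseless_abs_err": exact_err, "snr50_bias_pct": 100.0 * float(bias),
            "n": n}


# -- VOI geometry ----------------------------------------------------------

def _brute_force_hull(points, grid_shape):
    hull = ConvexHull(points)
    eq = hull.equations
    axes = [np.arange(n) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    inside = np.all(pts @ eq[:, :3].T + eq[:, 3] <= 1e-9, axis=1)
    return inside.reshape(grid_shape)


def _brute_force_erosion(mask):
    nx, ny, nz = mask.shape
    out = np.zeros_like(mask)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                ok = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            a, b, c = i + di, j + dj, k + dk
                            if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) \
                                    or not mask[a, b, c]:
                                ok = False
                out[i, j, k] = ok
    return out


def bulk_geometry(seed: int = 0) -> dict:
    """DN_bulk construction vs brute-force geometric oracles.

    Hull rasterization is compared voxel-by-voxel with a half-space test on
    32³ grids; the box erosion with an explicit 27-neighborhood check; the
    CSF rule by counting DN_bulk voxels below the R2* cutoff on the default
    phantom, where the Dice overlap with the ground-truth bulk is also
    measured.
    """
    rng = np.random.default_rng(seed)
    hull_mismatch = 0
    for _ in range(5):
        pts = rng.uniform(3, 28, size=(25, 3))
        pts = np.vstack([pts, np.round(pts[:4])])
        got = rasterize_hull(pts, (32, 32, 32))
        ref = _brute_force_hull(pts, (32, 32, 32))
        hull_mismatch += int(np.sum(got != ref))

    erosion_mismatch = 0
    for _ in range(3):
        blob = ndimage.binary_dilation(rng.random((18, 18, 18)) > 0.97,
                                       iterations=3)
        got = ndimage.binary_erosion(blob, structure=np.ones((3, 3, 3)),
                                     border_value=0)
        erosion_mismatch += int(np.sum(got != _brute_force_erosion(blob)))

    gt = make_dentate_phantom(PhantomSpec())
    r2s = R2StarMap(gt.r2star_true, np.ones_like(gt.r2star_true), 0.5)
    bulk = build_dn_bulk(gt.dn_sil_true, r2s)
    low_r2s = int(np.sum(bulk.mask & (gt.r2star_true < 15.0)))
    truth = gt.dn_bulk_true.mask
    dice = 2.0 * np.sum(bulk.mask & truth) / (bulk.mask.sum() + truth.sum())
    return {
        "hull_mismatch_voxels": hull_mismatch,
        "erosion_mismatch_voxels": erosion_mismatch,
        "bulk_voxels_below_r2star_cutoff": low_r2s,
        "dice_vs_truth": float(dice),
        "n": int(bulk.mask.sum()),
    }


def chi_mass_identity(seed: int = 0) -> dict:
    """Susceptibility-mass identity chi_mass = volume/1000 * mean_chi."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(20):
        labels = (rng.random((16, 16, 16)) > 0.6).astype(np.int16)
        labels[labels > 0] = rng.integers(1, 3, int(labels.sum()))
        chi = ChiMap(rng.normal(50, 20, (16, 16, 16)), 0.5)
        m = voi_metrics(chi, DNMask(labels, "bulk", 0.5))
        dev = abs(m.chi_mass_ppb_cm3 - m.volume_mm3 / 1000.0 * m.mean_chi_ppb)
        worst = max(worst, dev / max(abs(m.chi_mass_ppb_cm3), 1e-12))
    return {"max_rel_dev": worst, "n": 20}


# -- statistics ------------------------------------------------------------

def residualization_calibration(seed: int = 0, n_sims: int = 100) -> dict:
    """Control-residual centering and recovery of the volume–TIV slope.

    Simulated cohorts (16 patients / 16 controls) are generated with the
    default design; per cohort the control-only fit's 95% confidence
    interval for the slope is checked for coverage of the generating value.
    """
    seeds = _spawn(seed, n_sims)
    spec = PhantomSpec()
    covered = 0
    worst_mean = 0.0
    true_slope = CohortSpec().volume_tiv_slope
    from scipy import stats as sps

    for s in seeds:
        table, _ = make_cohort(CohortSpec(seed=s), spec)
        vols = table.true_bulk_volume_mm3.to_numpy()
        tivs = table.tiv_cm3.to_numpy()
        is_control = (table.group == "control").to_numpy()
        z, model = residualize(vols, tivs, is_control)
        raw = vols - model.predict(tivs)
        worst_mean = max(worst_mean, abs(raw[is_control].mean()))
        t_c, v_c = tivs[is_control], vols[is_control]
        resid_c = v_c - model.predict(t_c)
        n_c = is_control.sum()
        se = np.sqrt(np.sum(resid_c**2) / (n_c - 2) / np.sum((t_c - t_c.mean()) ** 2))
        half = sps.t.ppf(0.975, n_c - 2) * se
        if abs(model.slope - true_slope) <= half:
            covered += 1
    return {
        "control_resid_mean_abs_max": worst_mean,
        "slope_ci_coverage_pct": 100.0 * covered / n_sims,
        "n": n_sims,
    }


def ancova_type1_rate(seed: int = 0, n_sims: int = 2000, n_per_group: int = 16) -> dict:
    """Empirical type-I error of the ANCOVA group test at alpha = 0.05."""
    rng = np.random.default_rng(seed)
    group = np.array(["patient"] * n_per_group + ["control"] * n_per_group)
    hits = 0
    for _ in range(n_sims):
        dep = rng.standard_normal(2 * n_per_group)
        age = rng.uniform(30, 70, 2 * n_per_group)
        if ancova(dep, group, age)["group"]["p"] < 0.05:
            hits += 1
    return {"rate_pct": 100.0 * hits / n_sims, "n": n_sims}


def sidak_worked_value() -> dict:
    """Sidak adjustment of p = 0.01 over 15 comparisons."""
    return {"p_adjusted": float(sidak_adjust([0.01], 15)[0]), "n": 15}


def tfce_accuracy(seed: int = 0) -> dict:
    """TFCE vs the closed-form integral and brute-force monotonicity."""
    m = np.zeros((12, 12, 12))
    m[4:8, 4:8, 4:8] = 2.0
    out = tfce_enhance(m, TfceConfig(n_steps=100))
    expected = np.sqrt(64.0) * 2.0**3 / 3.0
    rel_err = abs(out[5, 5, 5] - expected) / expected

    rng = np.random.default_rng(seed)
    cfg = TfceConfig(dh=0.05)
    violations = 0
    for _ in range(20):
        stat = rng.random((8, 8, 8)) * 2.0
        base = tfce_enhance(stat, cfg)
        stat2 = stat.copy()
        stat2[tuple(rng.integers(0, 8, 3))] += 0.5
        bumped = tfce_enhance(stat2, cfg)
        violations += int(np.any(bumped < base - 1e-9))
    return {"closed_form_rel_err_pct": 100.0 * float(rel_err),
            "monotonicity_violations": violations, "n": 20}


def fwe_null_calibration(seed: int = 0, n_datasets: int = 200,
                         n_perm: int = 200, n_per_group: int = 8) -> dict:
    """Family-wise error of the TFCE permutation test under the null.

    Independent null datasets (Gaussian maps on a 16³ grid, random ages) are
    tested at FWE alpha = 0.05; the fraction with any significant voxel
    estimates the realized family-wise error rate.
    """
    rng = np.random.default_rng(seed)
    cfg = TfceConfig(n_steps=50)
    hits = 0
    for _ in range(n_datasets):
        pats = rng.standard_normal((n_per_group, 16, 16, 16))
        ctrls = rng.standard_normal((n_per_group, 16, 16, 16))
        ages = rng.uniform(30, 70, 2 * n_per_group)
        res = permutation_fwe(pats, ctrls, ages, n_perm=n_perm, cfg=cfg,
                              seed=int(rng.integers(2**31)))
        hits += bool((res.p_fwe[res.mask] < 0.05).any())
    return {"rate_pct": 100.0 * hits / n_datasets, "n": n_datasets}
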