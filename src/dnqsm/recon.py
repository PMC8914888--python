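"""QSM reconstruction: denoising, unwrapping, SHARP, dipole inversion, R2*.

The processing chain mirrors the standard multi-echo gradient-echo recipe:
complex denoising, per-echo 3D phase unwrapping, division by 2·pi·TE and
SNR-weighted combination into a frequency map, multi-radius SHARP (SMV)
background removal, regularized dipole inversion and zero-referencing to
mean brain tissue.  All fields are in Hz internally; susceptibility is ppb
at the API boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_tv_chambolle, unwrap_phase

from dnqsm.config import F0_HZ
from dnqsm.containers import (
    ChiMap,
    EchoSeries,
    FrequencyMap,
    R2StarMap,
    TissueFieldMap,
    as_voxel_size,
)
from dnqsm.phantom import dipole_kernel

__all__ = [
    "SharpConfig",
    "InversionConfig",
    "denoise_complex",
    "unwrap_phase_3d",
    "echoes_to_frequency",
    "sharp_remove_background",
    "invert_dipole",
    "reference_chi",
    "fit_r2star",
    "reconstruct_chi",
]


@dataclass
class SharpConfig:
    """Multi-radius SHARP (V-SHARP style) background-removal parameters."""

    radii_voxels: tuple = tuple(range(1, 11))
    highpass_threshold: float = 0.01

    def validate(self) -> None:
        r = np.asarray(self.radii_voxels, dtype=float)
        if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii_voxels must be positive and strictly increasing")
        if not 0.0 < self.highpass_threshold < 1.0:
            raise ValueError("highpass_threshold must lie in (0, 1)")


@dataclass
class InversionConfig:
    """Dipole-inversion settings (thresholded k-space division or Tikhonov)."""

    method: str = "tikhonov"
    tkd_threshold: float = 0.2
    tikhonov_lambda: float = 1e-5
    b0_direction: tuple = (0.0, 0.0, 1.0)

    def validate(self) -> None:
        if self.method not in ("tkd", "tikhonov"):
            raise ValueError("method must be 'tkd' or 'tikhonov'")
        if not 0.0 < self.tkd_threshold < 2.0 / 3.0:
            raise ValueError("tkd_threshold must lie in (0, 2/3)")
        if self.tikhonov_lambda <= 0:
            raise ValueError("tikhonov_lambda must be > 0")


# --------------------------------------------------------------------------
# denoising
# --------------------------------------------------------------------------

def denoise_complex(echoes: EchoSeries, strength: float = 0.0) -> EchoSeries:
    """Edge-preserving denoising of the complex data.

    Total-variation smoothing is applied to the real and imaginary channels
    of every echo independently; ``strength`` is the TV weight and 0 is the
    identity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return EchoSeries(
            echoes.magnitude.copy(), echoes.phase.copy(), echoes.tes_s, echoes.voxel_size_mm
        )
    mags = np.empty_like(echoes.magnitude)
    phases = np.empty_like(echoes.phase)
    for i in range(echoes.n_echoes):
        cplx = echoes.magnitude[i] * np.exp(1j * echoes.phase[i])
        re = denoise_tv_chambolle(cplx.real, weight=strength)
        im = denoise_tv_chambolle(cplx.imag, weight=strength)
        mags[i] = np.hypot(re, im)
        ph = np.arctan2(im, re)
        ph[ph == -np.pi] = np.pi
        phases[i] = ph
    return EchoSeries(mags, phases, echoes.tes_s, echoes.voxel_size_mm)


# --------------------------------------------------------------------------
# unwrapping
# --------------------------------------------------------------------------

def unwrap_phase_3d(
    wrapped_phase: np.ndarray,
    mask: Optional[np.ndarray] = None,
    quality_source: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Spatially unwrap a wrapped 3D phase volume inside a mask.

    Uses reliability-sorted ("best path") region unwrapping; each connected
    mask component is internally consistent but carries its own arbitrary
    global 2·pi·k offset.  ``quality_source`` is accepted for interface
    compatibility (the reliability ordering is derived from the phase
    itself).  Voxels outside the mask are returned as zero.
    """
    wrapped_phase = np.asarray(wrapped_phase, dtype=float)
    if mask is None:
        mask = np.ones(wrapped_phase.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    marr = np.ma.array(wrapped_phase, mask=~mask)
    out = unwrap_phase(marr)
    return np.where(mask, np.ma.filled(out, 0.0), 0.0)


# --------------------------------------------------------------------------
# frequency estimation
# --------------------------------------------------------------------------

def echoes_to_frequency(
    unwrapped_phases: np.ndarray,
    tes_s: Sequence[float],
    magnitudes: np.ndarray,
    mask: Optional[np.ndarray] = None,
    voxel_size_mm=1.0,
    temporal_consistency: bool = True,
) -> FrequencyMap:
    """Combine per-echo unwrapped phases into one Larmor-frequency map (Hz).

    Each echo's phase is divided by 2·pi·TE_i; the per-echo frequencies are
    averaged with SNR-optimal weights proportional to (magnitude·TE)²,
    normalized per voxel.  A temporal consistency pass first shifts each
    echo's phase by the integer multiple of 2·pi that best matches the
    prediction extrapolated from the earlier echoes, so all echoes share one
    wrapping convention.
    """
    phases = np.asarray(unwrapped_phases, dtype=float).copy()
    mags = np.asarray(magnitudes, dtype=float)
    tes = np.asarray(tes_s, dtype=float)
    if phases.ndim != 4 or phases.shape[0] != tes.size:
        raise ValueError("expected (n_echoes, nx, ny, nz) phases matching tes_s")
    if mask is None:
        mask = np.ones(phases.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    single = tes.size == 1
    if single:
        warnings.warn("single echo: frequency is phase/(2 pi TE) without combination")

    if temporal_consistency and not single:
        w = (mags[0] * tes[0]) ** 2
        f_est = phases[0] / (2 * np.pi * tes[0])
        w_sum = w.copy()
        f_acc = w * f_est
        for i in range(1, tes.size):
            pred = 2 * np.pi * np.where(w_sum > 0, f_acc / np.maximum(w_sum, 1e-30), 0.0) * tes[i]
            k = np.round((pred - phases[i]) / (2 * np.pi))
            phases[i] = phases[i] + 2 * np.pi * k
            wi = (mags[i] * tes[i]) ** 2
            w_sum += wi
            f_acc += wi * phases[i] / (2 * np.pi * tes[i])

    freqs = phases / (2 * np.pi * tes[:, None, None, None])
    weights = (mags * tes[:, None, None, None]) ** 2
    wsum = weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        combined = np.where(wsum > 0, (weights * freqs).sum(axis=0) / np.maximum(wsum, 1e-30), 0.0)
    combined[~mask] = 0.0
    return FrequencyMap(combined, mask, voxel_size_mm, single_echo=single)


# --------------------------------------------------------------------------
# SHARP background removal
# --------------------------------------------------------------------------

def _sphere_offsets(radius: float):
    """Boolean footprint of a sphere rasterized by voxel-center-in-radius."""
    n = int(np.floor(radius))
    ax = np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (gx**2 + gy**2 + gz**2) <= radius**2 + 1e-9


def _sphere_kernel_k(radius: float, grid_shape) -> np.ndarray:
    """k-space transform of the normalized spherical-mean kernel."""
    foot = _sphere_offsets(radius)
    kern = np.zeros(grid_shape)
    n = foot.shape[0] // 2
    idx = np.argwhere(foot) - n
    kern[tuple((idx % np.asarray(grid_shape)).T)] = 1.0
    kern /= kern.sum()
    return np.fft.fftn(kern).real


def sharp_remove_background(
    freq: FrequencyMap, brain_mask: np.ndarray, cfg: Optional[SharpConfig] = None
) -> TissueFieldMap:
    """Remove harmonic background fields by multi-radius SMV filtering.

    At each voxel the largest spherical-mean (SMV) kernel that fits entirely
    inside the brain mask is applied as (delta - rho_r) * f; the filtered
    field is then deconvolved by the largest-radius kernel in k-space,
    zeroing frequencies where |1 - P_R(k)| falls below the high-pass
    threshold.  Harmonic fields (external sources) are eigenfunctions of the
    SMV operator with eigenvalue 1 and are annihilated; internal (tissue)
    fields survive up to the high-pass effect.  The output is zero outside
    the reliability mask (voxels where the smallest kernel fits).
    """
    cfg = cfg or SharpConfig()
    cfg.validate()
    brain_mask = np.asarray(brain_mask, dtype=bool)
    shape = freq.data_hz.shape
    radii = list(cfg.radii_voxels)

    fits = {}
    for r in radii:
        fits[r] = ndimage.binary_erosion(
            brain_mask, structure=_sphere_offsets(r), border_value=0
        )
    r_max = radii[-1]
    if not fits[r_max].any():
        raise ValueError(
            f"the largest SMV kernel (radius {r_max} voxels) fits nowhere inside "
            "the brain mask; use smaller radii"
        )
    reliability = fits[radii[0]]

    f_masked = np.where(brain_mask, freq.data_hz, 0.0)
    f_k = np.fft.fftn(f_masked)
    filtered = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    for r in reversed(radii):
        smv = np.fft.ifftn(_sphere_kernel_k(r, shape) * f_k).real
        sel = fits[r] & ~assigned
        filtered[sel] = f_masked[sel] - smv[sel]
        assigned |= sel

    c_k = 1.0 - _sphere_kernel_k(r_max, shape)
    keep = np.abs(c_k) >= cfg.highpass_threshold
    t_k = np.fft.fftn(np.where(reliability, filtered, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_k = np.where(keep, t_k / np.where(keep, c_k, 1.0), 0.0)
    tissue = np.fft.ifftn(t_k).real
    tissue[~reliability] = 0.0
    return TissueFieldMap(tissue, reliability, brain_mask, freq.voxel_size_mm)


# --------------------------------------------------------------------------
# dipole inversion and referencing
# --------------------------------------------------------------------------

def invert_dipole(
    tissue: TissueFieldMap,
    cfg: Optional[InversionConfig] = None,
    f0_hz: float = F0_HZ,
) -> ChiMap:
    """Invert the tissue field (Hz) to susceptibility (ppb).

    chi = IFFT(FFT(field/f0) / D(k)) with the ill-posed cone regularized
    either by thresholded k-space division (TKD: |D| < t replaced by
    sign(D)·t) or by Tikhonov damping D/(D² + lambda); the result is masked
    to the reliability mask.
    """
    cfg = cfg or InversionConfig()
    cfg.validate()
    d = dipole_kernel(tissue.data_hz.shape, tissue.voxel_size_mm, cfg.b0_direction)
    phase_k = np.fft.fftn(tissue.data_hz / f0_hz)
    if cfg.method == "tkd":
        t = cfg.tkd_threshold
        sign = np.where(d >= 0, 1.0, -1.0)
        d_reg = np.where(np.abs(d) < t, sign * t, d)
        chi = np.fft.ifftn(phase_k / d_reg).real
    else:
        lam = cfg.tikhonov_lambda
        chi = np.fft.ifftn(phase_k * d / (d**2 + lam)).real
    chi_ppb = chi * 1e9
    chi_ppb[~tissue.reliability_mask] = 0.0
    return ChiMap(chi_ppb, tissue.voxel_size_mm)


def reference_chi(chi: ChiMap, reference_mask: np.ndarray) -> ChiMap:
    """Zero-reference a χ map to its mean over ``reference_mask``."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    mean = chi.data_ppb[reference_mask].mean()
    out = chi.data_ppb - mean
    return ChiMap(out, chi.voxel_size_mm, reference_mask=reference_mask)


# --------------------------------------------------------------------------
# R2* mapping
# --------------------------------------------------------------------------

def fit_r2star(echoes: EchoSeries, mask: Optional[np.ndarray] = None) -> R2StarMap:
    """Per-voxel weighted log-linear R2* fit over the echo train.

    log|S| is regressed on TE with weights |S|² (the noise-optimal weighting
    for log-transformed magnitudes); R2* = -slope, negative slopes clipped
    to 0.  Voxels with any zero magnitude are excluded (NaN).  The fit
    quality is the weighted R² of the log-linear model.
    """
    if echoes.n_echoes < 3:
        raise ValueError("need at least 3 echoes for a slope with quality estimate")
    shape = echoes.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    s = echoes.magnitude.reshape(echoes.n_echoes, -1)
    te = echoes.tes_s[:, None]
    valid = mask.ravel() & np.all(s > 0, axis=0)
    r2s = np.full(s.shape[1], np.nan)
    quality = np.full(s.shape[1], np.nan)
    if valid.any():
        sv = s[:, valid]
        y = np.log(sv)
        w = sv**2
        wsum = w.sum(axis=0)
        tbar = (w * te).sum(axis=0) / wsum
        ybar = (w * y).sum(axis=0) / wsum
        stt = (w * (te - tbar) ** 2).sum(axis=0)
        sty = (w * (te - tbar) * (y - ybar)).sum(axis=0)
        slope = sty / stt
        resid = y - (ybar + slope * (te - tbar))
        ss_res = (w * resid**2).sum(axis=0)
        ss_tot = (w * (y - ybar) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(ss_tot > 0, 1.0 - ss_res / np.maximum(ss_tot, 1e-300), 1.0)
        r2s[valid] = np.maximum(-slope, 0.0)
        quality[valid] = q
    return R2StarMap(r2s.reshape(shape), quality.reshape(shape), echoes.voxel_size_mm)


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------

def reconstruct_chi(
    echoes: EchoSeries,
    brain_mask: np.ndarray,
    sharp_cfg: Optional[SharpConfig] = None,
    inv_cfg: Optional[InversionConfig] = None,
    denoise_strength: float = 0.0,
    f0_hz: float = F0_HZ,
):
    """Full reconstruction: denoise → unwrap → combine → SHARP → invert → reference.

    Returns ``(chi, tissue_field, frequency)`` with χ referenced to the mean
    susceptibility of brain tissue inside the reliability mask.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    data = denoise_complex(echoes, denoise_strength)
    unwrapped = np.stack(
        [unwrap_phase_3d(data.phase[i], brain_mask) for i in range(data.n_echoes)]
    )
    freq = echoes_to_frequency(
        unwrapped, data.tes_s, data.magnitude, brain_mask, data.voxel_size_mm
    )
    tissue = sharp_remove_background(freq, brain_mask, sharp_cfg)
    chi = invert_dipole(tissue, inv_cfg, f0_hz)
    chi = reference_chi(chi, tissue.reliability_mask)
    return chi, tissue, freq
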