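"""Ground-truth phantoms, forward dipole physics and synthetic cohorts.

The dentate nucleus is modelled as a thin, corrugated, open-topped
ellipsoidal shell of elevated susceptibility (the "silhouette", DN_sil)
surrounding lower-susceptibility white matter; the filled shell is the
iron-rich bulk (DN_bulk).  A smooth harmonic background field (low-order
polynomial plus external point-dipole sources) and complex Gaussian noise
complete the forward model from which multi-echo gradient-echo data are
synthesized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from dnqsm.config import DEFAULT_TES_S, DEFAULT_VOXEL_SIZE_MM, F0_HZ
from dnqsm.voi import rasterize_hull
from dnqsm.containers import (
    ChiMap,
    DNMask,
    DN_LABEL_LEFT,
    DN_LABEL_RIGHT,
    EchoSeries,
    GroundTruth,
    as_voxel_size,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_dentate_phantom",
    "forward_field",
    "synthesize_echoes",
    "make_cohort",
    "make_sphere_chi",
    "analytic_sphere_field",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

def _default_poly():
    # harmonic basis coefficients, Hz at the edge of the field of view
    return {"x": 2.0, "y": -1.5, "z": 1.0, "xy": 0.8, "x2_y2": 0.6}


@dataclass
class PhantomSpec:
    """Parameters of a single-subject dentate phantom.

    The shell geometry is specified for the right hemisphere relative to the
    grid centre and mirrored about the mid-sagittal plane (axis 0) for the
    left.  The geometry itself is a synthetic stand-in: only the qualitative
    features (thin corrugated walls, enclosed white matter, CSF pockets) are
    modelled; no quantitative dentate shape atlas is emulated.
    """

    grid_shape: tuple = (112, 112, 112)
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    wall_chi_ppb: float = 100.0
    interior_chi_ppb: float = 20.0
    tissue_chi_ppb: float = 0.0
    shell_center_mm: tuple = (7.0, 0.0, 0.0)
    shell_radii_mm: tuple = (5.2, 6.6, 5.6)
    wall_thickness_mm: float = 1.0
    corrugation_amplitude_mm: float = 0.4
    corrugation_cycles: int = 6
    opening_half_angle_deg: float = 40.0
    brain_radii_mm: tuple = (24.0, 24.0, 22.0)
    background_poly_coeffs: dict = dc_field(default_factory=_default_poly)
    external_source_positions_mm: tuple = ((26.0, 24.0, 21.0), (-25.0, -24.0, -20.0))
    external_source_strengths: tuple = (10.0e3, -8.0e3)  # Hz * mm^3
    csf_pocket_radius_mm: float = 1.2
    csf_chi_ppb: float = 0.0
    r2star_wall: float = 40.0
    r2star_interior: float = 25.0
    r2star_tissue: float = 20.0
    r2star_csf: float = 5.0
    s0: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be three axes of at least 16 voxels")
        as_voxel_size(self.voxel_size_mm)
        if self.wall_thickness_mm >= min(self.shell_radii_mm):
            raise ValueError("wall_thickness_mm must be smaller than min(shell_radii_mm)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class CohortSpec:
    """Two-group cohort design with dentate χ and volume effects.

    Defaults parameterize a patient/control contrast of the magnitude seen in
    degenerative ataxia: +39 ppb dentate bulk susceptibility in patients with
    a between-subject sd of 28 ppb, a 22% dentate volume reduction, TIV
    1550 ± 140 cm³, and a linear dentate-volume–TIV relationship.
    """

    n_patients: int = 16
    n_controls: int = 16
    delta_chi_ppb: float = 39.0
    chi_between_sd_ppb: float = 28.0
    volume_scale: float = 0.78
    volume_jitter_sd: float = 0.10
    tiv_mean_cm3: float = 1550.0
    tiv_sd_cm3: float = 140.0
    volume_tiv_slope: float = 0.4  # mm^3 dentate volume per cm^3 TIV
    age_range_years: tuple = (31.6, 68.3)
    sara_model: dict = dc_field(
        default_factory=lambda: {
            "intercept": 14.0,
            "volume_coef": -6.0,
            "chi_coef": 1.5,
            "age_coef": 0.05,
            "noise_sd": 3.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.tiv_sd_cm3 <= 0:
            raise ValueError("tiv_sd_cm3 must be > 0")
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be > 0")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _centered_coords(grid_shape, voxel_size_mm):
    v = as_voxel_size(voxel_size_mm)
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v[i] for i, n in enumerate(grid_shape)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _shell_regions(coords, center, radii, wall, amp, cycles, opening_deg):
    """Return (shell, filled) boolean masks for one corrugated open shell."""
    px = coords[0] - center[0]
    py = coords[1] - center[1]
    pz = coords[2] - center[2]
    r = np.sqrt(px**2 + py**2 + pz**2)
    a, b, c = radii
    u = np.sqrt((px / a) ** 2 + (py / b) ** 2 + (pz / c) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        # ellipsoid radius along each voxel's direction; corrugation and wall
        # thickness are specified in mm and converted to the normalized
        # coordinate u by dividing by this direction-dependent radius
        r_dir = np.where(u > 0, r / np.maximum(u, 1e-12), np.mean(radii))
        theta = np.arctan2(py, px)
        phi = np.arccos(np.clip(np.where(r > 0, pz / np.maximum(r, 1e-12), 1.0), -1, 1))
    corr_u = amp * np.sin(cycles * theta) * np.sin(cycles * phi) / r_dir
    half_u = (wall / 2.0) / r_dir
    surface = 1.0 + corr_u
    filled = u <= surface + half_u
    shell = np.abs(u - surface) <= half_u
    # open top: remove the dorsal polar cap from the wall (not from the fill)
    cos_polar = np.where(r > 0, pz / np.maximum(r, 1e-12), 1.0)
    open_cap = cos_polar > np.cos(np.deg2rad(opening_deg))
    shell &= ~open_cap
    return shell, filled


def make_dentate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the ground-truth χ, masks, R2* and total field for one subject.

    The χ map holds two mirrored corrugated shells (``wall_chi_ppb``) around
    white-matter interiors (``interior_chi_ppb``) inside an ellipsoidal brain
    of ``tissue_chi_ppb``; the total field is the dipole field of χ plus the
    harmonic background (polynomial + external sources).  Deterministic for a
    given spec.
    """
    spec.validate()
    shape = tuple(int(n) for n in spec.grid_shape)
    v = as_voxel_size(spec.voxel_size_mm)
    half_extent = np.array([n * vi / 2.0 for n, vi in zip(shape, v)])
    reach = np.asarray(spec.shell_radii_mm) + spec.corrugation_amplitude_mm + spec.wall_thickness_mm / 2
    for ax in range(3):
        if abs(spec.shell_center_mm[ax]) + reach[ax] > half_extent[ax]:
            raise ValueError(
                f"dentate shell exceeds the grid along axis {ax} "
                f"(extent {abs(spec.shell_center_mm[ax]) + reach[ax]:.1f} mm > "
                f"{half_extent[ax]:.1f} mm)"
            )

    coords = _centered_coords(shape, v)
    bx, by, bz = spec.brain_radii_mm
    brain = (
        (coords[0] / bx) ** 2 + (coords[1] / by) ** 2 + (coords[2] / bz) ** 2
    ) <= 1.0

    cx, cy, cz = spec.shell_center_mm
    centers = {"right": (abs(cx), cy, cz), "left": (-abs(cx), cy, cz)}
    labels_sil = np.zeros(shape, dtype=np.int16)
    labels_bulk = np.zeros(shape, dtype=np.int16)
    chi = np.full(shape, 0.0)
    chi[brain] = spec.tissue_chi_ppb
    r2s = np.zeros(shape)
    r2s[brain] = spec.r2star_tissue
    csf = np.zeros(shape, dtype=bool)

    for name, center in centers.items():
        lab = DN_LABEL_LEFT if name == "left" else DN_LABEL_RIGHT
        shell, filled = _shell_regions(
            coords,
            center,
            spec.shell_radii_mm,
            spec.wall_thickness_mm,
            spec.corrugation_amplitude_mm,
            spec.corrugation_cycles,
            spec.opening_half_angle_deg,
        )
        interior = filled & ~shell
        chi[interior] = spec.interior_chi_ppb
        chi[shell] = spec.wall_chi_ppb
        r2s[interior] = spec.r2star_interior
        r2s[shell] = spec.r2star_wall
        if spec.csf_pocket_radius_mm > 0:
            d2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
            pocket = (d2 <= spec.csf_pocket_radius_mm**2) & filled
            csf |= pocket
        labels_sil[shell] = lab
        # the true bulk is the filled convex hull of the shell wall
        labels_bulk[rasterize_hull(np.argwhere(shell).astype(float), shape)] = lab

    chi[csf] = spec.csf_chi_ppb
    r2s[csf] = spec.r2star_csf
    labels_bulk[csf] = 0

    field = forward_field(chi, v)
    field += _background_field(coords, half_extent, spec)

    return GroundTruth(
        chi=ChiMap(chi, v),
        dn_sil_true=DNMask(labels_sil, "sil", v),
        dn_bulk_true=DNMask(labels_bulk, "bulk", v),
        brain_mask=brain,
        r2star_true=r2s,
        field_true_hz=field,
    )


def _background_field(coords, half_extent, spec: PhantomSpec) -> np.ndarray:
    """Harmonic background: order-2 polynomial plus external point dipoles."""
    xi = [coords[i] / half_extent[i] for i in range(3)]
    basis = {
        "const": np.ones_like(xi[0]),
        "x": xi[0],
        "y": xi[1],
        "z": xi[2],
        "xy": xi[0] * xi[1],
        "xz": xi[0] * xi[2],
        "yz": xi[1] * xi[2],
        "x2_y2": xi[0] ** 2 - xi[1] ** 2,
        "y2_z2": xi[1] ** 2 - xi[2] ** 2,
    }
    bg = np.zeros_like(xi[0])
    for key, coef in (spec.background_poly_coeffs or {}).items():
        if key not in basis:
            raise ValueError(f"unknown background polynomial term '{key}'")
        bg += coef * basis[key]
    for pos, m in zip(
        spec.external_source_positions_mm, spec.external_source_strengths
    ):
        dx = coords[0] - pos[0]
        dy = coords[1] - pos[1]
        dz = coords[2] - pos[2]
        r2 = dx**2 + dy**2 + dz**2
        r2 = np.maximum(r2, 1.0)  # clip near the source itself
        cos2 = dz**2 / r2
        bg += m * (3.0 * cos2 - 1.0) / r2**1.5
    return bg


# --------------------------------------------------------------------------
# forward dipole model
# --------------------------------------------------------------------------

def dipole_kernel(grid_shape, voxel_size_mm, b0_direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Unit dipole response D(k) = 1/3 - (k.b0)^2/|k|^2 with D(0) = 0.

    The k-grid is built per axis with ``fftfreq(n, d=voxel_size[axis])`` so
    anisotropic voxels enter explicitly through the axis spacings.
    """
    b0 = np.asarray(b0_direction, dtype=float)
    if abs(np.linalg.norm(b0) - 1.0) > 1e-6:
        raise ValueError("b0_direction must be a unit vector")
    v = as_voxel_size(voxel_size_mm)
    ks = [np.fft.fftfreq(int(n), d=v[i]) for i, n in enumerate(grid_shape)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b0[0] + ky * b0[1] + kz * b0[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d[k2 == 0] = 0.0
    return d


def forward_field(
    chi_ppb: np.ndarray,
    voxel_size_mm,
    b0_direction=(0.0, 0.0, 1.0),
    f0_hz: float = F0_HZ,
) -> np.ndarray:
    """Frequency shift (Hz) induced by a susceptibility distribution (ppb).

    field = f0 * IFFT(D(k) * FFT(chi)), chi dimensionless; with D(0) = 0 the
    mean field over the full grid is zero (the arbitrary offset is fixed).
    """
    chi_ppb = np.asarray(chi_ppb, dtype=float)
    d = dipole_kernel(chi_ppb.shape, voxel_size_mm, b0_direction)
    chi = chi_ppb * 1e-9
    return f0_hz * np.fft.ifftn(d * np.fft.fftn(chi)).real


def make_sphere_chi(grid_shape, voxel_size_mm, center_mm, radius_mm, dchi_ppb):
    """Sphere of uniform susceptibility contrast on the grid (test phantom)."""
    coords = _centered_coords(grid_shape, voxel_size_mm)
    d2 = sum((coords[i] - center_mm[i]) ** 2 for i in range(3))
    return np.where(d2 <= radius_mm**2, float(dchi_ppb), 0.0)


def analytic_sphere_field(
    grid_shape, voxel_size_mm, center_mm, radius_mm, dchi_ppb, f0_hz: float = F0_HZ
):
    """Closed-form dipole field of a uniform sphere, Hz.

    Outside the sphere: f = f0 * (dchi/3) * (a/r)^3 * (3 cos^2 theta - 1);
    inside, the Lorentz-corrected field shift is zero.  Serves as the
    independent oracle for the FFT forward model.
    """
    coords = _centered_coords(grid_shape, voxel_size_mm)
    dx = coords[0] - center_mm[0]
    dy = coords[1] - center_mm[1]
    dz = coords[2] - center_mm[2]
    r2 = dx**2 + dy**2 + dz**2
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = np.where(r2 > 0, dz**2 / np.maximum(r2, 1e-30), 0.0)
        f = (
            f0_hz
            * (dchi_ppb * 1e-9 / 3.0)
            * (radius_mm**2 / np.maximum(r2, 1e-30)) ** 1.5
            * (3.0 * cos2 - 1.0)
        )
    f[r2 <= radius_mm**2] = 0.0
    return f


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

def synthesize_echoes(
    field_hz: np.ndarray,
    s0,
    r2star: np.ndarray,
    tes_s: Sequence[float] = DEFAULT_TES_S,
    phi0: float = 0.0,
    noise_sigma: float = 0.0,
    seed=None,
    voxel_size_mm=DEFAULT_VOXEL_SIZE_MM,
) -> EchoSeries:
    """Simulate the multi-echo complex GRE signal.

    S(TE) = s0 exp(-R2* TE) exp(i(phi0 + 2 pi f TE)) + complex Gaussian
    noise of std ``noise_sigma`` per channel; the stored phase is wrapped to
    the half-open interval (-pi, pi] (exactly -pi maps to +pi).
    """
    field_hz = np.asarray(field_hz, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), field_hz.shape)
    if np.any(r2star < 0):
        raise ValueError("r2star must be non-negative everywhere")
    tes = np.asarray(tes_s, dtype=float)
    rng = np.random.default_rng(seed)
    mags = np.empty((tes.size,) + field_hz.shape)
    phases = np.empty_like(mags)
    for i, te in enumerate(tes):
        sig = s0 * np.exp(-r2star * te) * np.exp(1j * (phi0 + 2 * np.pi * field_hz * te))
        if noise_sigma > 0:
            sig = sig + noise_sigma * (
                rng.standard_normal(field_hz.shape)
                + 1j * rng.standard_normal(field_hz.shape)
            )
        mags[i] = np.abs(sig)
        ph = np.angle(sig)
        ph[ph == -np.pi] = np.pi
        phases[i] = ph
    return EchoSeries(mags, phases, tes, voxel_size_mm)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def _nominal_bulk_volume_mm3(phantom_spec: PhantomSpec) -> float:
    a, b, c = phantom_spec.shell_radii_mm
    return 2.0 * (4.0 / 3.0) * np.pi * a * b * c  # both hemispheres


def make_cohort(cohort_spec: CohortSpec, phantom_spec: Optional[PhantomSpec] = None):
    """Draw a two-group cohort of per-subject phantom specs plus covariates.

    Returns ``(table, subject_specs)``: a DataFrame with one row per subject
    (group, age, sex, SARA, TIV, generating dentate parameters) and the list
    of per-subject :class:`PhantomSpec` objects (wall χ and shell radii drawn
    around group means; dentate volume carries a ``volume_tiv_slope`` · TIV
    component).  Fully reproducible from ``cohort_spec.seed``.
    """
    cohort_spec.validate()
    phantom_spec = phantom_spec or PhantomSpec()
    phantom_spec.validate()
    rng = np.random.default_rng(cohort_spec.seed)
    v_base = _nominal_bulk_volume_mm3(phantom_spec)
    sm = cohort_spec.sara_model
    age_mid = float(np.mean(cohort_spec.age_range_years))

    rows = []
    specs = []
    groups = ["patient"] * cohort_spec.n_patients + ["control"] * cohort_spec.n_controls
    for idx, group in enumerate(groups):
        is_pat = group == "patient"
        sid = f"{'P' if is_pat else 'C'}{idx + 1:03d}"
        age = rng.uniform(*cohort_spec.age_range_years)
        sex = "f" if rng.random() < 0.5 else "m"
        tiv = rng.normal(cohort_spec.tiv_mean_cm3, cohort_spec.tiv_sd_cm3)
        chi = (
            phantom_spec.wall_chi_ppb
            + (cohort_spec.delta_chi_ppb if is_pat else 0.0)
            + rng.normal(0.0, cohort_spec.chi_between_sd_ppb)
        )
        g = cohort_spec.volume_scale if is_pat else 1.0
        v_target = (
            v_base * g * np.exp(rng.normal(0.0, cohort_spec.volume_jitter_sd))
            + cohort_spec.volume_tiv_slope * (tiv - cohort_spec.tiv_mean_cm3)
        )
        v_target = max(v_target, 0.05 * v_base)
        scale = (v_target / v_base) ** (1.0 / 3.0)
        if is_pat:
            z_vol = (v_target - g * v_base) / (0.15 * v_base)
            z_chi = (chi - phantom_spec.wall_chi_ppb) / max(
                cohort_spec.chi_between_sd_ppb, 1e-9
            )
            sara = (
                sm["intercept"]
                + sm["volume_coef"] * z_vol
                + sm["chi_coef"] * z_chi
                + sm["age_coef"] * (age - age_mid)
                + rng.normal(0.0, sm["noise_sd"])
            )
        else:
            sara = abs(rng.normal(0.0, 0.2))
        sara = float(np.clip(sara, 0.0, 40.0))
        subj_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(
            dataclasses.replace(
                phantom_spec,
                wall_chi_ppb=float(chi),
                shell_radii_mm=tuple(float(r * scale) for r in phantom_spec.shell_radii_mm),
                seed=subj_seed,
            )
        )
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age_years": round(float(age), 4),
                "sex": sex,
                "sara": round(sara, 4),
                "tiv_cm3": round(float(tiv), 4),
                "true_wall_chi_ppb": round(float(chi), 4),
                "true_bulk_volume_mm3": round(float(v_target), 4),
                "radii_scale": round(float(scale), 6),
                "subject_seed": subj_seed,
            }
        )
    table = pd.DataFrame(rows)
    return table, specs
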