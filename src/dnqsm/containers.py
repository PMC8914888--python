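"""In-memory containers shared across the pipeline stages.

Conventions
-----------
* Volumes are ``(nx, ny, nz)`` float arrays; axis 0 is the left-right
  (sagittal) axis, axis 2 is the slice axis along B0.
* Phase is stored wrapped to the half-open interval ``(-pi, pi]``.
* Susceptibility is expressed in ppb at API boundaries, field maps in Hz,
  echo times in seconds, voxel sizes in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def as_voxel_size(voxel_size_mm) -> np.ndarray:
    """Return a length-3 array of voxel spacings in mm from scalar or triple."""
    v = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3 or np.any(v <= 0):
        raise ValueError("voxel_size_mm must be a positive scalar or length-3 sequence")
    return v


@dataclass
class EchoSeries:
    """Multi-echo complex GRE data split into magnitude and phase volumes.

    ``magnitude`` and ``phase`` have shape ``(n_echoes, nx, ny, nz)``;
    ``tes_s`` are the echo times in seconds, strictly increasing.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    tes_s: np.ndarray
    voxel_size_mm: np.ndarray

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.tes_s = np.asarray(self.tes_s, dtype=float)
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if self.magnitude.ndim != 4:
            raise ValueError("expected (n_echoes, nx, ny, nz) volumes")
        if self.tes_s.ndim != 1 or self.tes_s.size != self.magnitude.shape[0]:
            raise ValueError("tes_s length must equal the number of echoes")
        if self.tes_s.size > 1 and np.any(np.diff(self.tes_s) <= 0):
            raise ValueError("tes_s must be strictly increasing")
        if np.any(self.phase > np.pi) or np.any(self.phase <= -np.pi):
            raise ValueError("phase must lie in (-pi, pi]")

    @property
    def n_echoes(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.magnitude.shape[1:]

    def complex(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


@dataclass
class FrequencyMap:
    """Voxelwise Larmor-frequency variation in Hz with a validity mask."""

    data_hz: np.ndarray
    mask: np.ndarray
    voxel_size_mm: np.ndarray
    single_echo: bool = False

    def __post_init__(self):
        self.data_hz = np.asarray(self.data_hz, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        if self.data_hz.shape != self.mask.shape:
            raise ValueError("frequency map and mask shapes differ")
        if not np.all(np.isfinite(self.data_hz[self.mask])):
            raise ValueError("frequency map not finite inside mask")


@dataclass
class TissueFieldMap:
    """Background-corrected (SHARP) tissue frequency in Hz.

    ``reliability_mask`` marks voxels where at least the smallest SMV kernel
    fits inside the brain mask; values are zero outside it.
    """

    data_hz: np.ndarray
    reliability_mask: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: np.ndarray

    def __post_init__(self):
        self.data_hz = np.asarray(self.data_hz, dtype=float)
        self.reliability_mask = np.asarray(self.reliability_mask, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        if np.any(self.reliability_mask & ~self.brain_mask):
            raise ValueError("reliability mask must be contained in brain mask")


@dataclass
class ChiMap:
    """Voxelwise magnetic susceptibility in ppb."""

    data_ppb: np.ndarray
    voxel_size_mm: np.ndarray
    reference_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data_ppb = np.asarray(self.data_ppb, dtype=float)
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        if self.reference_mask is not None:
            self.reference_mask = np.asarray(self.reference_mask, dtype=bool)
            if self.reference_mask.shape != self.data_ppb.shape:
                raise ValueError("reference mask shape differs from data")


@dataclass
class R2StarMap:
    """Effective transverse relaxation rate (s^-1) with log-linear fit quality."""

    data: np.ndarray
    r_squared: np.ndarray
    voxel_size_mm: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        valid = np.isfinite(self.data)
        if np.any(self.data[valid] < 0):
            raise ValueError("R2* must be non-negative where finite")


#: integer labels used in DNMask volumes
DN_LABEL_LEFT = 1
DN_LABEL_RIGHT = 2


@dataclass
class DNMask:
    """Labeled dentate VOI on the image grid.

    ``labels`` is an integer volume with 0 = background, 1 = left,
    2 = right hemisphere; ``kind`` is ``"sil"`` (traced silhouette) or
    ``"bulk"`` (filled iron-rich bulk).
    """

    labels: np.ndarray
    kind: str
    voxel_size_mm: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        if self.kind not in ("sil", "bulk"):
            raise ValueError("kind must be 'sil' or 'bulk'")
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def left(self) -> np.ndarray:
        return self.labels == DN_LABEL_LEFT

    @property
    def right(self) -> np.ndarray:
        return self.labels == DN_LABEL_RIGHT

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class VOIMetrics:
    """Per-subject dentate VOI metrics summed across hemispheres.

    Susceptibility mass is the non-normalized volume (in cm³) times the
    mean susceptibility (ppb), a proxy for total iron content.
    """

    volume_mm3: float
    mean_chi_ppb: float
    chi_mass_ppb_cm3: float
    per_hemisphere: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "volume_mm3": self.volume_mm3,
            "mean_chi_ppb": self.mean_chi_ppb,
            "chi_mass_ppb_cm3": self.chi_mass_ppb_cm3,
        }


@dataclass
class GroundTruth:
    """Ground-truth volumes attached to a simulated subject."""

    chi: ChiMap
    dn_sil_true: DNMask
    dn_bulk_true: DNMask
    brain_mask: np.ndarray
    r2star_true: np.ndarray
    field_true_hz: np.ndarray

    def __post_init__(self):
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if np.any(self.dn_sil_true.mask & ~self.brain_mask):
            raise ValueError("dn_sil_true must be contained in brain mask")
        if np.any(self.dn_bulk_true.mask & ~self.brain_mask):
            raise ValueError("dn_bulk_true must be contained in brain mask")
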