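"""In-memory containers for DCE-MRI volumes, perfusion maps and QC reports.

All image containers carry a NIfTI affine so they can round-trip through
:mod:`dceauc.io` without losing geometry. Voxel data are plain numpy arrays
in (x, y, z[, t]) order; times are seconds, concentrations mmol/L, AUC60
mmol.s/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicSeries",
    "VFAScanPair",
    "T1Map",
    "ConcentrationSeries",
    "AIFCurve",
    "AUCMap",
    "VoxelQCReport",
    "PerfusionSummary",
]


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class DynamicSeries:
    """4D dynamic signal volume with frame-time metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensities (arbitrary scanner units).
    times_s : ndarray, shape (t,)
        Acquisition time of each frame, seconds, strictly increasing.
    affine : ndarray (4, 4)
        Voxel-to-world affine.
    """

    data: np.ndarray
    times_s: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"dynamic series must be 4D, got shape {self.data.shape}")
        if self.times_s.ndim != 1 or self.times_s.size != self.data.shape[3]:
            raise ValueError("times_s must have one entry per frame")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def dt_s(self) -> float:
        """Median frame interval (frames are expected to be uniform)."""
        return float(np.median(np.diff(self.times_s)))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class VFAScanPair:
    """Two pre-contrast spoiled-gradient-echo scans at distinct flip angles.

    The protocol acquires these at 6 and 16 degrees to estimate native T1.
    """

    volumes: tuple[np.ndarray, np.ndarray]
    flip_angles_deg: tuple[float, float] = (6.0, 16.0)
    tr_s: float = 0.005
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        v0, v1 = (np.asarray(v, dtype=float) for v in self.volumes)
        if v0.shape != v1.shape:
            raise ValueError("VFA volumes must share the voxel grid")
        self.volumes = (v0, v1)
        a0, a1 = self.flip_angles_deg
        if a0 == a1:
            raise ValueError("flip angles must be distinct")
        for a in (a0, a1):
            if not 0.0 < a <= 90.0:
                raise ValueError(f"flip angle {a} deg outside (0, 90]")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape


@dataclass
class T1Map:
    """Per-voxel longitudinal relaxation time with a validity mask.

    ``t1_s`` is positive wherever ``valid``; invalid voxels hold NaN and are
    excluded downstream rather than imputed. ``m0`` is the equilibrium-signal
    scale recovered alongside T1.
    """

    t1_s: np.ndarray
    m0: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.t1_s = np.asarray(self.t1_s, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t1_s.shape == self.m0.shape == self.valid.shape):
            raise ValueError("t1_s, m0 and valid must share the voxel grid")
        if np.any(self.t1_s[self.valid] <= 0):
            raise ValueError("valid voxels must have positive T1")


@dataclass
class ConcentrationSeries:
    """Per-voxel gadolinium concentration over time (mmol/L).

    Baseline frames average to zero concentration by construction; voxels or
    frames where the signal model could not be inverted are NaN and counted
    in ``n_inversion_failures``.
    """

    conc: np.ndarray
    times_s: np.ndarray
    baseline_frames: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)
    n_inversion_failures: int = 0

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.baseline_frames = np.asarray(self.baseline_frames, dtype=int)
        if self.conc.ndim != 4:
            raise ValueError("concentration series must be 4D")
        if self.times_s.size != self.conc.shape[3]:
            raise ValueError("times_s must have one entry per frame")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.baseline_frames.size == 0:
            raise ValueError("at least one baseline frame is required")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.conc.shape[:3]


@dataclass
class AIFCurve:
    """Arterial input function: concentration over time in the artery ROI."""

    conc_mmol_per_l: np.ndarray
    times_s: np.ndarray
    peak_index: int

    def __post_init__(self) -> None:
        self.conc_mmol_per_l = np.asarray(self.conc_mmol_per_l, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.conc_mmol_per_l.size != self.times_s.size:
            raise ValueError("curve and times must have equal length")

    @property
    def peak_time_s(self) -> float:
        return float(self.times_s[self.peak_index])


@dataclass
class AUCMap:
    """Per-voxel AUC60 (mmol.s/L) with the retained-voxel mask after QC."""

    auc60: np.ndarray
    window_start_s: float
    window_end_s: float
    tumor_mask: np.ndarray
    retained_mask: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.auc60 = np.asarray(self.auc60, dtype=float)
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.auc60.shape != self.tumor_mask.shape:
            raise ValueError("auc60 and tumor mask must share the voxel grid")
        if np.any(self.retained_mask & ~self.tumor_mask):
            raise ValueError("retained voxels must lie inside the tumor mask")


@dataclass
class VoxelQCReport:
    """Accounting of the voxel quality-control filters."""

    n_tumor: int
    n_removed_percentile: int = 0
    n_removed_negative: int = 0
    n_removed_missing: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_tumor
            - self.n_removed_percentile
            - self.n_removed_negative
            - self.n_removed_missing
        )

    @property
    def fraction_retained(self) -> float:
        if self.n_tumor == 0:
            return 0.0
        return self.n_retained / self.n_tumor

    def to_dict(self) -> dict:
        return {
            "n_tumor": self.n_tumor,
            "n_removed_percentile": self.n_removed_percentile,
            "n_removed_negative": self.n_removed_negative,
            "n_removed_missing": self.n_removed_missing,
            "n_retained": self.n_retained,
            "fraction_retained": self.fraction_retained,
        }


@dataclass
class PerfusionSummary:
    """Tumor-level AUC60 summary: median and 95th percentile over retained voxels.

    ``excluded`` mirrors the study rule of dropping a tumor whose retained
    voxel fraction falls below a minimum (a tumor with only 3% of voxels
    surviving QC was excluded from the source analysis).
    """

    auc60_median: float | None
    auc60_p95: float | None
    qc: VoxelQCReport
    excluded: bool = False
    exclusion_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "auc60_median": self.auc60_median,
            "auc60_p95": self.auc60_p95,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "qc": self.qc.to_dict(),
        }
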