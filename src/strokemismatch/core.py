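"""Core domain types shared across the pipeline.

Volumes are carried internally as decimal millilitres; images are plain
numpy arrays on a common grid (coregistration is assumed upstream — every
array entering one analysis must share a single :class:`GeometryParams`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "AcquisitionParams",
    "GeometryParams",
    "DSCSeries",
    "ConcentrationSeries",
    "AifCurve",
    "PerfusionMapSet",
    "LesionMask",
    "InvalidKineticsError",
    "GeometryMismatchError",
]

#: Sentinel for voxels excluded from a map (no valid peak, cbf <= eps, ...).
INVALID = np.nan


class InvalidKineticsError(ValueError):
    """Raised when a simulated region has non-physical kinetics (mtt <= 0, cbv < 0)."""


class GeometryMismatchError(ValueError):
    """Raised when two grids that must be coregistered differ in shape or spacing."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing of a dynamic susceptibility-contrast (bolus-tracking) acquisition.

    Defaults mirror a standard 1.5 T gradient-echo EPI perfusion protocol:
    TR/TE 1500/40 ms, 46 dynamic frames (69 s of imaging), contrast injected
    10 s after the start of acquisition.
    """

    tr_s: float = 1.5
    te_s: float = 0.040
    n_frames: int = 46
    injection_delay_s: float = 10.0
    n_baseline_frames: int = 6

    def __post_init__(self) -> None:
        if self.tr_s <= 0 or self.te_s <= 0:
            raise ValueError("tr_s and te_s must be positive")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if not 0 <= self.n_baseline_frames < self.n_frames:
            raise ValueError("n_baseline_frames must lie in [0, n_frames)")
        if self.injection_delay_s < 0:
            raise ValueError("injection_delay_s must be non-negative")

    @property
    def time_axis_s(self) -> np.ndarray:
        """Frame acquisition times in seconds from the start of imaging."""
        return np.arange(self.n_frames) * self.tr_s


@dataclass(frozen=True)
class GeometryParams:
    """Voxel grid geometry: isotropic in-plane spacing plus slice spacing.

    Defaults correspond to a 22-cm field of view on a 256 matrix
    (220/256 = 0.859375 mm) with 5-mm slices and a 1-mm gap (6 mm
    centre-to-centre).
    """

    in_plane_spacing_mm: float = 220.0 / 256.0
    slice_spacing_mm: float = 6.0
    grid_shape: Tuple[int, int, int] = (256, 256, 16)

    def __post_init__(self) -> None:
        if self.in_plane_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("voxel spacings must be positive")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three entries >= 1")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return self.in_plane_spacing_mm**2 * self.slice_spacing_mm / 1000.0

    def affine(self) -> np.ndarray:
        """Diagonal RAS affine for NIfTI export."""
        return np.diag(
            [self.in_plane_spacing_mm, self.in_plane_spacing_mm, self.slice_spacing_mm, 1.0]
        )


def _check_same_geometry(a: "GeometryParams", b: "GeometryParams") -> None:
    if (
        tuple(a.grid_shape) != tuple(b.grid_shape)
        or not np.isclose(a.in_plane_spacing_mm, b.in_plane_spacing_mm)
        or not np.isclose(a.slice_spacing_mm, b.slice_spacing_mm)
    ):
        raise GeometryMismatchError(f"grids are not coregistered: {a} vs {b}")


@dataclass
class DSCSeries:
    """4D (x, y, z, t) signal-intensity series from a bolus-tracking scan."""

    data: np.ndarray
    acq: AcquisitionParams
    geometry: GeometryParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DSCSeries.data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != tuple(self.geometry.grid_shape):
            raise GeometryMismatchError("series spatial shape disagrees with geometry")
        if self.data.shape[3] != self.acq.n_frames:
            raise ValueError(
                f"series has {self.data.shape[3]} frames, acquisition says {self.acq.n_frames}"
            )

    @property
    def time_axis_s(self) -> np.ndarray:
        return self.acq.time_axis_s


@dataclass
class ConcentrationSeries:
    """Tracer concentration (arbitrary units) per voxel and frame."""

    data: np.ndarray
    time_axis_s: np.ndarray
    geometry: GeometryParams
    invalid_mask: Optional[np.ndarray] = None  # voxels with unusable baseline

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ConcentrationSeries.data must be 4D")
        if self.data.shape[3] != self.time_axis_s.size:
            raise ValueError("time axis length disagrees with the frame count")


@dataclass
class AifCurve:
    """Arterial input function: concentration per frame in a feeding-artery ROI."""

    values: np.ndarray
    time_axis_s: np.ndarray
    source_roi_id: str = "ipsilateral_mca"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.values.shape != self.time_axis_s.shape:
            raise ValueError("AIF values and time axis must have equal length")
        if not np.any(self.values > 0):
            raise ValueError(f"AIF from ROI '{self.source_roi_id}' has no positive peak")


@dataclass
class PerfusionMapSet:
    """Per-voxel haemodynamic maps derived from one DSC series.

    ``cbf_rel`` and ``cbv_rel`` are relative (arbitrary-unit) flow and blood
    volume; their ratio ``mtt_s = cbv_rel / cbf_rel`` is in seconds by the
    central volume theorem. Invalid voxels carry NaN, never silent zeros.
    """

    geometry: GeometryParams
    ttp_s: Optional[np.ndarray] = None
    ttp_delay_s: Optional[np.ndarray] = None
    cbf_rel: Optional[np.ndarray] = None
    cbv_rel: Optional[np.ndarray] = None
    mtt_s: Optional[np.ndarray] = None


@dataclass
class LesionMask:
    """Binary 3D lesion (or ROI) mask with its grid geometry."""

    data: np.ndarray
    geometry: GeometryParams
    provenance: str = "manual"  # one of dwi, pwi_ttp, pwi_mtt, manual

    _PROVENANCES = ("dwi", "pwi_ttp", "pwi_mtt", "manual")

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("LesionMask.data must be 3D")
        if arr.shape != tuple(self.geometry.grid_shape):
            raise GeometryMismatchError("mask shape disagrees with geometry")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.data = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))
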