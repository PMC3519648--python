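"""Lesion volumetry and the diffusion/perfusion mismatch statistic.

The mismatch rules, in the order they are applied:

1. *Union rule* — DWI voxels not covered by the perfusion lesion are added
   to the total perfusion-abnormality volume (the infarct is by definition
   part of the tissue that failed to perfuse).
2. *Zero floor* — the mismatch is zero whenever the (total) perfusion
   lesion is not larger than the DWI lesion.
3. *Relative mismatch* — absolute mismatch divided by DWI volume, in
   percent. Undefined for a DWI volume of exactly zero; callers may
   substitute a configured cap (simulations) or keep sub-ml decimals
   (cohort tables) so the division never degenerates.

Classification uses inclusive boundaries: a DWI lesion of 70 ml counts as
"70 ml or less", and a relative mismatch of exactly 100% counts as a large
mismatch.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import GeometryMismatchError, LesionMask, _check_same_geometry

__all__ = [
    "CohortRecord",
    "MismatchResult",
    "ZeroDwiVolumeError",
    "mask_volume",
    "abc2_volume",
    "total_perfusion_volume",
    "absolute_mismatch",
    "relative_mismatch_pct",
    "classify",
    "mismatch_from_volumes",
    "mismatch_from_masks",
    "validate_records",
]

DWI_CUTOFF_ML = 70.0
DWI_CUTOFF_SECONDARY_ML = 100.0
MISMATCH_CUTOFF_PCT = 100.0


class ZeroDwiVolumeError(ValueError):
    """Relative mismatch is undefined for a DWI volume of exactly zero."""


@dataclass
class CohortRecord:
    """One patient's measured volumes (the row type of the cohort tables)."""

    patient_id: str
    hours_after_onset: float
    dwi_vol_ml: float
    perf_vol_ml: float
    perf_modality: str
    mismatch_vol_ml: float
    mismatch_pct: float
    inconsistent: bool = False

    def __post_init__(self) -> None:
        if self.hours_after_onset <= 0:
            raise ValueError(f"{self.patient_id}: hours_after_onset must be positive")
        for name in ("dwi_vol_ml", "perf_vol_ml", "mismatch_vol_ml", "mismatch_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.patient_id}: {name} must be non-negative")
        if self.perf_modality not in ("MTT", "TTP"):
            raise ValueError(
                f"{self.patient_id}: perf_modality must be MTT or TTP, "
                f"got {self.perf_modality!r}"
            )


@dataclass
class MismatchResult:
    """Mismatch volumes and classification for one patient."""

    dwi_vol_ml: float
    perf_vol_ml: float
    total_perf_vol_ml: float
    absolute_mismatch_ml: float
    relative_mismatch_pct: Optional[float]
    is_large_mismatch: Optional[bool]
    dwi_size_class: str  # 'le_cutoff' or 'gt_cutoff'
    dwi_cutoff_ml: float = DWI_CUTOFF_ML
    mismatch_cutoff_pct: float = MISMATCH_CUTOFF_PCT


def mask_volume(mask: LesionMask) -> float:
    """Volume of a binary mask in ml (voxel count x voxel volume)."""
    return mask.n_voxels * mask.geometry.voxel_volume_ml


def abc2_volume(a_cm: float, b_cm: float, c_cm: float) -> float:
    """Ellipsoid bedside approximation A*B*C/2 from the three longest
    orthogonal diameters in cm; returns ml (cm^3)."""
    if a_cm < 0 or b_cm < 0 or c_cm < 0:
        raise ValueError("diameters must be non-negative")
    return a_cm * b_cm * c_cm / 2.0


def total_perfusion_volume(pwi: LesionMask, dwi: LesionMask) -> float:
    """Union-rule total: volume of pwi plus the DWI voxels pwi misses."""
    _check_same_geometry(pwi.geometry, dwi.geometry)
    union = np.count_nonzero(pwi.data | dwi.data)
    return union * pwi.geometry.voxel_volume_ml


def absolute_mismatch(dwi_vol_ml: float, total_perf_vol_ml: float) -> float:
    """Perfusion minus diffusion volume, floored at zero."""
    if dwi_vol_ml < 0 or total_perf_vol_ml < 0:
        raise ValueError("volumes must be non-negative")
    return max(total_perf_vol_ml - dwi_vol_ml, 0.0)


def relative_mismatch_pct(dwi_vol_ml: float, absolute_mismatch_ml: float) -> float:
    """Absolute mismatch as a percentage of the DWI lesion volume."""
    if dwi_vol_ml < 0 or absolute_mismatch_ml < 0:
        raise ValueError("volumes must be non-negative")
    if dwi_vol_ml == 0:
        raise ZeroDwiVolumeError(
            "relative mismatch is undefined for a DWI volume of exactly 0 ml; "
            "keep sub-ml decimals or configure zero_dwi_pct_cap"
        )
    return 100.0 * absolute_mismatch_ml / dwi_vol_ml


def classify(
    dwi_vol_ml: float,
    relative_mismatch_pct: Optional[float],
    dwi_cutoff_ml: float = DWI_CUTOFF_ML,
    mismatch_cutoff_pct: float = MISMATCH_CUTOFF_PCT,
) -> tuple:
    """(dwi_size_class, is_large_mismatch) with inclusive boundaries."""
    if dwi_cutoff_ml <= 0 or mismatch_cutoff_pct <= 0:
        raise ValueError("cutoffs must be positive")
    size_class = "le_cutoff" if dwi_vol_ml <= dwi_cutoff_ml else "gt_cutoff"
    is_large = (
        None
        if relative_mismatch_pct is None
        else bool(relative_mismatch_pct >= mismatch_cutoff_pct)
    )
    return size_class, is_large


def mismatch_from_volumes(
    dwi_vol_ml: float,
    perf_vol_ml: float,
    dwi_cutoff_ml: float = DWI_CUTOFF_ML,
    mismatch_cutoff_pct: float = MISMATCH_CUTOFF_PCT,
    zero_dwi_pct_cap: Optional[float] = None,
) -> MismatchResult:
    """Full mismatch computation from scalar volumes.

    With only scalars the union rule reduces to its tight lower bound
    total = max(perf, dwi) — which leaves the absolute mismatch equal to
    max(perf - dwi, 0) in every case.
    """
    total = max(perf_vol_ml, dwi_vol_ml)
    abs_mm = absolute_mismatch(dwi_vol_ml, total)
    if dwi_vol_ml > 0:
        pct: Optional[float] = relative_mismatch_pct(dwi_vol_ml, abs_mm)
    elif zero_dwi_pct_cap is not None:
        pct = zero_dwi_pct_cap if abs_mm > 0 else 0.0
    else:
        pct = None
    size_class, is_large = classify(dwi_vol_ml, pct, dwi_cutoff_ml, mismatch_cutoff_pct)
    return MismatchResult(
        dwi_vol_ml=dwi_vol_ml,
        perf_vol_ml=perf_vol_ml,
        total_perf_vol_ml=total,
        absolute_mismatch_ml=abs_mm,
        relative_mismatch_pct=pct,
        is_large_mismatch=is_large,
        dwi_size_class=size_class,
        dwi_cutoff_ml=dwi_cutoff_ml,
        mismatch_cutoff_pct=mismatch_cutoff_pct,
    )


def mismatch_from_masks(
    dwi: LesionMask,
    pwi: LesionMask,
    dwi_cutoff_ml: float = DWI_CUTOFF_ML,
    mismatch_cutoff_pct: float = MISMATCH_CUTOFF_PCT,
    zero_dwi_pct_cap: Optional[float] = None,
) -> MismatchResult:
    """Full mismatch computation from coregistered lesion masks."""
    dwi_vol = mask_volume(dwi)
    perf_vol = mask_volume(pwi)
    total = total_perfusion_volume(pwi, dwi)
    abs_mm = absolute_mismatch(dwi_vol, total)
    if dwi_vol > 0:
        pct: Optional[float] = relative_mismatch_pct(dwi_vol, abs_mm)
    elif zero_dwi_pct_cap is not None:
        pct = zero_dwi_pct_cap if abs_mm > 0 else 0.0
    else:
        pct = None
    size_class, is_large = classify(dwi_vol, pct, dwi_cutoff_ml, mismatch_cutoff_pct)
    return MismatchResult(
        dwi_vol_ml=dwi_vol,
        perf_vol_ml=perf_vol,
        total_perf_vol_ml=total,
        absolute_mismatch_ml=abs_mm,
        relative_mismatch_pct=pct,
        is_large_mismatch=is_large,
        dwi_size_class=size_class,
        dwi_cutoff_ml=dwi_cutoff_ml,
        mismatch_cutoff_pct=mismatch_cutoff_pct,
    )


def validate_records(records: List[CohortRecord], tol_ml: float = 1.5) -> List[dict]:
    """Check each printed row against the mismatch rules under rounding.

    For whole-ml inputs the recomputed mismatch max(perf - dwi, 0) must lie
    within ``tol_ml`` of the printed value, and the printed percentage must
    fall inside the interval propagated from +-0.5 ml on dwi and perf
    (unbounded for rows whose true DWI volume is sub-ml, printed as 0).
    Rows flagged ``inconsistent`` in the fixture are reported but not
    expected to pass.
    """
    out = []
    for rec in records:
        recomputed = absolute_mismatch(rec.dwi_vol_ml, max(rec.perf_vol_ml, rec.dwi_vol_ml))
        vol_ok = abs(recomputed - rec.mismatch_vol_ml) <= tol_ml
        dlo, dhi = rec.dwi_vol_ml - 0.5, rec.dwi_vol_ml + 0.5
        if dlo <= 0:
            pct_ok = True  # printed 0 ml hides a sub-ml volume; bound is unbounded
        else:
            plo, phi = rec.perf_vol_ml - 0.5, rec.perf_vol_ml + 0.5
            lo = 100.0 * max(plo - dhi, 0.0) / dhi - 0.5
            hi = 100.0 * max(phi - dlo, 0.0) / dlo + 0.5
            pct_ok = lo <= rec.mismatch_pct <= hi
        out.append(
            {
                "patient_id": rec.patient_id,
                "recomputed_mismatch_ml": recomputed,
                "mismatch_within_tol": vol_ok,
                "pct_within_bound": pct_ok,
                "flagged_inconsistent": rec.inconsistent,
                "consistent": (vol_ok and pct_ok) or rec.inconsistent,
            }
        )
    return out
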