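"""DSC perfusion mapping: concentration conversion, TTP, SVD deconvolution.

The chain mirrors standard bolus-tracking processing:

signal -> concentration  C(t) = -ln(S/S0) / (k * TE), S0 = baseline mean
concentration -> TTP     time of the concentration maximum
TTP -> TTP delay         TTP minus the mean over a contralateral reference ROI
concentration -> CBF/CBV/MTT  via truncated-SVD deconvolution against an AIF

Lesion masks are produced by thresholding: hypoperfusion as TTP delay
strictly greater than 4 s relative to the contralateral hemisphere, or MTT
above a relative multiple of the contralateral mean. Voxels without a
usable signal carry the NaN sentinel and are excluded from every ROI
statistic — never coerced to zero.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.linalg import toeplitz

from .core import (
    AifCurve,
    ConcentrationSeries,
    DSCSeries,
    GeometryMismatchError,
    LesionMask,
    PerfusionMapSet,
)

__all__ = [
    "signal_to_concentration",
    "extract_aif",
    "compute_ttp_map",
    "ttp_delay_map",
    "threshold_ttp_lesion",
    "svd_deconvolve",
    "mtt_lesion_mask",
    "TTP_DELAY_THRESHOLD_S",
    "MTT_REL_THRESHOLD",
    "SVD_TRUNCATION_FRAC",
]

TTP_DELAY_THRESHOLD_S = 4.0
MTT_REL_THRESHOLD = 1.5
SVD_TRUNCATION_FRAC = 0.2
_CBF_EPS = 1e-12


def _as_bool_grid(mask, shape) -> np.ndarray:
    arr = mask.data if isinstance(mask, LesionMask) else np.asarray(mask)
    if arr.shape != tuple(shape):
        raise GeometryMismatchError(
            f"mask shape {arr.shape} does not match grid {tuple(shape)}"
        )
    return arr.astype(bool)


def signal_to_concentration(
    series: DSCSeries,
    brain_mask=None,
    k_dsc: float = 1.0,
) -> ConcentrationSeries:
    """Convert signal to tracer concentration via the log-ratio relation.

    Per voxel, S0 is the mean over the pre-bolus baseline frames and
    C(t) = -ln(S(t)/S0) / (k_dsc * te). Voxels outside the brain mask or
    with non-positive baseline are zeroed and flagged in ``invalid_mask``.
    """
    if k_dsc <= 0:
        raise ValueError("k_dsc must be positive")
    nb = series.acq.n_baseline_frames
    if nb < 3:
        raise ValueError(
            f"need at least 3 baseline frames to estimate S0, got {nb}"
        )
    data = series.data
    shape3 = data.shape[:3]
    brain = (
        np.ones(shape3, dtype=bool)
        if brain_mask is None
        else _as_bool_grid(brain_mask, shape3)
    )
    s0 = data[..., :nb].mean(axis=-1)
    valid = brain & (s0 > 0) & np.all(data > 0, axis=-1)
    conc = np.zeros_like(data)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = data[valid] / s0[valid][..., None]
        conc[valid] = -np.log(ratio) / (k_dsc * series.acq.te_s)
    return ConcentrationSeries(
        conc, series.time_axis_s, series.geometry, invalid_mask=~valid
    )


def extract_aif(
    conc: ConcentrationSeries, artery_roi, source_roi_id: str = "ipsilateral_mca"
) -> AifCurve:
    """Mean concentration curve over an arterial ROI (e.g. ipsilateral MCA)."""
    roi = _as_bool_grid(artery_roi, conc.data.shape[:3])
    if not roi.any():
        raise ValueError(f"arterial ROI '{source_roi_id}' is empty")
    values = conc.data[roi].mean(axis=0)
    return AifCurve(values, conc.time_axis_s, source_roi_id)


def compute_ttp_map(
    conc: ConcentrationSeries, search_start_frame: int = 0
) -> np.ndarray:
    """Time to peak in seconds from acquisition start, NaN where invalid.

    The peak search starts at ``search_start_frame`` (e.g. past the
    baseline); ties break to the earliest frame (argmax convention). Voxels
    whose curve never rises above zero, or flagged invalid during
    concentration conversion, get the NaN sentinel.
    """
    n_frames = conc.data.shape[-1]
    if not 0 <= search_start_frame < n_frames:
        raise ValueError("search_start_frame must lie within the frame range")
    window = conc.data[..., search_start_frame:]
    peak_idx = np.argmax(window, axis=-1) + search_start_frame
    ttp = conc.time_axis_s[peak_idx].astype(float)
    invalid = np.max(window, axis=-1) <= 0
    if conc.invalid_mask is not None:
        invalid |= conc.invalid_mask
    ttp[invalid] = np.nan
    return ttp


def ttp_delay_map(
    ttp: np.ndarray, reference_roi, min_valid_voxels: int = 10
) -> np.ndarray:
    """TTP minus the mean TTP over the (contralateral) reference ROI."""
    roi = _as_bool_grid(reference_roi, ttp.shape)
    ref_vals = ttp[roi]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ref_vals.size < min_valid_voxels:
        raise ValueError(
            f"reference ROI has {ref_vals.size} valid-TTP voxels; "
            f"need at least {min_valid_voxels}"
        )
    return ttp - ref_vals.mean()


def threshold_ttp_lesion(
    delay: np.ndarray,
    brain_mask,
    exclusion_mask=None,
    threshold_s: float = TTP_DELAY_THRESHOLD_S,
    geometry=None,
) -> LesionMask:
    """Hypoperfusion mask: TTP delay strictly greater than the threshold.

    The inequality is strict — a delay of exactly 4.0 s is *not* part of
    the lesion. Artifact voxels (ventricles etc.) are removed via the
    exclusion mask; NaN delays never enter the lesion.
    """
    if threshold_s <= 0:
        raise ValueError("threshold_s must be positive")
    brain = _as_bool_grid(brain_mask, delay.shape)
    excl = (
        np.zeros(delay.shape, dtype=bool)
        if exclusion_mask is None
        else _as_bool_grid(exclusion_mask, delay.shape)
    )
    with np.errstate(invalid="ignore"):
        lesion = (delay > threshold_s) & brain & ~excl
    geom = geometry if geometry is not None else _geometry_of(brain_mask)
    return LesionMask(lesion.astype(np.uint8), geom, provenance="pwi_ttp")


def _geometry_of(mask):
    if isinstance(mask, LesionMask):
        return mask.geometry
    raise ValueError("pass geometry= when masks are raw arrays")


def svd_deconvolve(
    conc: ConcentrationSeries,
    aif: AifCurve,
    truncation_frac: float = SVD_TRUNCATION_FRAC,
    brain_mask=None,
) -> PerfusionMapSet:
    """Relative CBF/CBV/MTT maps by truncated-SVD deconvolution.

    The AIF is assembled into the lower-triangular discrete-convolution
    matrix A[i, j] = tr * aif[i - j]; singular values below
    ``truncation_frac`` times the largest are zeroed before inverting.
    Per voxel the residue estimate is r = A^+ C; CBF is its maximum, CBV
    the trapezoid area ratio to the AIF, and MTT = CBV / CBF (central
    volume theorem). Voxels with CBF below machine floor get NaN MTT.
    """
    if not 0 < truncation_frac < 1:
        raise ValueError("truncation_frac must lie in (0, 1)")
    n = conc.data.shape[-1]
    if aif.values.size != n:
        raise ValueError("AIF length must equal the frame count")
    if not np.any(aif.values != 0):
        raise ValueError("AIF is identically zero")
    tr = float(np.mean(np.diff(conc.time_axis_s)))

    a_mat = tr * toeplitz(aif.values, np.zeros(n))
    u, s, vt = np.linalg.svd(a_mat)
    s_inv = np.where(s >= truncation_frac * s[0], 1.0 / np.where(s == 0, 1.0, s), 0.0)
    pinv = (vt.T * s_inv) @ u.T

    shape3 = conc.data.shape[:3]
    brain = (
        np.ones(shape3, dtype=bool)
        if brain_mask is None
        else _as_bool_grid(brain_mask, shape3)
    )
    if conc.invalid_mask is not None:
        brain = brain & ~conc.invalid_mask

    flat = conc.data[brain]  # (n_voxels, n_frames)
    residue = flat @ pinv.T
    cbf_vals = residue.max(axis=-1)
    aif_area = np.trapezoid(aif.values, conc.time_axis_s)
    cbv_vals = np.trapezoid(flat, conc.time_axis_s, axis=-1) / aif_area

    cbf = np.full(shape3, np.nan)
    cbv = np.full(shape3, np.nan)
    mtt = np.full(shape3, np.nan)
    cbf[brain] = cbf_vals
    cbv[brain] = cbv_vals
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_vals = np.where(cbf_vals > _CBF_EPS, cbv_vals / cbf_vals, np.nan)
    mtt[brain] = mtt_vals
    return PerfusionMapSet(
        geometry=conc.geometry, cbf_rel=cbf, cbv_rel=cbv, mtt_s=mtt
    )


def mtt_lesion_mask(
    maps: PerfusionMapSet,
    reference_roi,
    rel_threshold: float = MTT_REL_THRESHOLD,
    brain_mask=None,
    exclusion_mask=None,
    min_valid_voxels: int = 10,
) -> LesionMask:
    """Threshold surrogate for visual MTT-lesion outlining.

    The lesion is where MTT exceeds ``rel_threshold`` times the mean MTT
    over the contralateral reference ROI.
    """
    if rel_threshold <= 1:
        raise ValueError("rel_threshold must exceed 1")
    mtt = maps.mtt_s
    if mtt is None:
        raise ValueError("map set has no MTT map; run svd_deconvolve first")
    roi = _as_bool_grid(reference_roi, mtt.shape)
    ref_vals = mtt[roi]
    ref_vals = ref_vals[np.isfinite(ref_vals)]
    if ref_vals.size < min_valid_voxels:
        raise ValueError(
            f"reference ROI has {ref_vals.size} valid-MTT voxels; "
            f"need at least {min_valid_voxels}"
        )
    brain = (
        np.ones(mtt.shape, dtype=bool)
        if brain_mask is None
        else _as_bool_grid(brain_mask, mtt.shape)
    )
    excl = (
        np.zeros(mtt.shape, dtype=bool)
        if exclusion_mask is None
        else _as_bool_grid(exclusion_mask, mtt.shape)
    )
    with np.errstate(invalid="ignore"):
        lesion = (mtt > rel_threshold * ref_vals.mean()) & brain & ~excl
    return LesionMask(lesion.astype(np.uint8), maps.geometry, provenance="pwi_mtt")
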