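"""Synthetic inputs with known ground truth.

Two generators live here:

* a geometric brain *phantom* plus a forward DSC signal model, so the
  perfusion-mapping and volumetry stages can be tested against exact
  kinetic ground truth without any acquisition; and
* a *cohort* simulator that reproduces the statistical structure of
  proximal-occlusion stroke: a large fixed territory at risk, a collateral
  grade that splits it into infarct core and penumbra (making the two
  inversely coupled), and whole-ml measurement rounding.

The phantom is deliberately non-anatomical: labelled blobs in one
hemisphere of a rectangular grid. Tissue curves follow the standard
indicator-dilution model C(t) = CBF * (AIF (*) R)(t - delay) with an
exponential residue R(t) = exp(-t/MTT) and a gamma-variate arterial input,
converted to gradient-echo signal via S(t) = S0 * exp(-k * TE * C(t)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (
    AcquisitionParams,
    DSCSeries,
    GeometryParams,
    InvalidKineticsError,
    LesionMask,
)
from .volumetry import CohortRecord, absolute_mismatch, relative_mismatch_pct

__all__ = [
    "Region",
    "RegionKinetics",
    "AifParams",
    "PhantomTruth",
    "CohortSimParams",
    "make_phantom",
    "gamma_variate_aif",
    "region_concentration",
    "simulate_dsc",
    "simulate_cohort",
    "DEFAULT_KINETICS",
]


class Region:
    """Integer labels of the phantom label map."""

    BACKGROUND = 0
    NORMAL_IPSI = 1
    NORMAL_CONTRA = 2
    CORE = 3
    PENUMBRA = 4
    ARTERY = 5


@dataclass(frozen=True)
class RegionKinetics:
    """Ground-truth kinetics of one phantom region.

    delay_s shifts the whole tissue curve (bolus arrival delay); mtt_s is
    the mean transit time of the exponential residue; cbv_rel the relative
    blood volume (area ratio tissue/AIF).
    """

    delay_s: float
    mtt_s: float
    cbv_rel: float

    def validate(self) -> None:
        if self.mtt_s <= 0:
            raise InvalidKineticsError(f"mtt_s must be positive, got {self.mtt_s}")
        if self.cbv_rel < 0:
            raise InvalidKineticsError(f"cbv_rel must be non-negative, got {self.cbv_rel}")

    @property
    def cbf_rel(self) -> float:
        return self.cbv_rel / self.mtt_s


#: Defaults: normal tissue ~4 s MTT; penumbra delayed and slowed but still
#: substantially perfused; core severely delayed with low blood volume.
DEFAULT_KINETICS: Dict[int, RegionKinetics] = {
    Region.NORMAL_IPSI: RegionKinetics(delay_s=0.0, mtt_s=4.0, cbv_rel=1.0),
    Region.NORMAL_CONTRA: RegionKinetics(delay_s=0.0, mtt_s=4.0, cbv_rel=1.0),
    Region.PENUMBRA: RegionKinetics(delay_s=6.0, mtt_s=10.0, cbv_rel=0.8),
    Region.CORE: RegionKinetics(delay_s=8.0, mtt_s=12.0, cbv_rel=0.3),
    Region.ARTERY: RegionKinetics(delay_s=0.0, mtt_s=1.5, cbv_rel=1.0),
}


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate arterial input A(t) = a (t-t0)^alpha exp(-(t-t0)/beta).

    t0 defaults to injection delay + 2 s (transit from injection site);
    the amplitude is normalised so the peak value is 1.
    """

    alpha: float = 3.0
    beta_s: float = 1.5
    arrival_offset_s: float = 2.0


@dataclass
class PhantomTruth:
    """Labelled phantom with per-region kinetic ground truth."""

    label_map: np.ndarray
    region_kinetics: Dict[int, RegionKinetics]
    geometry: GeometryParams

    def __post_init__(self) -> None:
        labels = set(np.unique(self.label_map).tolist()) - {Region.BACKGROUND}
        missing = labels - set(self.region_kinetics)
        if missing:
            raise ValueError(f"labelled regions without kinetics: {sorted(missing)}")
        for kin in self.region_kinetics.values():
            kin.validate()

    def region_mask(self, label: int, provenance: str = "manual") -> LesionMask:
        return LesionMask(
            (self.label_map == label).astype(np.uint8), self.geometry, provenance
        )

    def region_volume_ml(self, label: int) -> float:
        return float(
            np.count_nonzero(self.label_map == label) * self.geometry.voxel_volume_ml
        )

    def brain_mask(self) -> np.ndarray:
        return self.label_map != Region.BACKGROUND


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic stroke cohort.

    The territory at risk of a terminal-ICA/proximal-MCA occlusion is large
    and roughly fixed (mean 220 ml, comfortably over 200 ml); the collateral
    grade f in (0, 1) determines which fraction is spared from infarction,
    coupling core = (1-f)*T and hypoperfused ~ T inversely. Measured volumes
    are reported rounded to whole ml, as clinical tables do.
    """

    n_patients: int = 200
    territory_ml_mean: float = 220.0
    territory_ml_sd: float = 40.0
    collateral_alpha: float = 2.0
    collateral_beta: float = 2.0
    onset_window_h: Tuple[float, float] = (0.5, 24.0)
    measurement_cv: float = 0.10
    rounding_ml: float = 1.0
    zero_dwi_pct_cap: float = 10000.0
    perf_modality: str = "TTP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.territory_ml_mean <= 0:
            raise ValueError("territory_ml_mean must be positive")
        if self.collateral_alpha <= 0 or self.collateral_beta <= 0:
            raise ValueError("collateral shape parameters must be positive")
        if not 0 < self.onset_window_h[0] <= self.onset_window_h[1]:
            raise ValueError("onset window must satisfy 0 < min <= max")


# ---------------------------------------------------------------------------
# phantom construction


def make_phantom(
    geometry: GeometryParams,
    core_fraction: float,
    territory_ml: float,
    kinetics: Optional[Dict[int, RegionKinetics]] = None,
) -> PhantomTruth:
    """Build a labelled phantom with a territory of given volume in one hemisphere.

    The affected (ipsilateral) hemisphere is the low-x half of the grid.
    The territory (core + penumbra) is the set of in-hemisphere voxels
    nearest (in physical mm) to a territory centre, so its voxel-count
    volume matches ``territory_ml`` to within one voxel; the core is the
    innermost ``core_fraction`` of it. A contralateral hemisphere and a
    small arterial block (AIF source) are always present.
    """
    if not 0 <= core_fraction <= 1:
        raise ValueError("core_fraction must lie in [0, 1]")
    if territory_ml <= 0:
        raise ValueError("territory_ml must be positive")
    kin = dict(DEFAULT_KINETICS if kinetics is None else kinetics)

    nx, ny, nz = geometry.grid_shape
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    # one-voxel background shell (non-brain) where the grid allows it
    interior = np.zeros_like(labels, dtype=bool)
    sl = tuple(slice(1, -1) if n >= 3 else slice(None) for n in (nx, ny, nz))
    interior[sl] = True

    half = nx // 2
    ipsi = np.zeros_like(interior)
    ipsi[:half] = True
    labels[interior & ipsi] = Region.NORMAL_IPSI
    labels[interior & ~ipsi] = Region.NORMAL_CONTRA

    # arterial ROI: small block near the anterior edge of the ipsilateral side
    ax = slice(1, min(3, nx))
    ay = slice(1, min(3, ny))
    az = slice(nz // 2, nz // 2 + 1)
    artery = np.zeros_like(interior)
    artery[ax, ay, az] = interior[ax, ay, az]
    labels[artery] = Region.ARTERY

    candidates = interior & ipsi & ~artery
    vox_ml = geometry.voxel_volume_ml
    n_total = int(round(territory_ml / vox_ml))
    n_core = int(round(core_fraction * territory_ml / vox_ml))
    n_avail = int(np.count_nonzero(candidates))
    if n_total > n_avail:
        raise ValueError(
            f"territory does not fit: {territory_ml} ml needs {n_total} voxels, "
            f"only {n_avail} available in the hemisphere"
        )

    # physical distance from a centre deep in the ipsilateral hemisphere
    ix, iy, iz = np.nonzero(candidates)
    centre = np.array([half / 2.0, ny / 2.0, nz / 2.0])
    sp = np.array(
        [geometry.in_plane_spacing_mm, geometry.in_plane_spacing_mm, geometry.slice_spacing_mm]
    )
    d2 = (
        ((ix - centre[0]) * sp[0]) ** 2
        + ((iy - centre[1]) * sp[1]) ** 2
        + ((iz - centre[2]) * sp[2]) ** 2
    )
    order = np.lexsort((iz, iy, ix, d2))  # distance, ties broken by index
    chosen = order[:n_total]
    core_idx = chosen[:n_core]
    pen_idx = chosen[n_core:]
    labels[ix[pen_idx], iy[pen_idx], iz[pen_idx]] = Region.PENUMBRA
    labels[ix[core_idx], iy[core_idx], iz[core_idx]] = Region.CORE

    present = set(np.unique(labels).tolist()) - {Region.BACKGROUND}
    return PhantomTruth(labels, {k: v for k, v in kin.items() if k in present}, geometry)


# ---------------------------------------------------------------------------
# forward DSC model


def gamma_variate_aif(
    t_s: np.ndarray, t0_s: float, params: AifParams = AifParams()
) -> np.ndarray:
    """Peak-normalised gamma-variate bolus curve, zero before arrival t0."""
    t = np.asarray(t_s, dtype=float)
    dt = t - t0_s
    out = np.zeros_like(t)
    pos = dt > 0
    peak = (params.alpha * params.beta_s) ** params.alpha * math.exp(-params.alpha)
    out[pos] = dt[pos] ** params.alpha * np.exp(-dt[pos] / params.beta_s) / peak
    return out


def region_concentration(
    kinetics: RegionKinetics,
    acq: AcquisitionParams,
    aif_params: AifParams = AifParams(),
    oversample: int = 20,
) -> np.ndarray:
    """Noise-free tissue concentration curve of one region on the frame grid.

    The convolution CBF * (AIF (*) exp(-t/MTT)) is evaluated on a grid
    oversampled ``oversample``-fold relative to TR, then resampled at the
    frame times shifted by the bolus-arrival delay, so quadrature error and
    delay quantisation stay well below the frame spacing.
    """
    kinetics.validate()
    t0 = acq.injection_delay_s + aif_params.arrival_offset_s
    dt = acq.tr_s / oversample
    t_end = acq.n_frames * acq.tr_s + kinetics.delay_s + acq.tr_s
    t_fine = np.arange(0.0, t_end, dt)
    aif = gamma_variate_aif(t_fine, t0, aif_params)
    residue = np.exp(-t_fine / kinetics.mtt_s)
    conv = np.convolve(aif, residue)[: t_fine.size] * dt
    c_fine = kinetics.cbf_rel * conv
    frame_t = acq.time_axis_s - kinetics.delay_s
    return np.interp(frame_t, t_fine, c_fine, left=0.0, right=c_fine[-1])


def simulate_dsc(
    phantom: PhantomTruth,
    acq: AcquisitionParams = AcquisitionParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
    s0: float = 100.0,
    k_dsc: float = 1.0,
    aif_params: AifParams = AifParams(),
) -> DSCSeries:
    """Forward-simulate the DSC signal of a phantom.

    Arterial voxels emit the input function itself (that is what an AIF ROI
    measures); every tissue region follows the convolution model. Gaussian
    noise of standard deviation ``noise_sd`` is added on the signal scale;
    identical seeds give identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t0 = acq.injection_delay_s + aif_params.arrival_offset_s
    curves: Dict[int, np.ndarray] = {}
    for label, kin in phantom.region_kinetics.items():
        if label == Region.ARTERY:
            curves[label] = gamma_variate_aif(acq.time_axis_s, t0, aif_params)
        else:
            curves[label] = region_concentration(kin, acq, aif_params)

    shape = tuple(phantom.geometry.grid_shape) + (acq.n_frames,)
    conc = np.zeros(shape)
    for label, curve in curves.items():
        conc[phantom.label_map == label] = curve
    signal = s0 * np.exp(-k_dsc * acq.te_s * conc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=shape)
    return DSCSeries(signal, acq, phantom.geometry)


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(params: CohortSimParams) -> List[CohortRecord]:
    """Draw a synthetic cohort with inversely coupled core and penumbra.

    Per patient: territory T ~ Normal(mean, sd) (truncated at 20 ml),
    collateral grade f ~ Beta(alpha, beta); the DWI core measures
    (1 - f) * T and the hypoperfused (PWI) lesion measures T, each with
    multiplicative lognormal measurement noise, then rounded to the
    reporting precision. Mismatch fields are computed from the rounded
    volumes by the volumetry rules, never independently.
    """
    rng = np.random.default_rng(params.seed)
    records: List[CohortRecord] = []
    sigma = math.sqrt(math.log(1.0 + params.measurement_cv**2))
    for i in range(params.n_patients):
        territory = max(
            20.0, rng.normal(params.territory_ml_mean, params.territory_ml_sd)
        )
        collateral = rng.beta(params.collateral_alpha, params.collateral_beta)
        u = rng.lognormal(-sigma**2 / 2.0, sigma)
        v = rng.lognormal(-sigma**2 / 2.0, sigma)
        hours = rng.uniform(*params.onset_window_h)

        dwi = (1.0 - collateral) * territory * u
        perf = territory * v
        r = params.rounding_ml
        dwi_r = round(dwi / r) * r
        perf_r = round(perf / r) * r
        mismatch = absolute_mismatch(dwi_r, max(perf_r, dwi_r))
        if dwi_r > 0:
            pct = relative_mismatch_pct(dwi_r, mismatch)
        else:
            pct = params.zero_dwi_pct_cap if mismatch > 0 else 0.0
        records.append(
            CohortRecord(
                patient_id=f"S{i + 1:03d}",
                hours_after_onset=round(hours, 1),
                dwi_vol_ml=dwi_r,
                perf_vol_ml=perf_r,
                perf_modality=params.perf_modality,
                mismatch_vol_ml=mismatch,
                mismatch_pct=pct,
            )
        )
    return records
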