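"""File formats and packaged fixtures.

Cohort tables travel as delimited text with a fixed header; images as
NIfTI with the grid geometry in the header affine; reports as JSON with
deterministic field order (missing p-values serialize as null, never 0).
Two cohort fixtures ship with the package — the retrospective (MTT, 68
patients) and prospective (TTP, 48 patients) per-patient tables at their
printed whole-ml precision — with pinned checksums so silent edits fail
loudly.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AcquisitionParams, DSCSeries, GeometryParams, LesionMask
from .volumetry import CohortRecord

__all__ = [
    "COHORT_COLUMNS",
    "FIXTURE_SHA256",
    "fixture_path",
    "fixture_sha256",
    "load_cohort",
    "load_fixture_cohort",
    "save_cohort",
    "save_report",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_series_nifti",
    "load_series_nifti",
    "PipelineConfig",
]

COHORT_COLUMNS = [
    "patient_id",
    "hours_after_onset",
    "dwi_vol_ml",
    "perf_vol_ml",
    "perf_modality",
    "mismatch_vol_ml",
    "mismatch_pct",
    "inconsistent_flag",
]

#: Pinned digests of the packaged cohort fixtures; tests fail if a fixture
#: is edited without updating these.
FIXTURE_SHA256 = {
    "table3_retrospective.csv": "1b5e3e5f4300219ffa386dba0db26cc0170bb7c361f4192e34a0328fd218a4d3",
    "table4_prospective.csv": "7850de6bb9469bb2aba69087cfba6e984a29f1530a5561ffefc0ce7f070c342a",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    ref = resources.files("strokemismatch.data").joinpath(name)
    with resources.as_file(ref) as p:
        return Path(p)


def fixture_sha256(name: str) -> str:
    return hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()


def load_cohort(path) -> List[CohortRecord]:
    """Load a cohort table into typed records, rejecting malformed rows.

    Errors name the offending rows (1-based, excluding comments/header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, comment="#", dtype={"patient_id": str}, float_precision="round_trip"
    )
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        problems.append(f"duplicate patient_id values: {dupes}")
    for col in ("hours_after_onset", "dwi_vol_ml", "perf_vol_ml", "mismatch_vol_ml",
                "mismatch_pct"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            problems.append(f"non-numeric {col} in rows {[i + 1 for i in bad]}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                CohortRecord(
                    patient_id=str(row["patient_id"]),
                    hours_after_onset=float(row["hours_after_onset"]),
                    dwi_vol_ml=float(row["dwi_vol_ml"]),
                    perf_vol_ml=float(row["perf_vol_ml"]),
                    perf_modality=str(row["perf_modality"]),
                    mismatch_vol_ml=float(row["mismatch_vol_ml"]),
                    mismatch_pct=float(row["mismatch_pct"]),
                    inconsistent=bool(int(row["inconsistent_flag"])),
                )
            )
        except ValueError as exc:
            problems.append(f"row {i + 1}: {exc}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return records


def load_fixture_cohort(which: str) -> List[CohortRecord]:
    """Load a packaged cohort: 'retrospective' or 'prospective'."""
    name = {
        "retrospective": "table3_retrospective.csv",
        "prospective": "table4_prospective.csv",
    }[which]
    return load_cohort(fixture_path(name))


def save_cohort(records: Sequence[CohortRecord], path) -> Path:
    """Write records as a cohort CSV that round-trips through load_cohort."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "hours_after_onset": r.hours_after_onset,
                "dwi_vol_ml": r.dwi_vol_ml,
                "perf_vol_ml": r.perf_vol_ml,
                "perf_modality": r.perf_modality,
                "mismatch_vol_ml": r.mismatch_vol_ml,
                "mismatch_pct": r.mismatch_pct,
                "inconsistent_flag": int(r.inconsistent),
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN -> explicit null
        return None
    return obj


def save_report(report: Dict, path) -> Path:
    """Serialize a report dict as JSON with deterministic ordering.

    Insertion order is preserved (the report builders construct their dicts
    deterministically), so identical inputs give byte-identical files.
    Not-applicable values serialize as null.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(_jsonify(report), indent=2, allow_nan=False)
    path.write_text(text + "\n")
    return path


# ---------------------------------------------------------------------------
# NIfTI


def save_mask_nifti(mask: LesionMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.geometry.affine())
    nib.save(img, str(path))
    return path


def load_mask_nifti(path, provenance: str = "manual") -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    geom = GeometryParams(float(zooms[0]), float(zooms[2]), tuple(data.shape))
    return LesionMask((data > 0).astype(np.uint8), geom, provenance)


def save_series_nifti(series: DSCSeries, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.geometry.affine())
    img.header.set_zooms(
        (
            series.geometry.in_plane_spacing_mm,
            series.geometry.in_plane_spacing_mm,
            series.geometry.slice_spacing_mm,
            series.acq.tr_s,
        )
    )
    nib.save(img, str(path))
    return path


def load_series_nifti(path, acq: AcquisitionParams) -> DSCSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    geom = GeometryParams(float(zooms[0]), float(zooms[2]), tuple(data.shape[:3]))
    return DSCSeries(data, acq, geom)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Single home for every tunable threshold and simulation default."""

    ttp_delay_threshold_s: float = 4.0
    dwi_cutoffs_ml: Tuple[float, ...] = (70.0, 100.0)
    mismatch_cutoff_pct: float = 100.0
    truncation_frac: float = 0.2
    mtt_rel_threshold: float = 1.5
    seed: int = 0
    output_dir: str = "results"
    acquisition: Dict = field(default_factory=dict)
    geometry: Dict = field(default_factory=dict)
    simulation: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ttp_delay_threshold_s <= 0 or self.mismatch_cutoff_pct <= 0:
            raise ValueError("thresholds must be positive")
        if any(c <= 0 for c in self.dwi_cutoffs_ml):
            raise ValueError("DWI cutoffs must be positive")
        if not 0 < self.truncation_frac < 1:
            raise ValueError("truncation_frac must lie in (0, 1)")
        if self.mtt_rel_threshold <= 1:
            raise ValueError("mtt_rel_threshold must exceed 1")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["dwi_cutoffs_ml"] = list(d["dwi_cutoffs_ml"])
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["dwi_cutoffs_ml"] = tuple(d.get("dwi_cutoffs_ml", (70.0, 100.0)))
        return cls(**d)
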