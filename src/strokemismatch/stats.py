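"""Cohort statistics: Fisher's exact test, Spearman rank correlation,
group summaries and the headline report.

Conventions (fixed here because the source analyses name none):

* Two-tailed Fisher p by the point-probability (Irwin) rule — the sum of
  hypergeometric probabilities, over all tables with the observed margins,
  of every table no more probable than the observed one. Evaluated through
  log-pmf accumulation, so it is exact to float precision for any counts.
* Spearman rho is the tie-corrected (midrank Pearson) coefficient. The
  two-tailed p uses the exact permutation distribution for n <= 9 and the
  t approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 d.f. otherwise;
  |rho| = 1 always falls back to the exact permutation tail so p stays
  positive.
* Quartiles use linear interpolation (type 7); means come with
  SEM = sd / sqrt(n) using the n-1 standard deviation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .volumetry import (
    CohortRecord,
    DWI_CUTOFF_ML,
    DWI_CUTOFF_SECONDARY_ML,
    MISMATCH_CUTOFF_PCT,
    classify,
)

__all__ = [
    "ContingencyTable2x2",
    "StatsResult",
    "build_contingency",
    "fisher_exact_two_tailed",
    "spearman_two_tailed",
    "median_iqr",
    "group_comparison",
    "headline_report",
]

#: Findings are called significant below this two-tailed p.
SIGNIFICANCE_LEVEL = 0.05

#: Relative slack when comparing point probabilities in the Irwin rule,
#: guarding against ties lost to floating-point rounding.
_PMF_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = DWI size class (<= cutoff / > cutoff) and
    columns = mismatch class (>= cutoff% / < cutoff%)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class StatsResult:
    statistic: float
    p_value: float
    n: int
    method: str


def build_contingency(
    records: Sequence[CohortRecord],
    dwi_cutoff_ml: float = DWI_CUTOFF_ML,
    mismatch_cutoff_pct: float = MISMATCH_CUTOFF_PCT,
) -> ContingencyTable2x2:
    """Cross-classify patients by DWI size and large-mismatch status."""
    if not records:
        raise ValueError("record list is empty")
    a = b = c = d = 0
    for rec in records:
        if rec.mismatch_pct is None or (
            isinstance(rec.mismatch_pct, float) and math.isnan(rec.mismatch_pct)
        ):
            raise ValueError(f"record {rec.patient_id} has no mismatch_pct")
        size_class, large = classify(
            rec.dwi_vol_ml, rec.mismatch_pct, dwi_cutoff_ml, mismatch_cutoff_pct
        )
        if size_class == "le_cutoff":
            a, b = (a + 1, b) if large else (a, b + 1)
        else:
            c, d = (c + 1, d) if large else (c, d + 1)
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> StatsResult:
    """Two-tailed Fisher's exact test (point-probability rule).

    Degenerate margins (an empty row or column) give p = 1 by convention.
    The statistic reported is the sample odds ratio ad/bc (inf when bc=0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    row1, col1 = a + b, a + c
    if row1 in (0, n) or col1 in (0, n):
        p = 1.0
    else:
        lo = max(0, row1 + col1 - n)
        hi = min(row1, col1)
        support = np.arange(lo, hi + 1)
        logpmf = sps.hypergeom.logpmf(support, n, col1, row1)
        log_obs = sps.hypergeom.logpmf(a, n, col1, row1)
        keep = logpmf <= log_obs + _PMF_REL_TOL
        p = float(min(1.0, np.exp(logpmf[keep]).sum()))
        if p > 1.0 - 1e-12:  # full support summed; absorb accumulation error
            p = 1.0
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return StatsResult(odds, p, n, "fisher_exact_two_tailed")


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((rx * ry).sum() / denom)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-tailed p from the full permutation distribution of rho.

    Vectorised over all n! permutations (n <= 9 keeps this below ~30 MB).
    """
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = math.sqrt(float((rxc**2).sum())) * np.sqrt((ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    thresh = abs(rho_obs) - 1e-12
    return float((np.abs(rhos) >= thresh).mean())


def spearman_two_tailed(
    x: Sequence[float], y: Sequence[float], exact_n_max: int = 9
) -> StatsResult:
    """Tie-corrected Spearman rank correlation with a two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= exact_n_max or abs(rho) >= 1.0 - 1e-12:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return StatsResult(rho, min(p, 1.0), n, "spearman_two_tailed")


def median_iqr(values: Sequence[float]) -> Tuple[float, float]:
    """Median and interquartile range with linear (type-7) interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1)


def _mean_sem(values: np.ndarray) -> Tuple[float, float]:
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, sem


def group_comparison(
    records: Sequence[CohortRecord],
    dwi_cutoff_ml: float = DWI_CUTOFF_ML,
    mismatch_cutoff_pct: float = MISMATCH_CUTOFF_PCT,
) -> Dict:
    """Per-size-group summary (n, median/IQR volumes, large-mismatch counts)
    with rank-sum p for continuous variables and Fisher p for proportions."""
    if not records:
        raise ValueError("record list is empty")
    le = [r for r in records if r.dwi_vol_ml <= dwi_cutoff_ml]
    gt = [r for r in records if r.dwi_vol_ml > dwi_cutoff_ml]

    def summarise(group: List[CohortRecord]) -> Dict:
        if not group:
            return {"n": 0}
        dwi = np.array([r.dwi_vol_ml for r in group])
        mm = np.array([r.mismatch_vol_ml for r in group])
        pct = np.array([r.mismatch_pct for r in group])
        n_large = int((pct >= mismatch_cutoff_pct).sum())
        return {
            "n": len(group),
            "dwi_vol_median_iqr": median_iqr(dwi),
            "mismatch_vol_median_iqr": median_iqr(mm),
            "mismatch_pct_median_iqr": median_iqr(pct),
            "n_large_mismatch": n_large,
            "prop_large_mismatch": n_large / len(group),
        }

    out = {
        "dwi_cutoff_ml": dwi_cutoff_ml,
        "all": summarise(list(records)),
        "le_cutoff": summarise(le),
        "gt_cutoff": summarise(gt),
    }
    if le and gt:
        def ranksum_p(attr):
            x = [getattr(r, attr) for r in le]
            y = [getattr(r, attr) for r in gt]
            return float(sps.ranksums(x, y).pvalue)

        out["p_values"] = {
            "dwi_vol": ranksum_p("dwi_vol_ml"),
            "mismatch_vol": ranksum_p("mismatch_vol_ml"),
            "mismatch_pct": ranksum_p("mismatch_pct"),
            "large_mismatch": fisher_exact_two_tailed(
                build_contingency(records, dwi_cutoff_ml, mismatch_cutoff_pct)
            ).p_value,
        }
    else:
        out["p_values"] = None
    return out


def _cohort_block(records: Sequence[CohortRecord], cutoffs: Sequence[float]) -> Dict:
    hours = [r.hours_after_onset for r in records]
    dwi = [r.dwi_vol_ml for r in records]
    mm = [r.mismatch_vol_ml for r in records]
    block: Dict = {"n": len(records), "by_cutoff": {}}
    for cutoff in cutoffs:
        table = build_contingency(records, cutoff, MISMATCH_CUTOFF_PCT)
        fisher = fisher_exact_two_tailed(table)
        le_dwi = np.array([r.dwi_vol_ml for r in records if r.dwi_vol_ml <= cutoff])
        mean, sem = _mean_sem(le_dwi)
        block["by_cutoff"][f"{cutoff:g}"] = {
            "n_le": table.a + table.b,
            "n_gt": table.c + table.d,
            "large_mismatch_le": table.a,
            "large_mismatch_gt": table.c,
            "prop_large_le": table.a / (table.a + table.b) if table.a + table.b else None,
            "prop_large_gt": table.c / (table.c + table.d) if table.c + table.d else None,
            "fisher_p": fisher.p_value,
            "mean_dwi_le_ml": mean,
            "sem_dwi_le_ml": sem,
        }
    sp_dwi = spearman_two_tailed(hours, dwi)
    sp_mm = spearman_two_tailed(hours, mm)
    block["spearman_hours_vs_dwi"] = {"rho": sp_dwi.statistic, "p": sp_dwi.p_value}
    block["spearman_hours_vs_mismatch"] = {"rho": sp_mm.statistic, "p": sp_mm.p_value}
    return block


def headline_report(
    retro_records: Sequence[CohortRecord],
    prosp_records: Sequence[CohortRecord],
    cutoffs: Sequence[float] = (DWI_CUTOFF_ML, DWI_CUTOFF_SECONDARY_ML),
) -> Dict:
    """The study-level summary: group sizes, large-mismatch counts and
    Fisher p at both DWI cutoffs, plus Spearman correlations against time
    and the mean/SEM DWI volume of the small-lesion groups."""
    return {
        "retrospective": _cohort_block(retro_records, cutoffs),
        "prospective": _cohort_block(prosp_records, cutoffs),
        "significance_level": SIGNIFICANCE_LEVEL,
    }
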