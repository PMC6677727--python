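"""Coverage-derived relative copy number, D-loop coverage comparison, and
closed-form calculators for blood admixture and replication counts."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .genome import RegionMap


def relative_copy_number(depth_profile: np.ndarray,
                         correction_ratio: float = 1.0 / 150.0) -> float:
    """Mean sequencing depth times the correction ratio converting relative
    capture-enrichment coverage to absolute per-cell copy number."""
    depth = np.asarray(depth_profile, dtype=float)
    if depth.size == 0:
        raise ValueError("empty coverage profile")
    if depth.sum() == 0:
        return 0.0
    return float(depth.mean() * correction_ratio)


def dloop_coverage_ratio(depth_profile: np.ndarray,
                         region_map: RegionMap | None = None) -> float:
    """Ratio of mean D-loop depth to mean depth over the rest of the genome."""
    rmap = region_map if region_map is not None else RegionMap()
    depth = np.asarray(depth_profile, dtype=float)
    mask = rmap.dloop_mask()
    if depth.size != mask.size:
        raise ValueError("profile length does not match the genome")
    din, dout = depth[mask], depth[~mask]
    if din.size == 0 or dout.size == 0 or dout.mean() == 0:
        raise ValueError("empty region")
    return float(din.mean() / dout.mean())


def cohort_dloop_test(depth_profiles, region_map: RegionMap | None = None) -> dict:
    """Per-sample D-loop/rest coverage ratios plus a two-sided cohort-level
    test of ratio == 1 (Wilcoxon signed-rank on ratio - 1)."""
    ratios = np.array([dloop_coverage_ratio(p, region_map)
                       for p in depth_profiles])
    if np.allclose(ratios, 1.0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(ratios - 1.0, alternative="two-sided")[1])
    return {"ratios": ratios, "mean_ratio": float(ratios.mean()), "p": p}


def blood_admixture_threshold(cell_ratio: float, copy_factor: float,
                              liver_maf_min: float = 0.025) -> dict:
    """Minimum blood MAF that could produce a liver heteroplasmy call by
    blood admixture alone. Genome ratio R = cell_ratio x copy_factor;
    threshold = liver_maf_min x R, capped at 1 with an impossibility flag."""
    if cell_ratio <= 0 or copy_factor <= 0 or liver_maf_min <= 0:
        raise ValueError("inputs must be positive")
    genome_ratio = cell_ratio * copy_factor
    raw = liver_maf_min * genome_ratio
    return {"genome_ratio": genome_ratio,
            "threshold": min(raw, 1.0),
            "impossible": raw > 1.0}


def replications_to_cells(n_cells) -> int:
    """Smallest integer k with 2**k >= n_cells (cell doublings from one)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(n_cells, int):
        return max(0, (n_cells - 1).bit_length())
    k = math.ceil(math.log2(n_cells) - 1e-12)
    return max(0, k)


def mtdna_turnover_cycles(half_life_days: float, copy_number: float,
                          horizon_days: float) -> dict:
    """Expected original molecules surviving exponential turnover and
    whether complete replacement (< 1 survivor) occurs within the horizon."""
    if half_life_days <= 0 or copy_number <= 0 or horizon_days < 0:
        raise ValueError("inputs must be positive (horizon >= 0)")
    survivors = copy_number * 2.0 ** (-horizon_days / half_life_days)
    return {"survivors": survivors, "complete_replacement": survivors < 1.0}
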