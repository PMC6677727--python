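"""Sharing tables, MAF correlations, and permutation/subsampling
significance procedures for paired-tissue heteroplasmy comparisons.

Permutation p-values use the add-one estimator (b + 1) / (n_perm + 1) and
are therefore never zero. All stochastic procedures take an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import classify_region
from .cohort import Cohort, FWD, REV
from .calling import CallResult
from .genome import ALLELES


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_perm: float
    n_perm: int
    seed: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: Pearson r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def pearson_r_perm(x, y, n_perm: int = 1000, seed: int = 0,
                   two_sided: bool = True) -> CorrelationResult:
    """Pearson r with a permutation p-value obtained by shuffling *y*
    relative to *x*; two-sided compares |r| >= |r_obs|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        r = _pearson(x, rng.permutation(y))
        if (abs(r) >= abs(r_obs)) if two_sided else (r >= r_obs):
            b += 1
    return CorrelationResult(r_obs, int(x.size), (b + 1) / (n_perm + 1),
                             n_perm, seed)


def build_maf_pairs(result: CallResult, cohort: Cohort, tissue_a: str,
                    tissue_b: str) -> pd.DataFrame:
    """One row per (individual, position) called heteroplasmic in at least
    one of the two tissues. The uncalled tissue contributes its raw
    blood-oriented MAF, even below the calling threshold."""
    calls = result.calls
    passed = calls[calls["passed"] & calls["tissue"].isin([tissue_a, tissue_b])]
    rows = []
    for (ind, pos), grp in passed.groupby(["individual", "pos"]):
        tissues = set(grp["tissue"])
        major = grp["major"].iloc[0]
        mafs = {}
        for t in (tissue_a, tissue_b):
            if (ind, t) not in cohort.counts:
                mafs = None
                break
            sub = grp[grp["tissue"] == t]
            if len(sub):
                mafs[t] = float(sub["maf"].iloc[0])
            else:
                mafs[t] = raw_maf(cohort.counts[(ind, t)], pos, major)
        if mafs is None:
            continue
        region = classify_region(pos, cohort.genome.region_map) \
            if cohort.genome.length == 16_569 else None
        rows.append({
            "individual": ind, "pos": int(pos),
            "maf_a": mafs[tissue_a], "maf_b": mafs[tissue_b],
            "shared": tissue_a in tissues and tissue_b in tissues,
            "region": (region.region if region else
                       ("control" if pos <= cohort.genome.length // 2
                        else "noncontrol")),
            "dloop": region.dloop if region else False,
        })
    return pd.DataFrame(rows, columns=["individual", "pos", "maf_a", "maf_b",
                                       "shared", "region", "dloop"])


def raw_maf(arr: np.ndarray, pos: int, blood_major: str) -> float:
    """Blood-oriented MAF from raw counts (most frequent non-major allele)."""
    row = arr[pos - 1]
    combined = np.asarray(row[FWD] + row[REV], dtype=float)
    depth = combined.sum()
    if depth == 0:
        return 0.0
    major_i = ALLELES.index(blood_major)
    cand = [i for i in range(4) if i != major_i]
    return float(max(combined[i] for i in cand) / depth)


def sharing_table(pairs: pd.DataFrame, by: str = "region",
                  categories=("control", "noncontrol")) -> np.ndarray:
    """2x2 table [[shared_cat1, shared_cat2], [notshared_cat1, notshared_cat2]]."""
    tab = np.zeros((2, 2), dtype=int)
    for j, cat in enumerate(categories):
        sub = pairs[pairs[by] == cat]
        tab[0, j] = int(sub["shared"].sum())
        tab[1, j] = int((~sub["shared"]).sum())
    return tab


def sharing_fisher(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of hypergeometric
    probabilities of tables no more probable than the observed one).
    Zero margins give p = 1 by convention."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


def shared_fraction(table, column: int) -> float:
    """Percentage of category *column* (0 or 1) that is shared."""
    tab = np.asarray(table, dtype=float)
    total = tab[:, column].sum()
    if total == 0:
        raise ValueError("zero category total")
    return float(100.0 * tab[0, column] / total)


def partition_permutation_test(pairs: pd.DataFrame, n_group1: int,
                               n_perm: int = 1000, seed: int = 0,
                               one_sided: bool = True) -> dict:
    """Observed Δr = r(group1) - r(group2) where group1 is the first
    ``n_group1`` rows after sorting by the group label implied by the
    caller. The null randomly partitions all pairs into sets of the
    observed sizes. One-sided by default (Δr >= observed)."""
    x = pairs["maf_a"].to_numpy(float)
    y = pairs["maf_b"].to_numpy(float)
    n = x.size
    if not 0 < n_group1 < n:
        raise ValueError("degenerate partition")
    if "group" in pairs:
        mask = (pairs["group"] == 1).to_numpy()
        if mask.sum() != n_group1:
            raise ValueError("n_group1 disagrees with group labels")
    else:
        mask = np.zeros(n, dtype=bool)
        mask[:n_group1] = True
    d_obs = _pearson(x[mask], y[mask]) - _pearson(x[~mask], y[~mask])
    rng = np.random.default_rng(seed)
    b = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        m = np.zeros(n, dtype=bool)
        m[perm[:n_group1]] = True
        try:
            d = _pearson(x[m], y[m]) - _pearson(x[~m], y[~m])
        except ValueError:
            continue
        if (d >= d_obs) if one_sided else (abs(d) >= abs(d_obs)):
            b += 1
    return {"delta_r": d_obs, "p": (b + 1) / (n_perm + 1), "n_perm": n_perm,
            "seed": seed}


def partition_test_by_region(pairs: pd.DataFrame, n_perm: int = 1000,
                             seed: int = 0) -> dict:
    """Control vs non-control Δr partition test (control is group 1)."""
    ordered = pd.concat([pairs[pairs["region"] == "control"],
                         pairs[pairs["region"] != "control"]],
                        ignore_index=True)
    n1 = int((pairs["region"] == "control").sum())
    return partition_permutation_test(ordered, n1, n_perm=n_perm, seed=seed)


def subsample_correlation_test(pairs: pd.DataFrame, target_sites,
                               n_perm: int = 1000, seed: int = 0) -> dict:
    """Compare r at the target sites against r of random same-size
    subsamples of the full pair pool. p = add-one fraction of subsamples
    with r >= r(target)."""
    target_mask = pairs["pos"].isin(set(target_sites)).to_numpy()
    k = int(target_mask.sum())
    n = len(pairs)
    if k == 0:
        raise ValueError("no pairs at target sites")
    if k > n:
        raise ValueError("subsample larger than population")
    x = pairs["maf_a"].to_numpy(float)
    y = pairs["maf_b"].to_numpy(float)
    r_target = _pearson(x[target_mask], y[target_mask])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    b = 0
    idx = np.arange(n)
    for i in range(n_perm):
        pick = rng.choice(idx, size=k, replace=False)
        null[i] = _pearson(x[pick], y[pick])
        # ties (within FP jitter of summation order) count as >=
        if null[i] >= r_target - 1e-12:
            b += 1
    return {"r_target": r_target, "n_target": k, "p": (b + 1) / (n_perm + 1),
            "null_r": null, "n_perm": n_perm, "seed": seed}


def maf_diff_vs_age(pairs: pd.DataFrame, ages: pd.Series, n_perm: int = 1000,
                    seed: int = 0, min_individuals_per_site: int = 20) -> dict:
    """Pearson r of |ΔMAF| vs age among shared pairs, overall per region and
    per frequently heteroplasmic site (>= ``min_individuals_per_site``
    occurrences)."""
    shared = pairs[pairs["shared"]].copy()
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared pairs")
    shared["dmaf"] = (shared["maf_a"] - shared["maf_b"]).abs()
    shared["age"] = shared["individual"].map(ages).astype(float)
    out = {"per_region": {}, "per_site": {}}
    for region, grp in shared.groupby("region"):
        if len(grp) >= 3:
            out["per_region"][region] = pearson_r_perm(
                grp["dmaf"], grp["age"], n_perm=n_perm, seed=seed)
    counts = shared.groupby("pos").size()
    for pos in counts[counts >= min_individuals_per_site].index:
        grp = shared[shared["pos"] == pos]
        out["per_site"][int(pos)] = pearson_r_perm(
            grp["dmaf"], grp["age"], n_perm=n_perm, seed=seed)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj
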