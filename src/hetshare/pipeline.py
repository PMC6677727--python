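"""End-to-end orchestration: simulate -> call -> share -> drift ->
selection -> copy number -> summary report.

One global seed deterministically derives every stage seed via
numpy SeedSequence spawning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import calling, copynumber, drift, selection, sharing
from .cohort import Cohort, CohortConfig
from .calling import FilterConfig
from .drift import DriftConfig
from .genome import MitoGenome
from .io import dump_json


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    n_perm: int = 1000
    seed: int = 0
    frequent_sites: tuple[int, ...] = (60, 72, 94)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def config_hash(config: RunConfig) -> str:
    payload = json.dumps({
        "cohort": cohort_mod.config_dict(config.cohort),
        "n_perm": config.n_perm, "seed": config.seed,
        "drift": {"copy_numbers": list(config.drift.copy_numbers),
                  "initial_mafs": list(config.drift.initial_mafs),
                  "generations": list(config.drift.generations),
                  "replicates": config.drift.replicates},
        "filters": {"maf_min": config.filters.maf_min,
                    "depth_min": config.filters.depth_min},
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, cohort: Cohort | None = None,
                 genome: MitoGenome | None = None, outdir=None) -> dict:
    """Run every stage; returns (and optionally writes) the report bundle."""
    seeds = _stage_seeds(config.seed)
    if cohort is None:
        config.cohort.seed = seeds[0]
        cohort = cohort_mod.generate_cohort(config.cohort, genome)

    result = calling.run_calling(cohort, config.filters)
    pairs = sharing.build_maf_pairs(result, cohort, "liver1", "liver2")
    if pairs.empty:
        raise RuntimeError("sharing stage: no heteroplasmy pairs to analyse")

    table = sharing.sharing_table(pairs)
    fisher_p = sharing.sharing_fisher(table)
    corr_all = sharing.pearson_r_perm(pairs["maf_a"], pairs["maf_b"],
                                      n_perm=config.n_perm, seed=seeds[1])
    corr_by_region = {}
    for region, grp in pairs.groupby("region"):
        if len(grp) >= 3:
            corr_by_region[region] = sharing.pearson_r_perm(
                grp["maf_a"], grp["maf_b"], n_perm=config.n_perm, seed=seeds[1])
    partition = sharing.partition_test_by_region(pairs, n_perm=config.n_perm,
                                                 seed=seeds[2])

    shared = pairs[pairs["shared"]]
    age_corr = None
    if int(pairs["shared"].sum()) >= 3 and cohort.ages().notna().all():
        try:
            age_corr = sharing.maf_diff_vs_age(
                pairs, cohort.ages(), n_perm=config.n_perm, seed=seeds[5],
                min_individuals_per_site=config.filters.common_site_min_individuals)
        except ValueError:
            age_corr = None

    observed_dmaf = (shared["maf_a"] - shared["maf_b"]).abs().to_numpy()
    profiles = [cohort.counts[k].sum(axis=1) for k in cohort.sample_keys
                if k[1] != "blood" and k[0] in result.retained]
    copy_numbers = [copynumber.relative_copy_number(p) for p in profiles]
    grid = drift.run_grid(DriftConfig(
        copy_numbers=config.drift.copy_numbers,
        initial_mafs=config.drift.initial_mafs,
        generations=config.drift.generations,
        replicates=config.drift.replicates, seed=seeds[3]))
    mean_cn = float(np.mean(copy_numbers)) if copy_numbers else 2_500.0
    mean_maf = float(shared["maf_a"].mean()) if len(shared) else 0.10
    cell = drift.select_matching_cell(grid, mean_cn, mean_maf)
    t_ref = min(config.drift.generations, key=lambda t: abs(t - 50))
    ftest = None
    if observed_dmaf.size >= 2 and observed_dmaf.var(ddof=1) > 0:
        ftest = drift.variance_f_test(observed_dmaf, grid.cells[cell][t_ref])

    labelled = selection.classify_heteroplasmies(result.passed(), cohort.genome)
    liver_labels = labelled[labelled["tissue"] != "blood"]
    shared_key = pairs[["individual", "pos", "shared"]]
    class_table = selection.sharing_table_by_class(liver_labels, shared_key)
    hnhs = None
    if (liver_labels["coding_label"] == "synonymous").any():
        hnhs = selection.hn_hs_permutation_null(
            liver_labels, cohort.genome, n_perm=config.n_perm, seed=seeds[4])

    report = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_individuals_retained": len(result.retained),
        "n_calls": int(result.calls["passed"].sum()),
        "qc": result.qc,
        "sharing": {
            "table": table.tolist(),
            "fisher_p": fisher_p,
            "shared_fraction_control": sharing.shared_fraction(table, 0),
            "shared_fraction_noncontrol": sharing.shared_fraction(table, 1)
                if table[:, 1].sum() else None,
            "r_all": vars(corr_all),
            "r_by_region": {k: vars(v) for k, v in corr_by_region.items()},
            "partition_test": partition,
            "maf_diff_vs_age": None if age_corr is None else {
                "per_region": {k: vars(v)
                               for k, v in age_corr["per_region"].items()},
                "per_site": {str(k): vars(v)
                             for k, v in age_corr["per_site"].items()},
            },
        },
        "drift": {
            "matched_cell": list(cell),
            "mean_copy_number": mean_cn,
            "mean_shared_maf": mean_maf,
            "f_test": ftest,
            "summary": grid.summary().to_dict(orient="records"),
        },
        "selection": {
            "class_table": class_table.tolist(),
            "class_fisher_p": sharing.sharing_fisher(class_table)
                if class_table.sum() else None,
            "hn_hs": vars(hnhs) if hnhs else None,
        },
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        pairs.to_csv(out / "maf_pairs.tsv", sep="\t", index=False)
        grid.summary().to_csv(out / "drift_summary.tsv", sep="\t", index=False)
        dump_json(report, out / "report.json")
    return report
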