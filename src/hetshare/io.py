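"""TSV/JSON/YAML readers and writers for the pipeline stages.

Tabular interchange is headered, tab-separated, UTF-8, '.' decimal. Count
tables are one TSV per sample named ``<individual>__<tissue>.tsv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, counts_to_frame, frame_to_counts, config_dict
from .genome import MitoGenome


def write_cohort(cohort: Cohort, outdir) -> None:
    out = Path(outdir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    for (ind, tissue), arr in sorted(cohort.counts.items()):
        df = counts_to_frame(arr, cohort.genome.sequence)
        df.to_csv(out / "counts" / f"{ind}__{tissue}.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cohort.individuals.to_csv(out / "ages.tsv", sep="\t", index=False)
    with open(out / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(config_dict(cohort.config), fh)


def read_counts_dir(counts_dir, genome: MitoGenome) -> dict:
    """counts/<individual>__<tissue>.tsv -> {(individual, tissue): array}."""
    counts = {}
    files = sorted(Path(counts_dir).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no count TSVs in {counts_dir}")
    for f in files:
        stem = f.stem
        if "__" not in stem:
            raise ValueError(f"bad sample file name {f.name}")
        ind, tissue = stem.split("__", 1)
        arr = frame_to_counts(pd.read_csv(f, sep="\t"))
        if arr.shape[0] != genome.length:
            raise ValueError(f"{f.name}: {arr.shape[0]} rows, expected "
                             f"{genome.length}")
        counts[(ind, tissue)] = arr
    return counts


def read_ages(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("individual")["age"]


def load_cohort(indir, genome: MitoGenome | None = None) -> Cohort:
    """Rebuild a Cohort from a directory written by :func:`write_cohort`."""
    from .cohort import consensus_from_counts

    indir = Path(indir)
    genome = genome if genome is not None else MitoGenome()
    cfg_path = indir / "cohort_config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            d = yaml.safe_load(fh)
        d["recurrent_sites"] = {int(k): v
                                for k, v in d.get("recurrent_sites", {}).items()}
        for key in ("het_rate_control", "het_rate_noncontrol", "het_rate_blood"):
            if key in d:
                d[key] = tuple(d[key])
        config = CohortConfig(**d)
    else:
        config = CohortConfig()
    counts = read_counts_dir(indir / "counts", genome)
    truth_path = indir / "truth.tsv"
    truth = (pd.read_csv(truth_path, sep="\t") if truth_path.exists()
             else pd.DataFrame())
    ages_path = indir / "ages.tsv"
    if ages_path.exists():
        individuals = pd.read_csv(ages_path, sep="\t")
    else:
        individuals = pd.DataFrame(
            {"individual": sorted({i for i, _ in counts}), "age": np.nan})
    consensus = {}
    for ind in individuals["individual"]:
        key = (ind, "blood") if (ind, "blood") in counts else \
            next(k for k in sorted(counts) if k[0] == ind)
        consensus[ind] = consensus_from_counts(counts[key])
    return Cohort(config, genome, individuals, consensus, counts, truth)


def dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(type(o))

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
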