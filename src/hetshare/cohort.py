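"""Synthetic autopsy-cohort generator.

Produces strand-resolved allele-count tables for n individuals x three
tissues (blood, liver1, liver2) with the statistical structure the
downstream analysis assumes: age-dependent heteroplasmy counts, recurrent
liver sites, a tunable fraction of liver heteroplasmies shared between
lobes with correlated MAFs, binomial read sampling split across strands,
uniform sequencing error, per-individual consensus haplotypes, and optional
cross-sample contamination. A truth table is returned for recovery tests.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import ALLELES, MitoGenome

#: count-array column layout: forward A,C,G,T then reverse A,C,G,T
FWD = slice(0, 4)
REV = slice(4, 8)

# lookup: for consensus allele c, the three other allele indices
_OTHERS = np.array([[a for a in range(4) if a != c] for c in range(4)])

TISSUES = ("blood", "liver1", "liver2")


@dataclass
class CohortConfig:
    n_individuals: int = 83
    age_min: int = 24
    age_max: int = 94
    depth_blood: float = 1175.0
    depth_liver: float = 2640.0
    error_rate: float = 1e-3
    # Poisson heteroplasmy-count rate = a + b * age, per region class
    het_rate_control: tuple[float, float] = (0.2, 0.018)
    het_rate_noncontrol: tuple[float, float] = (0.3, 0.022)
    het_rate_blood: tuple[float, float] = (0.2, 0.005)
    # recurrent liver sites: position -> per-individual occurrence probability
    recurrent_sites: dict = field(
        default_factory=lambda: {60: 0.30, 72: 0.80, 94: 0.25})
    shared_fraction_control: float = 0.55
    shared_fraction_noncontrol: float = 0.075
    # Beta(alpha, beta) true-MAF model; defaults give mean ~= 0.108
    maf_alpha: float = 1.2
    maf_beta: float = 9.9
    lobe_maf_jitter: float = 0.02
    # Poisson mean number of consensus differences vs the reference
    haplotype_variant_rate: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if min(self.depth_blood, self.depth_liver) <= 0:
            raise ValueError("depths must be positive")
        for p in (self.shared_fraction_control, self.shared_fraction_noncontrol,
                  self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        for a, b in (self.het_rate_control, self.het_rate_noncontrol,
                     self.het_rate_blood):
            if a < 0 or b < 0:
                raise ValueError("heteroplasmy rates must be non-negative")


@dataclass
class Cohort:
    config: CohortConfig
    genome: MitoGenome
    individuals: pd.DataFrame  # columns: individual, age
    consensus: dict  # individual -> allele-index array (0=A..3=T), len = genome
    counts: dict  # (individual, tissue) -> int32 array (L, 8)
    truth: pd.DataFrame

    @property
    def sample_keys(self) -> list[tuple[str, str]]:
        return sorted(self.counts.keys())

    def ages(self) -> pd.Series:
        return self.individuals.set_index("individual")["age"]


def _sample_counts(rng, consensus_idx, mean_depth, error_rate):
    """Background count array (L, 8) for one sample: consensus reads plus
    uniform errors on the three other alleles, split per strand."""
    L = consensus_idx.size
    depth = rng.poisson(mean_depth, size=L)
    fwd_depth = rng.binomial(depth, 0.5)
    rev_depth = depth - fwd_depth
    out = np.zeros((L, 8), dtype=np.int64)
    rows = np.arange(L)
    others = _OTHERS[consensus_idx]  # (L, 3)
    for strand, sdepth in ((FWD, fwd_depth), (REV, rev_depth)):
        err = rng.binomial(sdepth, error_rate)
        split = rng.multinomial(err, [1 / 3] * 3)  # (L, 3)
        block = np.zeros((L, 4), dtype=np.int64)
        block[rows[:, None], others] = split
        block[rows, consensus_idx] = sdepth - err
        out[:, strand] = block
    return out


def _inject_heteroplasmy(rng, counts, pos, cons_idx, minor_idx, maf):
    """Move reads from the consensus to the minor allele at one position so
    the minor fraction ~ Binomial(depth, maf) split across strands."""
    row = counts[pos - 1]
    depth = int(row.sum())
    if depth == 0:
        return
    m = rng.binomial(depth, maf)
    mf = rng.binomial(m, 0.5)
    mr = m - mf
    mf = min(mf, int(row[FWD][cons_idx]))
    mr = min(mr, int(row[REV][cons_idx]))
    row[cons_idx] -= mf
    row[minor_idx] += mf
    row[4 + cons_idx] -= mr
    row[4 + minor_idx] += mr


def generate_cohort(config: CohortConfig, genome: MitoGenome | None = None) -> Cohort:
    """Generate the full cohort. Deterministic given ``config.seed``."""
    config.validate()
    genome = genome if genome is not None else MitoGenome()
    rng = np.random.default_rng(config.seed)
    L = genome.length
    rmap = genome.region_map
    ref_idx = np.fromiter((ALLELES.index(b) for b in genome.sequence), dtype=np.int64,
                          count=L)
    control_mask = rmap.control_mask()[:L] if L == len(rmap.control_mask()) else None
    if control_mask is None or L != 16_569:
        # toy genomes: first half control, second half noncontrol
        control_mask = np.zeros(L, dtype=bool)
        control_mask[: L // 2] = True
        excluded_mask = np.zeros(L, dtype=bool)
    else:
        excluded_mask = rmap.excluded_mask()
    eligible_control = np.flatnonzero(control_mask & ~excluded_mask) + 1
    eligible_noncontrol = np.flatnonzero(~control_mask & ~excluded_mask) + 1
    recurrent_pos = set(config.recurrent_sites) if L == 16_569 else set()
    eligible_control = np.array(
        [p for p in eligible_control if p not in recurrent_pos])

    individuals = []
    consensus = {}
    counts = {}
    truth_rows = []

    for i in range(config.n_individuals):
        ind = f"I{i:03d}"
        age = int(rng.integers(config.age_min, config.age_max + 1))
        individuals.append({"individual": ind, "age": age})

        cons = ref_idx.copy()
        n_var = rng.poisson(config.haplotype_variant_rate)
        if n_var > 0:
            var_pool = np.flatnonzero(~excluded_mask) + 1
            var_pool = var_pool[~np.isin(var_pool, list(recurrent_pos))]
            var_pos = rng.choice(var_pool, size=min(n_var, var_pool.size),
                                 replace=False)
            for p in var_pos:
                cons[p - 1] = (cons[p - 1] + rng.integers(1, 4)) % 4
            var_pos_set = set(int(p) for p in var_pos)
        else:
            var_pos_set = set()
        consensus[ind] = cons

        # --- truth heteroplasmies -------------------------------------
        def new_het(pos, region, tissues, mafs):
            cons_allele = ALLELES[cons[pos - 1]]
            minor_i = int(_OTHERS[cons[pos - 1]][rng.integers(0, 3)])
            minor = ALLELES[minor_i]
            if cons[pos - 1] == ref_idx[pos - 1] and L == genome.length:
                try:
                    label = genome.annotate_substitution(pos, cons_allele, minor).label
                except ValueError:
                    label = "non-coding"
            else:
                label = "non-coding"
            for tis, maf in zip(tissues, mafs):
                truth_rows.append({
                    "individual": ind, "tissue": tis, "pos": int(pos),
                    "minor": minor, "true_maf": float(maf),
                    "shared": len(tissues) == 2, "region": region,
                    "coding_label": label,
                })

        def draw_maf():
            return float(np.clip(rng.beta(config.maf_alpha, config.maf_beta),
                                 1e-4, 0.999))

        used = set(var_pos_set)

        def sample_positions(pool, n):
            avail = pool[~np.isin(pool, list(used))] if used else pool
            n = min(n, avail.size)
            return rng.choice(avail, size=n, replace=False) if n else np.array([], int)

        def add_liver_het(pos, region, p_shared):
            maf = draw_maf()
            if rng.random() < p_shared:
                maf2 = float(np.clip(maf + rng.normal(0, config.lobe_maf_jitter),
                                     0.0, 1.0))
                new_het(pos, region, ("liver1", "liver2"), (maf, maf2))
            else:
                lobe = "liver1" if rng.random() < 0.5 else "liver2"
                new_het(pos, region, (lobe,), (maf,))
            used.add(int(pos))

        for pos, prob in (config.recurrent_sites.items() if L == 16_569 else []):
            if rng.random() < prob:
                region = ("control" if control_mask[pos - 1] else "noncontrol")
                p_shared = (config.shared_fraction_control if region == "control"
                            else config.shared_fraction_noncontrol)
                add_liver_het(pos, region, p_shared)

        a, b = config.het_rate_control
        for pos in sample_positions(eligible_control, rng.poisson(a + b * age)):
            add_liver_het(int(pos), "control", config.shared_fraction_control)
        a, b = config.het_rate_noncontrol
        for pos in sample_positions(eligible_noncontrol, rng.poisson(a + b * age)):
            add_liver_het(int(pos), "noncontrol", config.shared_fraction_noncontrol)
        a, b = config.het_rate_blood
        n_blood = rng.poisson(a + b * age)
        pool = np.concatenate([eligible_control, eligible_noncontrol])
        for pos in sample_positions(pool, n_blood):
            region = "control" if control_mask[pos - 1] else "noncontrol"
            new_het(int(pos), region, ("blood",), (draw_maf(),))
            used.add(int(pos))

        # --- emit counts ----------------------------------------------
        for tissue in TISSUES:
            mean_depth = (config.depth_blood if tissue == "blood"
                          else config.depth_liver)
            arr = _sample_counts(rng, cons, mean_depth, config.error_rate)
            counts[(ind, tissue)] = arr

    truth = pd.DataFrame(
        truth_rows, columns=["individual", "tissue", "pos", "minor", "true_maf",
                             "shared", "region", "coding_label"])
    cohort = Cohort(config, genome, pd.DataFrame(individuals), consensus, counts,
                    truth)
    # inject truth heteroplasmies into the count arrays
    for r in truth.itertuples():
        cons = cohort.consensus[r.individual]
        _inject_heteroplasmy(rng, cohort.counts[(r.individual, r.tissue)],
                             r.pos, int(cons[r.pos - 1]), ALLELES.index(r.minor),
                             r.true_maf)
    for k in cohort.counts:
        cohort.counts[k] = cohort.counts[k].astype(np.int32)
    return cohort


def consensus_from_counts(arr: np.ndarray) -> np.ndarray:
    """Per-position consensus allele index from a (L, 8) count array."""
    combined = arr[:, FWD] + arr[:, REV]
    return np.argmax(combined, axis=1)


def inject_contamination(cohort: Cohort, donor_key, recipient_key,
                         fraction: float, seed: int = 0) -> Cohort:
    """Return a copy of *cohort* with the recipient sample's counts replaced
    by a binomially re-sampled (1-fraction)·recipient + fraction·donor
    allele-fraction mixture."""
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    if donor_key not in cohort.counts or recipient_key not in cohort.counts:
        raise KeyError("unknown sample key")
    don = cohort.counts[donor_key].astype(float)
    rec = cohort.counts[recipient_key].astype(float)
    if np.array_equal(consensus_from_counts(cohort.counts[donor_key]),
                      consensus_from_counts(cohort.counts[recipient_key])):
        raise ValueError("donor and recipient consensus are identical")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(rec, dtype=np.int64)
    for strand in (FWD, REV):
        dn, rn = don[:, strand], rec[:, strand]
        d_tot, r_tot = dn.sum(axis=1), rn.sum(axis=1)
        pd_ = np.divide(dn, d_tot[:, None], out=np.full_like(dn, 0.25),
                        where=d_tot[:, None] > 0)
        pr_ = np.divide(rn, r_tot[:, None], out=np.full_like(rn, 0.25),
                        where=r_tot[:, None] > 0)
        mix = (1.0 - fraction) * pr_ + fraction * pd_
        mix /= mix.sum(axis=1, keepdims=True)
        out[:, strand] = rng.multinomial(r_tot.astype(np.int64), mix)
    new = _copy.copy(cohort)
    new.counts = dict(cohort.counts)
    new.counts[recipient_key] = out.astype(np.int32)
    return new


def counts_to_frame(arr: np.ndarray, reference: str) -> pd.DataFrame:
    """(L, 8) count array -> tidy TSV-ready frame."""
    cols = [f"{a}_fwd" for a in ALLELES] + [f"{a}_rev" for a in ALLELES]
    df = pd.DataFrame(arr, columns=cols)
    df.insert(0, "ref", list(reference))
    df.insert(0, "pos", np.arange(1, arr.shape[0] + 1))
    return df


def frame_to_counts(df: pd.DataFrame) -> np.ndarray:
    cols = [f"{a}_fwd" for a in ALLELES] + [f"{a}_rev" for a in ALLELES]
    df = df.sort_values("pos")
    return df[cols].to_numpy(dtype=np.int32)


def config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["recurrent_sites"] = {int(k): float(v)
                            for k, v in config.recurrent_sites.items()}
    return d
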