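"""hN/hS selection statistic over protein-coding heteroplasmies.

Site counting is NG86-style and unweighted: for every complete codon and
codon position, the synonymous fraction is the share of the three possible
substitutions that preserve the amino acid under the vertebrate
mitochondrial code. At heteroplasmy densities (at most one change per
codon) no multiple-hit correction applies. Stop-codon-creating
substitutions count as non-synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ALLELES, MitoGenome, translate_codon
from .sharing import bh_adjust


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(nonsyn_sites, syn_sites) contributed by one codon: per position,
    the fraction of the 3 substitutions preserving the amino acid is
    synonymous, the rest non-synonymous."""
    aa = translate_codon(codon)
    syn = 0.0
    for i in range(3):
        for b in ALLELES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if translate_codon(mutant) == aa:
                syn += 1 / 3
    return 3.0 - syn, syn


def count_syn_nonsyn_sites(genome: MitoGenome) -> tuple[float, float]:
    """Expected (N_sites, S_sites) over all complete codons of all genes.
    Overlapping genes contribute each frame separately, so
    N + S = 3 x total codons counted."""
    n_sites = s_sites = 0.0
    for gene in genome.genes:
        for idx in range(gene.n_codons):
            n, s = codon_site_fractions(genome.codon_at(gene, idx))
            n_sites += n
            s_sites += s
    return n_sites, s_sites


def classify_heteroplasmies(calls: pd.DataFrame, genome: MitoGenome) -> pd.DataFrame:
    """Label each passed call synonymous / non-synonymous / non-coding by
    introducing its minor allele into the reference coding sequence.

    Calls whose orientation major disagrees with the reference base are
    labelled against the reference (the minor allele is still the
    introduced substitution); calls whose minor equals the reference are
    non-coding by convention (no substitution relative to the reference).
    """
    labels = []
    for r in calls.itertuples():
        ref = genome.base(int(r.pos))
        if r.minor == ref:
            labels.append("non-coding")
            continue
        labels.append(genome.annotate_substitution(int(r.pos), ref, r.minor).label)
    out = calls.copy()
    out["coding_label"] = labels
    return out


def sharing_table_by_class(labelled: pd.DataFrame, shared_key: pd.DataFrame
                           ) -> np.ndarray:
    """2x2 table [[shared_nonsyn, shared_syn], [notshared_nonsyn,
    notshared_syn]] from labelled liver calls joined with per-(individual,
    pos) shared flags."""
    merged = labelled.merge(shared_key, on=["individual", "pos"], how="inner")
    tab = np.zeros((2, 2), dtype=int)
    for j, lbl in enumerate(("non-synonymous", "synonymous")):
        sub = merged[merged["coding_label"] == lbl]
        sub = sub.drop_duplicates(subset=["individual", "pos"])
        tab[0, j] = int(sub["shared"].sum())
        tab[1, j] = int((~sub["shared"].astype(bool)).sum())
    return tab


@dataclass(frozen=True)
class HnHsResult:
    n_nonsyn_het: int
    n_syn_het: int
    n_sites: float
    s_sites: float
    hn: float
    hs: float
    ratio: float | None
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def hn_hs(labelled: pd.DataFrame, genome: MitoGenome,
          site_counts: tuple[float, float] | None = None) -> HnHsResult:
    """hN/hS ratio of a labelled call set (occurrence counts; non-coding
    labels are ignored). Ratio is None when no synonymous heteroplasmy."""
    n_sites, s_sites = (site_counts if site_counts is not None
                        else count_syn_nonsyn_sites(genome))
    n_het = int((labelled["coding_label"] == "non-synonymous").sum())
    s_het = int((labelled["coding_label"] == "synonymous").sum())
    hn = n_het / n_sites
    hs = s_het / s_sites
    ratio = (hn / hs) if s_het > 0 else None
    return HnHsResult(n_het, s_het, n_sites, s_sites, hn, hs, ratio)


def _coding_position_index(genome: MitoGenome) -> dict[str, np.ndarray]:
    """reference base -> coding positions carrying that base."""
    pos = genome.coding_positions()
    by_base: dict[str, list[int]] = {b: [] for b in ALLELES}
    for p in pos:
        by_base[genome.base(int(p))].append(int(p))
    return {b: np.asarray(v, dtype=int) for b, v in by_base.items()}


def hn_hs_permutation_null(labelled: pd.DataFrame, genome: MitoGenome,
                           n_perm: int = 1000, seed: int = 0) -> HnHsResult:
    """Permutation p for hN/hS > expected: each permutation re-places the
    observed coding substitutions (preserving each base change) at uniform
    random coding positions whose reference base matches, then recomputes
    the ratio. p = (b+1)/(n_perm+1) with b = permutations with
    ratio >= observed."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    site_counts = count_syn_nonsyn_sites(genome)
    obs = hn_hs(labelled, genome, site_counts)
    if obs.ratio is None:
        raise ValueError("observed ratio undefined (no synonymous calls)")
    coding = labelled[labelled["coding_label"] != "non-coding"]
    subs = [(genome.base(int(r.pos)), r.minor) for r in coding.itertuples()]
    index = _coding_position_index(genome)
    for ref, _ in subs:
        if index[ref].size == 0:
            raise ValueError(f"no coding positions with reference base {ref}")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        n_het = s_het = 0
        for ref, alt in subs:
            p = int(index[ref][rng.integers(index[ref].size)])
            lbl = genome.annotate_substitution(p, ref, alt).label
            if lbl == "non-synonymous":
                n_het += 1
            elif lbl == "synonymous":
                s_het += 1
        if s_het == 0:
            b += 1  # infinite ratio counts as >= observed
            continue
        ratio = (n_het / obs.n_sites) / (s_het / obs.s_sites)
        if ratio >= obs.ratio:
            b += 1
    return HnHsResult(obs.n_nonsyn_het, obs.n_syn_het, obs.n_sites,
                      obs.s_sites, obs.hn, obs.hs, obs.ratio,
                      p_perm=(b + 1) / (n_perm + 1), n_perm=n_perm, seed=seed)


def age_group_counts(labelled: pd.DataFrame, ages: pd.Series, cut: int = 60
                     ) -> pd.DataFrame:
    """Per-individual synonymous / non-synonymous call counts split at the
    age cut, with two-sided Mann-Whitney U p per label, BH-adjusted."""
    missing = set(labelled["individual"]) - set(ages.index)
    if missing:
        raise ValueError(f"ages missing for {sorted(missing)}")
    individuals = sorted(ages.index)
    age_arr = ages.loc[individuals].astype(float)
    young = [i for i in individuals if age_arr[i] < cut]
    old = [i for i in individuals if age_arr[i] >= cut]
    if not young or not old:
        raise ValueError("an age group is empty")
    rows = []
    for lbl in ("synonymous", "non-synonymous"):
        sub = labelled[labelled["coding_label"] == lbl]
        per_ind = sub.groupby("individual").size()
        cy = np.array([per_ind.get(i, 0) for i in young], dtype=float)
        co = np.array([per_ind.get(i, 0) for i in old], dtype=float)
        if np.all(cy == cy[0]) and np.all(co == co[0]) and cy[0] == co[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(cy, co, alternative="two-sided")[1])
        rows.append({"label": lbl, "n_young": len(young), "n_old": len(old),
                     "mean_young": float(cy.mean()), "mean_old": float(co.mean()),
                     "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
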