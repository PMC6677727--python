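"""Heteroplasmy calling: per-site filter cascade, sample-level coverage QC,
and cross-sample contamination screens.

All thresholds are inclusive (">= threshold" passes). MAF is oriented to the
major allele in blood, so values above 0.5 are legal when the liver
consensus differs from blood (flagged as a consensus flip).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ALLELES, MitoGenome
from .cohort import Cohort, FWD, REV, consensus_from_counts

DEFAULT_COMMON_SITES = {
    "liver": frozenset({60, 72, 94, 185, 189, 203, 11_126, 16_093, 16_126}),
    "blood": frozenset({12_705}),
}


@dataclass
class FilterConfig:
    maf_min: float = 0.025
    depth_min: int = 500
    minor_reads_min_per_strand: int = 10
    quality_min_per_strand: float = 10.0
    coverage_band: tuple[float, float] = (0.2, 2.0)
    sample_low_coverage_max: float = 0.02
    common_sites: dict = field(
        default_factory=lambda: {k: set(v) for k, v in DEFAULT_COMMON_SITES.items()})
    common_site_min_individuals: int = 5
    quality_error_rate: float = 0.01
    quality_cap: float = 1000.0
    # candidate emission / "minor allele observed" threshold for screens
    candidate_maf_min: float = 0.01
    # contamination screen thresholds (criteria 1-3)
    contam_match_fraction: float = 0.8
    contam_mean_maf_min: float = 0.01
    contam_called_fraction: float = 0.6
    haplogroup_min_sites: int = 5

    def validate(self) -> None:
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if self.depth_min <= 0 or self.minor_reads_min_per_strand <= 0:
            raise ValueError("thresholds must be positive")

    def tissue_class(self, tissue: str) -> str:
        return "liver" if tissue.startswith("liver") else tissue

    def is_common_site(self, pos: int, tissue: str) -> bool:
        cls = self.tissue_class(tissue)
        if cls not in self.common_sites and tissue not in self.common_sites:
            raise KeyError(f"no common-site list for tissue {tissue!r}")
        return pos in self.common_sites.get(cls, self.common_sites.get(tissue, set()))


@dataclass(frozen=True)
class SiteCounts:
    sample: str
    tissue: str
    pos: int
    fwd: np.ndarray  # counts A,C,G,T on the forward strand
    rev: np.ndarray

    @property
    def depth(self) -> int:
        return int(self.fwd.sum() + self.rev.sum())


@dataclass(frozen=True)
class MafResult:
    minor: str
    maf: float
    maf_fwd: float
    maf_rev: float
    consensus_flip: bool
    tie: bool


def compute_maf(counts: SiteCounts, blood_major: str) -> MafResult:
    """Most frequent non-blood-major allele and its frequency, overall and
    per strand. Ties between candidate minors break toward the higher
    combined-strand count, then lexicographically (flagged)."""
    if blood_major not in ALLELES:
        raise ValueError(f"bad blood major {blood_major!r}")
    depth = counts.depth
    if depth == 0:
        raise ValueError(f"zero depth at {counts.pos}")
    combined = counts.fwd + counts.rev
    major_i = ALLELES.index(blood_major)
    cand = [i for i in range(4) if i != major_i]
    best = max(combined[i] for i in cand)
    winners = [i for i in cand if combined[i] == best]
    minor_i = winners[0]  # lexicographic among equals
    fwd_tot, rev_tot = counts.fwd.sum(), counts.rev.sum()
    maf = combined[minor_i] / depth
    return MafResult(
        minor=ALLELES[minor_i],
        maf=float(maf),
        maf_fwd=float(counts.fwd[minor_i] / fwd_tot) if fwd_tot else 0.0,
        maf_rev=float(counts.rev[minor_i] / rev_tot) if rev_tot else 0.0,
        consensus_flip=bool(maf > 0.5),
        tie=len(winners) > 1,
    )


def quality_score(minor_count: int, strand_depth: int, error_rate: float,
                  cap: float = 1000.0) -> float:
    """Phred-like score: -10*log10 of the one-sided Binomial tail
    P(X >= minor_count | n=strand_depth, p=error_rate), capped."""
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    if minor_count <= 0:
        return 0.0
    tail = stats.binom.sf(minor_count - 1, strand_depth, error_rate)
    if tail <= 0.0:
        return float(cap)
    return float(min(cap, -10.0 * np.log10(tail)))


@dataclass
class HeteroplasmyCall:
    individual: str
    tissue: str
    pos: int
    major: str  # blood major allele (orientation)
    minor: str
    maf: float
    maf_fwd: float
    maf_rev: float
    qual_fwd: float
    qual_rev: float
    depth: int
    passed: bool
    reasons: tuple[str, ...]
    consensus_flip: bool = False
    tie: bool = False


def call_site(counts: SiteCounts, blood_major: str, config: FilterConfig,
              sample_mean_depth: float, region_map=None,
              qual_override: tuple[float, float] | None = None) -> HeteroplasmyCall:
    """Apply the full per-site filter cascade. Pass/fail is a pure
    conjunction; every failed criterion is recorded in ``reasons``."""
    m = compute_maf(counts, blood_major)
    minor_i = ALLELES.index(m.minor)
    fwd_tot, rev_tot = int(counts.fwd.sum()), int(counts.rev.sum())
    if qual_override is not None:
        qf, qr = qual_override
    else:
        qf = quality_score(int(counts.fwd[minor_i]), fwd_tot,
                           config.quality_error_rate, config.quality_cap)
        qr = quality_score(int(counts.rev[minor_i]), rev_tot,
                           config.quality_error_rate, config.quality_cap)
    reasons = []
    if not (m.maf_fwd >= config.maf_min and m.maf_rev >= config.maf_min):
        reasons.append("strand_maf")
    if counts.depth < config.depth_min:
        reasons.append("low_depth")
    if (counts.fwd[minor_i] < config.minor_reads_min_per_strand
            or counts.rev[minor_i] < config.minor_reads_min_per_strand):
        reasons.append("strand_support")
    common = config.is_common_site(counts.pos, counts.tissue)
    if not common and (qf < config.quality_min_per_strand
                       or qr < config.quality_min_per_strand):
        reasons.append("quality")
    from .genome import classify_region
    if counts.pos <= 16_569 and classify_region(counts.pos, region_map).excluded:
        reasons.append("excluded_region")
    lo, hi = config.coverage_band
    if not (lo * sample_mean_depth <= counts.depth <= hi * sample_mean_depth):
        reasons.append("coverage_band")
    return HeteroplasmyCall(
        counts.sample, counts.tissue, counts.pos, blood_major, m.minor,
        m.maf, m.maf_fwd, m.maf_rev, qf, qr, counts.depth,
        passed=not reasons, reasons=tuple(reasons),
        consensus_flip=m.consensus_flip, tie=m.tie)


def sample_qc(depth_profile: np.ndarray, config: FilterConfig,
              genome_length: int | None = None) -> tuple[bool, float]:
    """Keep/drop decision for one sample: drop when strictly more than
    ``sample_low_coverage_max`` of positions are below ``depth_min``.
    Returns (keep, low_coverage_fraction)."""
    if genome_length is not None and depth_profile.size != genome_length:
        raise ValueError("coverage profile length mismatch")
    frac = float(np.mean(depth_profile < config.depth_min))
    return frac <= config.sample_low_coverage_max, frac


# ---------------------------------------------------------------------------
# vectorized cohort path
# ---------------------------------------------------------------------------

def _sample_site_table(arr: np.ndarray, blood_major_idx: np.ndarray,
                       config: FilterConfig, tissue: str,
                       excluded_mask: np.ndarray) -> pd.DataFrame:
    """Evaluate the cascade for all candidate positions of one sample.

    Candidates are positions whose combined blood-oriented MAF is at least
    ``candidate_maf_min``; everything below that is background error and is
    not emitted."""
    L = arr.shape[0]
    fwd, rev = arr[:, FWD].astype(np.int64), arr[:, REV].astype(np.int64)
    combined = fwd + rev
    depth = combined.sum(axis=1)
    fwd_tot, rev_tot = fwd.sum(axis=1), rev.sum(axis=1)
    rows = np.arange(L)
    masked = combined.copy()
    masked[rows, blood_major_idx] = -1
    minor_idx = np.argmax(masked, axis=1)
    n_best = (masked == masked[rows, minor_idx][:, None]).sum(axis=1)
    tie = n_best > 1
    minor_cnt = combined[rows, minor_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(depth > 0, minor_cnt / np.maximum(depth, 1), 0.0)
        maf_f = np.where(fwd_tot > 0, fwd[rows, minor_idx] / np.maximum(fwd_tot, 1), 0.0)
        maf_r = np.where(rev_tot > 0, rev[rows, minor_idx] / np.maximum(rev_tot, 1), 0.0)
    cand = (maf >= config.candidate_maf_min) & (depth > 0)
    idx = np.flatnonzero(cand)
    mf, mr = fwd[idx, minor_idx[idx]], rev[idx, minor_idx[idx]]
    qf = -10.0 * np.log10(np.maximum(
        stats.binom.sf(mf - 1, fwd_tot[idx], config.quality_error_rate), 1e-300))
    qr = -10.0 * np.log10(np.maximum(
        stats.binom.sf(mr - 1, rev_tot[idx], config.quality_error_rate), 1e-300))
    qf = np.where(mf > 0, np.minimum(qf, config.quality_cap), 0.0)
    qr = np.where(mr > 0, np.minimum(qr, config.quality_cap), 0.0)
    mean_depth = depth.mean()
    lo, hi = config.coverage_band
    common = np.zeros(idx.size, dtype=bool)
    cls = config.tissue_class(tissue)
    for p in config.common_sites.get(cls, set()):
        common |= idx + 1 == p
    crit = {
        "strand_maf": (maf_f[idx] >= config.maf_min) & (maf_r[idx] >= config.maf_min),
        "low_depth": depth[idx] >= config.depth_min,
        "strand_support": (mf >= config.minor_reads_min_per_strand)
                          & (mr >= config.minor_reads_min_per_strand),
        "quality": common | ((qf >= config.quality_min_per_strand)
                             & (qr >= config.quality_min_per_strand)),
        "excluded_region": ~excluded_mask[idx],
        "coverage_band": (depth[idx] >= lo * mean_depth)
                         & (depth[idx] <= hi * mean_depth),
    }
    passed = np.ones(idx.size, dtype=bool)
    for ok in crit.values():
        passed &= ok
    reasons = [",".join(k for k, ok in crit.items() if not ok[i])
               for i in range(idx.size)]
    return pd.DataFrame({
        "pos": idx + 1,
        "major": [ALLELES[i] for i in blood_major_idx[idx]],
        "minor": [ALLELES[i] for i in minor_idx[idx]],
        "maf": maf[idx], "maf_fwd": maf_f[idx], "maf_rev": maf_r[idx],
        "qual_fwd": qf, "qual_rev": qr, "depth": depth[idx],
        "passed": passed, "reasons": reasons,
        "consensus_flip": maf[idx] > 0.5, "tie": tie[idx],
    })


@dataclass
class CallResult:
    calls: pd.DataFrame  # candidate sites of retained samples, with pass/fail
    qc: dict  # per-individual QC dispositions and diagnostics
    retained: list  # individuals surviving all sample-level filters

    def passed(self) -> pd.DataFrame:
        return self.calls[self.calls["passed"]].reset_index(drop=True)


def run_calling(cohort: Cohort, config: FilterConfig | None = None) -> CallResult:
    """Full calling pipeline on a cohort: per-sample coverage QC, per-site
    cascade, pairwise contamination screens, and the haplogroup-excess
    filter. Flagged or failing individuals lose all their samples."""
    config = config if config is not None else FilterConfig()
    config.validate()
    genome = cohort.genome
    rmap = genome.region_map
    if genome.length == 16_569:
        excluded_mask = rmap.excluded_mask()
    else:
        excluded_mask = np.zeros(genome.length, dtype=bool)
    qc: dict = {"dropped": {}, "samples": {}}
    inds = list(cohort.individuals["individual"])

    retained = []
    for ind in inds:
        ok_all = True
        for tissue in sorted({t for i, t in cohort.counts if i == ind}):
            arr = cohort.counts[(ind, tissue)]
            depth = arr.sum(axis=1)
            keep, frac = sample_qc(depth, config, genome.length)
            qc["samples"][f"{ind}:{tissue}"] = {
                "low_coverage_fraction": frac, "keep": bool(keep),
                "mean_depth": float(depth.mean())}
            ok_all &= keep
        if ok_all:
            retained.append(ind)
        else:
            qc["dropped"][ind] = "low_coverage"

    frames = []
    for ind in retained:
        tissues = sorted({t for i, t in cohort.counts if i == ind})
        if "blood" in tissues:
            blood_major = consensus_from_counts(cohort.counts[(ind, "blood")])
        else:
            blood_major = cohort.consensus[ind]
        for tissue in tissues:
            df = _sample_site_table(cohort.counts[(ind, tissue)], blood_major,
                                    config, tissue, excluded_mask)
            df.insert(0, "tissue", tissue)
            df.insert(0, "individual", ind)
            frames.append(df)
    calls = (pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["individual", "tissue", "pos", "major", "minor", "maf",
                 "maf_fwd", "maf_rev", "qual_fwd", "qual_rev", "depth",
                 "passed", "reasons", "consensus_flip", "tie"]))

    contaminated = screen_cohort_contamination(cohort, calls, config,
                                               retained, qc)
    for ind in contaminated:
        qc["dropped"][ind] = qc["dropped"].get(ind, "contamination")
    retained = [i for i in retained if i not in contaminated]
    calls = calls[calls["individual"].isin(retained)].reset_index(drop=True)
    return CallResult(calls, qc, retained)


def _sample_profiles(cohort: Cohort, calls: pd.DataFrame, config: FilterConfig,
                     retained: list) -> dict:
    """Per-sample summaries used by the contamination screens."""
    ref_idx = np.fromiter((ALLELES.index(b) for b in cohort.genome.sequence),
                          dtype=np.int64, count=cohort.genome.length)
    prof = {}
    for (ind, tissue), arr in cohort.counts.items():
        if ind not in retained:
            continue
        cons = consensus_from_counts(arr)
        var = {int(p) + 1: int(cons[p]) for p in np.flatnonzero(cons != ref_idx)}
        sub = calls[(calls["individual"] == ind) & (calls["tissue"] == tissue)]
        observed = sub[sub["maf"] >= config.candidate_maf_min]
        called = set(sub[sub["passed"]]["pos"])
        prof[(ind, tissue)] = {
            "cons": cons, "var": var, "arr": arr,
            "n_observed": len(observed), "n_called_observed":
                int(observed["passed"].sum()),
            "called": called,
            "called_minor": {int(r.pos): r.minor
                             for r in sub[sub["passed"]].itertuples()},
        }
    return prof


def pairwise_contamination_screen(recipient, donor, config: FilterConfig):
    """Criteria 1-3 for one ordered (recipient, donor) sample pair; both
    arguments are profile dicts from :func:`_sample_profiles`.

    Returns (flagged, diagnostics). With zero differing-consensus sites the
    pair is clear (criterion 1 is vacuously unmet)."""
    diff_pos = sorted(
        p for p in set(recipient["var"]) | set(donor["var"])
        if recipient["cons"][p - 1] != donor["cons"][p - 1])
    diag = {"n_diff_sites": len(diff_pos)}
    if not diff_pos:
        return False, diag
    match = 0
    mafs = []
    for p in diff_pos:
        row = recipient["arr"][p - 1]
        combined = row[FWD] + row[REV]
        depth = combined.sum()
        cons_r = int(recipient["cons"][p - 1])
        cand = [i for i in range(4) if i != cons_r]
        minor_i = max(cand, key=lambda i: (combined[i], -i))
        if combined[minor_i] > 0 and minor_i == int(donor["cons"][p - 1]):
            match += 1
        mafs.append(combined[minor_i] / depth if depth else 0.0)
    frac_match = match / len(diff_pos)
    mean_maf = float(np.mean(mafs))
    n_obs = recipient["n_observed"]
    frac_called = (recipient["n_called_observed"] / n_obs) if n_obs else 0.0
    diag.update(match_fraction=frac_match, mean_maf=mean_maf,
                called_fraction=frac_called)
    flagged = (frac_match >= config.contam_match_fraction
               and mean_maf >= config.contam_mean_maf_min
               and frac_called >= config.contam_called_fraction)
    return flagged, diag


def haplogroup_excess_filter(recipient, others, config: FilterConfig) -> bool:
    """True (drop) if >= ``haplogroup_min_sites`` of the recipient's called
    minor alleles jointly match one other sample's consensus at positions
    where that sample's consensus differs from the recipient's."""
    for other in others:
        n = 0
        for p, minor in recipient["called_minor"].items():
            cons_o = int(other["cons"][p - 1])
            if cons_o != int(recipient["cons"][p - 1]) and ALLELES[cons_o] == minor:
                n += 1
        if n >= config.haplogroup_min_sites:
            return True
    return False


def screen_cohort_contamination(cohort: Cohort, calls: pd.DataFrame,
                                config: FilterConfig, retained: list,
                                qc: dict) -> set:
    """Run the pairwise screens liver-vs-liver and blood-vs-blood across
    individuals, plus the haplogroup-excess filter. Returns the set of
    flagged individuals."""
    prof = _sample_profiles(cohort, calls, config, retained)
    flagged = set()
    keys = sorted(prof)
    by_class: dict[str, list] = {}
    for k in keys:
        by_class.setdefault(config.tissue_class(k[1]), []).append(k)
    for cls, ks in by_class.items():
        for rk in ks:
            for dk in ks:
                if rk[0] == dk[0]:
                    continue
                hit, diag = pairwise_contamination_screen(prof[rk], prof[dk], config)
                if hit:
                    flagged.add(rk[0])
                    qc.setdefault("contamination_pairs", []).append(
                        {"recipient": list(rk), "donor": list(dk), **diag})
    for rk in keys:
        others = [prof[k] for k in keys if k[0] != rk[0]
                  and config.tissue_class(k[1]) == config.tissue_class(rk[1])]
        if haplogroup_excess_filter(prof[rk], others, config):
            flagged.add(rk[0])
            qc.setdefault("haplogroup_flags", []).append(list(rk))
    return flagged
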