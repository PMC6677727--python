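"""Two-step mtDNA segregation/replication drift simulator.

Each cell division segregates the N molecules equally into two daughters
(hypergeometric split of the minor allele) and every molecule is then
replicated exactly once, restoring N copies. The two cells whose MAF
difference is recorded sit on the two sides of the pedigree: their first
division is shared (anti-correlated), after which each side follows one
random daughter lineage per generation.

Generation indexing: t counts divisions since the progenitor split, so
t = 0 is the state of the two first daughters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DriftConfig:
    copy_numbers: tuple[int, ...] = (1_000, 2_500, 5_000)
    initial_mafs: tuple[float, ...] = (0.05, 0.10, 0.20, 0.50)
    generations: tuple[int, ...] = (10, 20, 50, 100, 250)
    replicates: int = 1_000
    seed: int = 0
    polya_replication: bool = False  # stochastic (Pólya) replication variant

    def validate(self) -> None:
        for n in self.copy_numbers:
            if n < 2 or n % 2:
                raise ValueError(f"copy number {n} must be even and >= 2")
        for p in self.initial_mafs:
            if not 0.0 <= p <= 0.5:
                raise ValueError(f"initial MAF {p} outside [0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if min(self.generations) < 0:
            raise ValueError("generations must be >= 0")


def divide_cell(k: int, n: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split a cell with minor count *k* of *n* molecules into two daughters
    and double each back to *n*. Returns the daughters' minor counts."""
    if n % 2:
        raise ValueError("N must be even")
    if not 0 <= k <= n:
        raise ValueError("k outside 0..N")
    k1 = int(rng.hypergeometric(k, n - k, n // 2)) if 0 < k < n else k // 2
    return 2 * k1, 2 * (k - k1)


def _step(k: np.ndarray, n: int, rng: np.random.Generator,
          polya: bool = False) -> np.ndarray:
    """One generation for an array of lineages: hypergeometric split, keep
    one random daughter, replicate back to n."""
    half = n // 2
    k1 = rng.hypergeometric(k, n - k, half)
    keep = np.where(rng.random(k.shape) < 0.5, k1, k - k1)
    if not polya:
        return 2 * keep
    # Pólya-urn replication: add half of the molecules one at a time with
    # probability proportional to current composition
    out = keep.copy()
    cur = np.full(k.shape, half)
    for _ in range(half):
        out = out + (rng.random(k.shape) < out / cur).astype(np.int64)
        cur += 1
    return out


def simulate_pedigree_pair(n: int, p0: float, t_max: int, replicates: int,
                           seed: int = 0, record_at: tuple[int, ...] | None = None,
                           polya: bool = False) -> dict[int, np.ndarray]:
    """|ΔMAF| between the two pedigree sides at each requested generation.

    Returns {t: vector of length *replicates*}. t = 0 records the two first
    daughters produced by the shared progenitor division.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if n % 2:
        raise ValueError("N must be even")
    record = sorted(set(record_at if record_at is not None else [t_max]))
    if record and record[-1] > t_max:
        raise ValueError("record_at beyond t_max")
    rng = np.random.default_rng(seed)
    k0 = int(round(p0 * n))
    k_init = np.full(replicates, k0, dtype=np.int64)
    k1 = rng.hypergeometric(k_init, n - k_init, n // 2) if 0 < k0 < n \
        else k_init // 2
    left, right = 2 * k1, 2 * (k_init - k1)
    out = {}
    if 0 in record:
        out[0] = np.abs(left - right) / n
    for t in range(1, t_max + 1):
        left = _step(left, n, rng, polya)
        right = _step(right, n, rng, polya)
        if t in record:
            out[t] = np.abs(left - right) / n
    return out


@dataclass
class DriftResult:
    config: DriftConfig
    #: (N, p0) -> {t: |ΔMAF| vector}
    cells: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for (n, p0), per_t in sorted(self.cells.items()):
            for t, v in sorted(per_t.items()):
                rows.append({"N": n, "p0": p0, "t": t,
                             "mean_dmaf": float(v.mean()),
                             "var_dmaf": float(v.var(ddof=1))})
        return pd.DataFrame(rows)


def run_grid(config: DriftConfig) -> DriftResult:
    """Simulate every (copy number, initial MAF) cell of the grid,
    recording |ΔMAF| at each requested generation."""
    config.validate()
    result = DriftResult(config)
    ss = np.random.SeedSequence(config.seed)
    combos = list(product(config.copy_numbers, config.initial_mafs))
    for (n, p0), child in zip(combos, ss.spawn(len(combos))):
        result.cells[(n, p0)] = simulate_pedigree_pair(
            n, p0, max(config.generations), config.replicates,
            seed=child, record_at=tuple(config.generations),
            polya=config.polya_replication)
    return result


def variance_f_test(observed: np.ndarray, simulated: np.ndarray) -> dict:
    """One-sided F-test that the observed |ΔMAF| variance is smaller than
    the simulated one: F = var(sim)/var(obs), upper-tail p."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.size < 2 or sim.size < 2:
        raise ValueError("need >= 2 values in each vector")
    v_obs, v_sim = obs.var(ddof=1), sim.var(ddof=1)
    if v_obs == 0 or v_sim == 0:
        raise ValueError("zero variance")
    f = v_sim / v_obs
    p = float(stats.f.sf(f, sim.size - 1, obs.size - 1))
    return {"F": float(f), "p": p, "df": (sim.size - 1, obs.size - 1),
            "var_observed": float(v_obs), "var_simulated": float(v_sim)}


def select_matching_cell(result: DriftResult, observed_copy_number: float,
                         observed_maf: float) -> tuple[int, float]:
    """Nearest grid cell, lexicographic on (|log N - log N_obs|, |p0 - MAF|)."""
    if not result.cells:
        raise ValueError("empty grid")
    ns = sorted({n for n, _ in result.cells})
    best_n = min(ns, key=lambda n: (abs(np.log(n) - np.log(observed_copy_number)), n))
    p0s = sorted({p for n, p in result.cells if n == best_n})
    best_p = min(p0s, key=lambda p: (abs(p - observed_maf), p))
    return best_n, best_p


def transition_matrix(n: int) -> np.ndarray:
    """(n+1)x(n+1) exact one-generation kernel of the split-and-double
    process for a single lineage (states = minor counts 0..n)."""
    if n % 2:
        raise ValueError("N must be even")
    half = n // 2
    T = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        pmf = stats.hypergeom.pmf(np.arange(half + 1), n, k, half)
        for k1, p in enumerate(pmf):
            if p <= 0:
                continue
            # keep either daughter with probability 1/2
            T[k, min(2 * k1, n)] += p / 2
            T[k, min(2 * (k - k1), n)] += p / 2
    return T


def exact_lineage_distribution(n: int, k0: int, t: int) -> np.ndarray:
    """Exact minor-count distribution of one lineage after *t* generations
    following the first (shared) division, starting from a daughter of a
    progenitor with minor count *k0*."""
    half = n // 2
    start = np.zeros(n + 1)
    pmf = stats.hypergeom.pmf(np.arange(half + 1), n, k0, half)
    for k1, p in enumerate(pmf):
        if p > 0:
            start[min(2 * k1, n)] += p
    T = transition_matrix(n)
    return start @ np.linalg.matrix_power(T, t)
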