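# hetshare

Analysis pipeline for mtDNA heteroplasmy sharing between paired tissue
samples (two liver lobes plus blood per individual): heteroplasmy calling
with strand-aware filters and contamination screens, sharing/correlation
statistics with permutation nulls, a two-step random-genetic-drift
simulator with a variance test, hN/hS selection statistics, and a
synthetic-cohort generator so the whole pipeline runs without any external
data.

## Package layout

| module | contents |
| --- | --- |
| `hetshare.genome` | circular 16,569 bp coordinate system, control/non-control/D-loop/excluded region partition, 13 protein-coding gene annotation, synonymous/non-synonymous classification (translation table 2, light-strand genes handled on the reverse complement) |
| `hetshare.cohort` | synthetic autopsy-cohort generator (strand-split binomial read sampling, age-dependent heteroplasmy counts, recurrent sites, tunable lobe sharing, consensus haplotypes, contamination injection) with a truth table |
| `hetshare.calling` | per-site filter cascade (per-strand MAF ≥ 2.5 %, depth ≥ 500, ≥ 10 minor reads per strand, per-strand quality ≥ 10 with a common-site override, excluded regions, 20–200 % coverage band), sample-level coverage QC, pairwise contamination screens, haplogroup-excess filter |
| `hetshare.sharing` | blood-oriented MAF pairs, 2×2 sharing tables, Fisher exact, Pearson r with permutation p, partition and subsampling tests, \|ΔMAF\|-vs-age, Benjamini-Hochberg |
| `hetshare.drift` | hypergeometric split + doubling drift simulator over a (copy number × initial MAF) grid, exact Markov-chain kernel for validation, one-sided variance F-test, grid-cell matching |
| `hetshare.selection` | NG86-style synonymous/non-synonymous site counting, hN/hS with a substitution-preserving permutation null, age-group Mann-Whitney comparisons |
| `hetshare.copynumber` | coverage-derived relative copy number, D-loop coverage ratio test, blood-admixture threshold and replication-count calculators |
| `hetshare.pipeline`, `hetshare.cli`, `hetshare.io` | end-to-end orchestration, CLI, TSV/JSON/YAML interchange |

The packaged default reference FASTA is a deterministic synthetic sequence
of rCRS length with the real rCRS gene coordinates; pass your own reference
with `--reference` (coordinates, region boundaries, and all statistics are
defined on the coordinate system, not the base content).

## CLI

```bash
hetshare simulate --config cohort.yaml --seed 1 --out cohortdir
hetshare call --counts cohortdir/counts --out callsdir
hetshare share --cohort cohortdir --out sharedir --seed 1 --n-perm 1000
hetshare drift --config drift.yaml --out driftdir --seed 1
hetshare selection --cohort cohortdir --out seldir --n-perm 1000 --seed 1
hetshare report --cohort cohortdir --out repdir
hetshare run --seed 1 --n-perm 1000 --out rundir   # synthetic end-to-end
```

Exit codes: 0 ok, 2 configuration error, 3 data error. Count tables are
one TSV per sample (`pos, ref, A_fwd..T_fwd, A_rev..T_rev`).

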