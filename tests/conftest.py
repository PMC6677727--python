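import numpy as np
import pytest

from hetshare.cohort import CohortConfig, generate_cohort
from hetshare.genome import Gene, MitoGenome


@pytest.fixture(scope="session")
def genome():
    return MitoGenome()


@pytest.fixture(scope="session")
def toy_genome():
    """120 bp circular genome with one heavy-strand and one light-strand
    gene (both 30 bp, 10 codons)."""
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
    genes = [Gene("fwd_gene", 11, 40, "H"), Gene("rev_gene", 61, 90, "L")]
    return MitoGenome(seq, genes)


@pytest.fixture(scope="session")
def small_cohort(genome):
    cfg = CohortConfig(n_individuals=12, seed=42)
    return generate_cohort(cfg, genome)


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    from hetshare.calling import run_calling

    return run_calling(small_cohort)
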