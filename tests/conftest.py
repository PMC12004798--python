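import numpy as np
import pandas as pd
import pytest

import cnvrkit as ck


@pytest.fixture(scope="session")
def small_config():
    return ck.SimulationConfig(seed=11, n_samples=60, n_loci=40,
                               chromosome_lengths_mb=(30.0, 25.0, 20.0))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Genome, SNP map, loci and paired call sets of a small seeded cohort."""
    genome = ck.make_genome(small_config)
    snp_map = ck.make_snp_map(genome, small_config)
    loci = ck.plant_loci(genome, small_config)
    calls_a, calls_b, truth = ck.simulate_samples(
        loci, genome, snp_map, small_config)
    return {"config": small_config, "genome": genome, "snp_map": snp_map,
            "loci": loci, "calls_a": calls_a, "calls_b": calls_b,
            "truth": truth}


def random_calls(rng: np.random.Generator, n: int, span: int = 100_000,
                 max_len: int = 20_000, chroms=("1", "2")) -> pd.DataFrame:
    """Random call table for interval-arithmetic oracle comparisons."""
    starts = rng.integers(1, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts,
        "end": starts + lengths,
        "state": rng.choice([0, 1, 3, 4], size=n),
        "sample_id": [f"S{i % 17}" for i in range(n)],
        "numsnp": rng.integers(1, 50, size=n),
    })
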