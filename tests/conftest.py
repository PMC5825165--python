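import logging

import numpy as np
import pandas as pd
import pytest

from phasworks.pipeline import run_pipeline
from phasworks.synthetic_data import SimConfig, generate_dataset, generate_genome

logging.getLogger("phasworks").setLevel(logging.WARNING)


def small_sim_config(seed: int = 5, **overrides) -> SimConfig:
    """A reduced study design for fast unit tests (same structure, fewer loci)."""
    base = dict(
        seed=seed, n_chroms=2, chrom_len=60_000, n_coding_genes=8, n_repeats=6,
        n_phas_eat1_dep=6, n_phas_eat1_indep=3, n_decoy_lincrna=3,
        n_decoy_highvar=3, n_decoy_nosite=3, srna_background_reads=800,
        mrna_background_reads=20, degradome_background_reads=200,
        rip_lib_size=20_000,
        n_rip_species={"PHAS": 30, "coding": 15, "intergenic": 30,
                       "repeat": 40, "background": 100},
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run at the default study conditions (seed 1)."""
    return run_pipeline(SimConfig(seed=1))


def random_read_table(rng: np.random.Generator, n: int, chroms=("chr1", "chr2"),
                      chrom_len: int = 100_000) -> pd.DataFrame:
    """A random BED6+3 read table exercising all filter dimensions."""
    lengths = rng.choice([20, 21, 24, 25], size=n)
    starts = rng.integers(0, chrom_len - 30, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(list(chroms), size=n),
        "start": starts,
        "end": starts + lengths,
        "name": ".",
        "copies": rng.integers(1, 5, size=n),
        "strand": rng.choice(["+", "-"], size=n),
        "read_length": lengths,
        "mismatches": rng.choice([0, 0, 0, 1, 2], size=n),
        "hits": rng.choice([1, 1, 1, 2, 49, 50, 51, 60], size=n),
    })
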