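import numpy as np
import pandas as pd
import pytest

from mutacc import callset_io as cio
from mutacc.simulate import SimulationConfig, simulate_ma_experiment


@pytest.fixture(scope="session")
def small_config():
    """A 2-genotype, 6-line experiment on a 200 kb genome with rates
    scaled up so every event class is represented."""
    return SimulationConfig(
        n_genotypes=2,
        lines_per_genotype=3,
        nuclear_length=200_000,
        mito_length=15_000,
        ancestral_het_density=0.002,
        true_mu_bs=5e-7,
        true_mu_gc=2e-4,
        mito_mu=5e-6,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_ma_experiment(small_config)


@pytest.fixture
def toy_reference():
    """A deterministic 60 bp nuclear contig plus a 30 bp circular mito."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    nuc = bases[rng.integers(0, 4, 60)].tobytes().decode()
    mito = bases[rng.integers(0, 4, 30)].tobytes().decode()
    return cio.ReferenceGenome(
        contigs={"chr1": nuc, "mtDNA": mito},
        partition={"chr1": cio.NUCLEAR, "mtDNA": cio.MITO},
        circular={"chr1": False, "mtDNA": True},
    )


def make_calls(rows):
    """Build a call table from (contig, pos, ref, alt, genotype[, af, dp, q])."""
    full = []
    for row in rows:
        row = list(row)
        defaults = [np.nan, 30, 99.0]
        row = row + defaults[len(row) - 5 :]
        full.append(row)
    if not full:
        return cio.empty_calls()
    return pd.DataFrame(full, columns=cio.CALL_COLUMNS)
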