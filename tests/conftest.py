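import numpy as np
import pandas as pd
import pytest

from nomescape.simulate import SimulationConfig, simulate_study


def tiny_config(**overrides) -> SimulationConfig:
    """A fast desk-scale config for unit tests (one 400-kb chromosome)."""
    defaults = dict(
        seed=42, n_chroms=1, chrom_length=800_000, n_genes=30, n_lncrnas=8,
        n_linked_pairs=4, n_dmrs=4, n_ndrs=4, dmr_length=1_200,
        n_meth_samples_per_group=2, n_expr_samples_per_group=5,
        n_deg_up_a=4, n_deg_up_b=4, n_species_specific=4,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_study():
    return simulate_study(tiny_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_calls(rng, n=200, chrom="chr1", length=10_000):
    """A random call table for oracle tests (positions unique and sorted).

    Context is a deterministic function of position so that two independent
    tables over the same coordinate space never disagree on context.
    """
    pos = np.sort(rng.choice(length, size=n, replace=False))
    ctx = np.where(pos % 5 < 2, "WCG", "GCH")
    cov = rng.poisson(8, size=n)
    meth = rng.binomial(cov, rng.uniform(0, 1, size=n))
    return pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "strand": rng.choice(["+", "-"], size=n),
        "context": ctx, "meth": meth, "unmeth": cov - meth,
    })
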