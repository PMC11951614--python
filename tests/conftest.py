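import numpy as np
import pandas as pd
import pytest

from methylmemory.methylome import MethylationSample


def make_sample(chrom, pos, m, u, sample_id="s", group="g"):
    """Build a MethylationSample from parallel arrays (chrom may be scalar)."""
    n = len(pos)
    if isinstance(chrom, str):
        chrom = [chrom] * n
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "m": m, "u": u})
    return MethylationSample(sample_id=sample_id, group=group, data=df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_methylome():
    """A small grouped methylome simulation shared across tests."""
    from methylmemory.simulate import GroupSpec, MethylomeSimConfig, simulate_methylomes

    cfg = MethylomeSimConfig(
        n_chrom=1,
        chrom_len=600_000,
        n_dmrs=6,
        dmr_width=2000,
        delta=0.3,
        coverage_mean=15.0,
        island_count=6,
        groups=(
            GroupSpec("acinar", 3, 0.5, 0.0),
            GroupSpec("adm", 3, 0.5, 1.0),
            GroupSpec("recovered", 3, 0.5, None),
        ),
        memory_multiplier=0.5,
        chrx_len=100_000,
        seed=42,
    )
    samples, truth = simulate_methylomes(cfg)
    return cfg, samples, truth
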