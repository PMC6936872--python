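import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poolsweep as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_pools():
    return [ps.PoolSpec("breedA", 12), ps.PoolSpec("breedB", 10)]


@pytest.fixture
def small_layout():
    return ps.GenomeLayout([("chr1", 3_000_000)])


@pytest.fixture
def small_sim(small_layout, two_pools):
    """~3,000 sites on 3 Mb, two pools, no sweeps."""
    cfg = ps.SimConfig(small_layout, two_pools, seed=11, snv_density=1.0)
    return ps.simulate_pool_sync(cfg)


def brute_force_window_snvs(snvs, window):
    """Oracle: scan every SNV for window membership (no index structure)."""
    return [
        r
        for r in snvs
        if r.chrom == window.chrom and window.start <= r.pos - 1 < window.end
    ]
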