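import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diffislands as di

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_panel() -> di.GenotypePanel:
    """3 SNPs x 4 individuals, two populations in two groups."""
    return di.GenotypePanel(
        snp_ids=np.array(["rs1", "rs2", "rs3"], dtype=object),
        chrom=np.array(["1", "1", "2"], dtype=object),
        pos=np.array([100, 250, 90], dtype=np.int64),
        genotypes=np.array([[0, 1, 2, 1],
                            [2, 2, 0, 0],
                            [1, 0, 1, 2]], dtype=np.int8),
        sample_ids=np.array(["a", "b", "c", "d"], dtype=object),
        sample_pop=np.array(["P1", "P1", "P2", "P2"], dtype=object),
        pop_group={"P1": "G1", "P2": "G2"},
    )


def random_panel(seed: int, n_snps: int = 30, n_pops: int = 4,
                 per_pop: int = 6, n_groups: int = 2,
                 missing_rate: float = 0.1) -> di.GenotypePanel:
    """Small random panel helper used across test modules."""
    rng = np.random.default_rng(seed)
    n_ind = n_pops * per_pop
    g = rng.integers(0, 3, size=(n_snps, n_ind)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = di.MISSING
    pops = np.repeat([f"P{k}" for k in range(n_pops)], per_pop)
    groups = {f"P{k}": f"G{k % n_groups}" for k in range(n_pops)}
    pos = np.sort(rng.choice(10**6, size=n_snps, replace=False)) + 1
    return di.GenotypePanel(
        snp_ids=np.array([f"s{i}" for i in range(n_snps)], dtype=object),
        chrom=np.array(["1"] * n_snps, dtype=object),
        pos=pos,
        genotypes=g,
        sample_ids=np.array([f"i{j}" for j in range(n_ind)], dtype=object),
        sample_pop=np.array(pops, dtype=object),
        pop_group=groups,
    )
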