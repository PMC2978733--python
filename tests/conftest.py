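import numpy as np
import pandas as pd
import pytest

import copydepth as cd


def simulate_adjusted(
    n_loci, n_samples, genotypes, alpha, sigma2_bg, seed, length=3000, depth_per_kb=200 / 3
):
    """Count table with r_adj filled (no GC bias planted, so raw == adjusted)."""
    loci = cd.uniform_loci(n_loci, length=length, depth_per_kb=depth_per_kb, seed=seed)
    cfg = cd.SimConfig(
        n_samples, loci, genotypes, seed=seed + 1, alpha=alpha, sigma2_bg=sigma2_bg
    )
    counts, truth = cd.simulate_counts(cfg)
    counts = counts.rename(columns={"r_raw": "r_adj"})
    return counts, truth


@pytest.fixture
def small_reference():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return {"chr1": seq}


@pytest.fixture
def vmodel():
    return cd.VarianceModel(alpha=1.0, sigma2_bg=0.002)


@pytest.fixture
def gmodel():
    return cd.GenotypeModel()
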