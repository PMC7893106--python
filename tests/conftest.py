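"""Shared fixtures: the frozen tiny oracle dataset and medium simulated data."""

import numpy as np
import pandas as pd
import pytest

from poolcheck import (GenotypeMatrix, MethodSpec, PoolDesign,
                       PoolFrequencyTable, align, simulate_genotypes,
                       simulate_pool_set)

# Frozen 3-animal x 8-SNP dataset with two pools of one method.  Pool P1 was
# generated from weights (0.5, 0.3, 0.2) and P2 from a small perturbation of
# them, both with SD-0.02 measurement noise, so the contribution variance is
# well inside the interior of the parameter space and the two pools are
# strongly correlated.
TINY_DOSAGES = np.array([
    [2., 1., 2., 0., 1., 1., 1., 2.],
    [1., 0., 1., 1., 1., 2., 0., 0.],
    [1., 0., 2., 2., 0., 1., 1., 0.],
])
TINY_Y1 = np.array([0.77257945, 0.24772105, 0.83319687, 0.33351038,
                    0.41301186, 0.66486508, 0.36086309, 0.48668981])
TINY_Y2 = np.array([0.75056793, 0.24825842, 0.86994565, 0.39115105,
                    0.38482474, 0.64800639, 0.36692346, 0.49763179])


def make_tiny_dataset():
    gm = GenotypeMatrix([f"A{i+1}" for i in range(3)],
                        [f"S{j+1}" for j in range(8)], TINY_DOSAGES)
    meta = pd.DataFrame(
        {"method": ["CBC", "CBC"], "construction_replicate": [1, 1],
         "extraction_replicate": [1, 2]},
        index=pd.Index(["P1", "P2"], name="pool_id"))
    pft = PoolFrequencyTable(["P1", "P2"], gm.snp_ids,
                             np.vstack([TINY_Y1, TINY_Y2]), meta)
    return align(gm, pft)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def medium_dataset():
    """20 animals x 800 SNPs, 2 methods x 1 x 2 pools; fast but informative."""
    rng = np.random.default_rng(314)
    gm = simulate_genotypes(20, 800, rng=rng)
    design = PoolDesign(
        methods=(MethodSpec("CBC", 0.01, 0.95), MethodSpec("Volume", 0.02, 0.95)),
        constructed_pools=1, extractions=2, n_animals=20, n_snps=800,
        array_noise_sd=0.004)
    pools, truth = simulate_pool_set(gm, design, rng=rng)
    return align(gm, pools), truth
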