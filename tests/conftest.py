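import numpy as np
import pandas as pd
import pytest

import meipop as mp


@pytest.fixture
def small_sim_config():
    """Single-population desk-scale study conditions."""
    return mp.SimConfig(
        theta_by_family={"Alu": 400.0, "L1": 60.0, "SVA": 15.0},
        n_samples_by_pop={"CEU": 60},
        genome_length=200_000_000,
        coverage_mean=4.0,
        seed=7,
    )


@pytest.fixture
def small_catalog(small_sim_config):
    loci, tracks = mp.simulate_catalog(small_sim_config)
    return loci, tracks


def make_locus(pos, family="Alu", chrom="chr1", **kw):
    return mp.MeiLocus(chrom=chrom, pos=pos, family=family, **kw)


@pytest.fixture
def locus_factory():
    return make_locus
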