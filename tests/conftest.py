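import numpy as np
import pandas as pd
import pytest

import methylite as ml
from methylite.io import CX_COLUMNS


def make_sample(rows, sample_id="s"):
    """Build a MethylomeSample from (chrom, pos, strand, m, u, ctx, tri) rows."""
    data = pd.DataFrame(rows, columns=CX_COLUMNS)
    return ml.MethylomeSample(sample_id=sample_id, data=data)


@pytest.fixture(scope="session")
def small_reference():
    cfg = ml.SimConfig(seed=7, chrom_lengths={"Chr1": 50_000})
    return cfg, ml.generate_reference(cfg)


@pytest.fixture(scope="session")
def planted_pair(small_reference):
    """A seeded sample pair with four planted CG DMRs plus its truth."""
    cfg, ref = small_reference
    truth_a, truth_b = ml.plant_dmrs(
        ref, n_dmrs=4, context="CG", m_a=0.1, m_b=0.8,
        min_sites=10, region_len=1000, seed=11,
    )
    sample_a = ml.simulate_counts(truth_a, cfg, seed=21, sample_id="wt")
    sample_b = ml.simulate_counts(truth_b, cfg, seed=22, sample_id="mut")
    return truth_a, truth_b, sample_a, sample_b
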