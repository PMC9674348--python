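import numpy as np
import pandas as pd
import pytest

from secretomics import synthdata
from secretomics.msio import IntensityMatrix


@pytest.fixture
def small_config():
    return synthdata.SynthConfig(
        n_proteins=120, n_atlas_genes=60, n_tissues=10, n_adipose_genes=8,
        n_adipokines=3, seed=42,
    )


@pytest.fixture
def cm_small(small_config):
    return synthdata.simulate_cm_matrix(small_config)


@pytest.fixture
def tiny_matrix():
    """Hand-built 4-protein, 2x3-sample matrix with mixed flags."""
    samples = pd.DataFrame(
        {"group": ["A", "A", "A", "B", "B", "B"], "replicate": [1, 2, 3, 1, 2, 3]},
        index=[f"{g}_{r}" for g in "AB" for r in (1, 2, 3)],
    )
    idx = pd.Index(["p1", "p2", "p3", "p4"], name="protein")
    rng = np.random.default_rng(0)
    lfq = pd.DataFrame(rng.uniform(1e5, 1e7, (4, 6)), index=idx, columns=samples.index)
    lfq.iloc[0, 0] = 0.0  # one missing value
    ibaq = lfq * 0.25
    flags = pd.DataFrame(
        {"reverse": [False, True, False, False],
         "contaminant": [False, False, True, False],
         "only_by_site": [False, False, False, False]},
        index=idx,
    )
    genes = pd.Series(["GeneA", "GeneB", "GeneC", "GeneD"], index=idx)
    return IntensityMatrix(lfq=lfq, ibaq=ibaq, samples=samples, flags=flags,
                           gene_symbols=genes)
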