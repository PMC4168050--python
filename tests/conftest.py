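import numpy as np
import pandas as pd
import pytest

from nodentropy import Compendium, simulate_compendium
from nodentropy.synthetic_compendium import SyntheticConfig


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic compendium (seed 1) shared across the suite."""
    return simulate_compendium(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def compendium(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def truth(default_sim):
    return default_sim[1]


def make_compendium(values, gene_ids=None, condition_ids=None, organs=None):
    """Small hand-built compendium for unit tests.

    ``values``: 2-D array-like, genes x conditions.  Conditions default to
    whole-organ leaf samples unless ``organs`` is given.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_cond = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(1, n_genes + 1)]
    condition_ids = condition_ids or [f"c{i}" for i in range(1, n_cond + 1)]
    organs = organs or ["leaf"] * n_cond
    signals = pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"), columns=condition_ids
    )
    meta = pd.DataFrame(
        {
            "organ": organs,
            "treatment": "none",
            "timepoint": np.nan,
            "timepoint_unit": "",
            "sample_class": "whole_organ",
            "replicate_group": condition_ids,
        },
        index=pd.Index(condition_ids, name="condition_id"),
    )
    return Compendium(signals, meta)
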