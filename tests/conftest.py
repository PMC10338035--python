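import numpy as np
import pandas as pd
import pytest

from kidbioage.preprocess import OmicsBlock
from kidbioage.synth import SimConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A 300-child study at default effect sizes, shared across tests."""
    return generate_study(SimConfig(n_children=300, seed=7))


@pytest.fixture(scope="session")
def tiny_sim_config():
    """A deliberately small design for fast end-to-end runs."""
    return SimConfig(
        n_children=120,
        seed=13,
        block_sizes={"proteins": 12, "serum_metab": 24, "urine_metab": 10, "transcripts": 40},
        n_age_features={"proteins": 5, "serum_metab": 8, "urine_metab": 4, "transcripts": 12},
        plate_count=4,
    )


def make_block(values: np.ndarray, feature_ids=None, sample_ids=None, **meta_cols) -> OmicsBlock:
    """Hand-built OmicsBlock with per-feature metadata columns from kwargs."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
    meta["block"] = "test"
    for col, vals in meta_cols.items():
        meta[col] = vals
    return OmicsBlock(
        values=pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=feature_ids),
        feature_meta=meta,
    )
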