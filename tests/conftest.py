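import numpy as np
import pandas as pd
import pytest

from plureval.core_io import CountTable


def make_table(
    values,
    subgenomes=None,
    feature_class="hc_gene",
    roles=None,
    chromosomes=None,
    lengths=None,
    unit="counts",
):
    """Small CountTable builder for unit tests."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    fids = [f"f{i}" for i in range(n_feat)]
    sids = [f"s{j}" for j in range(n_samp)]
    subgenomes = subgenomes or ["A"] * n_feat
    roles = roles or ["synthetic"] * n_samp
    if isinstance(feature_class, str):
        feature_class = [feature_class] * n_feat
    chromosomes = chromosomes or [f"chr1{s}" for s in subgenomes]
    features = pd.DataFrame(
        {
            "feature_class": feature_class,
            "subgenome": subgenomes,
            "chromosome": chromosomes,
            "order_index": np.arange(n_feat),
            "length_bp": lengths if lengths is not None else [1000] * n_feat,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "genotype_id": [f"g_{r}" for r in roles],
            "tissue": ["grain"] * n_samp,
            "generation_label": ["C2"] * n_samp,
            "role": roles,
            "replicate_of": [f"g_{r}" for r in roles],
        },
        index=pd.Index(sids, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=features.index, columns=samples.index)
    return CountTable(vals, features, samples, unit=unit)


@pytest.fixture
def tiny_table():
    return make_table([[10, 20], [30, 40]], subgenomes=["A", "D"])
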