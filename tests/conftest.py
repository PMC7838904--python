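import numpy as np
import pandas as pd
import pytest

from metaexpr.core_io import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_dataset(
    values,
    groups,
    dataset_id="ds1",
    platform_id="p1",
    feature_ids=None,
    sample_ids=None,
    tumor_content=None,
    feature_level="gene",
):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    if feature_ids is None:
        feature_ids = [f"G{i}" for i in range(nf)]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(ns)]
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform_id=platform_id,
        values=values,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        sample_groups=list(groups),
        tumor_content=tumor_content,
        feature_level=feature_level,
    )


@pytest.fixture
def small_dataset(rng):
    values = rng.normal(7.0, 1.0, size=(20, 8))
    groups = ["control"] * 4 + ["primary_tumor"] * 4
    return make_dataset(values, groups)


@pytest.fixture
def two_platform_frames(rng):
    """Two gene x sample frames over a shared 30-gene universe."""
    genes = [f"G{i}" for i in range(30)]
    a = pd.DataFrame(rng.normal(size=(30, 12)), index=genes)
    b = pd.DataFrame(rng.normal(size=(30, 10)), index=genes)
    return {"pA": a, "pB": b}
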