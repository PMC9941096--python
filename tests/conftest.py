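import numpy as np
import pandas as pd
import pytest

from lipid4d.core import BucketTable, Feature4D, ToleranceSet
from lipid4d.core.types import PROV_MISSING, PROV_PRIMARY
from lipid4d.simulate import SimulationConfig, gen_library


@pytest.fixture
def tol():
    return ToleranceSet()


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, n_per_class=4, n_background=10)


@pytest.fixture
def small_library(small_config):
    entries, _ = gen_library(small_config)
    return entries


def feature(mz=760.5851, rt=10.0, ccs=290.0, area=1000.0,
            polarity="negative", sample_id=None):
    return Feature4D(mz=mz, rt=rt, ccs=ccs, area=area, polarity=polarity,
                     sample_id=sample_id)


def make_bucket_table(coords, values, polarity="negative"):
    """coords: list of (mz, rt, ccs); values: dict sample -> list of
    areas (None = missing)."""
    index = pd.RangeIndex(len(coords), name="bucket_id")
    buckets = pd.DataFrame(coords, columns=["mz", "rt", "ccs"], index=index)
    vals = pd.DataFrame(values, index=index, dtype=float)
    prov = pd.DataFrame(
        np.where(vals.notna(), PROV_PRIMARY, PROV_MISSING),
        index=index, columns=vals.columns)
    return BucketTable(buckets=buckets, values=vals, provenance=prov,
                       polarity=polarity)
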