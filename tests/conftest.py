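import numpy as np
import pandas as pd
import pytest

from rescuetax.io import AbundanceTable, StudyDesign


@pytest.fixture
def toy_counts():
    data = pd.DataFrame(
        [[10, 30, 0], [5, 5, 10], [1, 1, 18], [8, 8, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["taxA", "taxB", "taxC"],
    )
    return AbundanceTable(data=data, mode="counts")


@pytest.fixture
def toy_design_2groups():
    """Six samples, two groups - small enough for exhaustive permutation."""
    ids = [f"s{i}" for i in range(1, 7)]
    return pd.Series(["g1", "g1", "g1", "g2", "g2", "g2"], index=ids)


@pytest.fixture
def three_group_design():
    ids = [f"s{i}" for i in range(1, 10)]
    labels = ["ND"] * 3 + ["WD"] * 3 + ["WD-T070"] * 3
    return StudyDesign(assignments=pd.Series(labels, index=ids))


def make_relative_table(values, sample_ids=None, taxon_ids=None, level=None):
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(1, len(values) + 1)]
    if taxon_ids is None:
        taxon_ids = [f"t{j}" for j in range(1, values.shape[1] + 1)]
    rel = values / values.sum(axis=1, keepdims=True)
    return AbundanceTable(
        data=pd.DataFrame(rel, index=sample_ids, columns=taxon_ids),
        mode="relative", level=level,
    )
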