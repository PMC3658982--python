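import numpy as np
import pandas as pd
import pytest

from tnbcomics.expression import OmicsMatrix
from tnbcomics.synthetic import CohortDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20230520)


@pytest.fixture
def small_design():
    """A reduced cohort for fast end-to-end tests."""
    return CohortDesign(
        n_per_subgroup={"TNBC": 8, "Her2": 6, "LB": 6, "LA": 6, "healthy": 5},
        seed=7,
    )


def make_matrix(values, subgroups, batches=None, replicate_groups=None,
                feature_ids=None, layer="mRNA"):
    """Assemble an OmicsMatrix from plain arrays for unit tests."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    samples = [f"s{i:02d}" for i in range(n)]
    info = pd.DataFrame({
        "subgroup": list(subgroups),
        "batch": list(batches) if batches is not None else ["b1"] * n,
        "replicate_group": list(replicate_groups) if replicate_groups is not None else samples,
    }, index=pd.Index(samples, name="sample_id"))
    if feature_ids is None:
        feature_ids = [f"g{i:03d}" for i in range(values.shape[0])]
    return OmicsMatrix(layer=layer,
                       values=pd.DataFrame(values, index=feature_ids, columns=samples),
                       sample_info=info)
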