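import numpy as np
import pandas as pd
import pytest

from cortiscope.io import CountMatrix
from cortiscope.simulate import (
    CohortSpec,
    GroupSpec,
    default_cohort_spec,
    simulate_annotation,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped synthetic cohort used by several suites."""
    spec = default_cohort_spec(seed=101)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def two_group_cohort():
    """A plain 8v8 single-tissue cohort with 50 planted genes at |log2FC| = 4."""
    ids = [f"g{i:04d}" for i in range(1, 2001)]
    rng = np.random.default_rng(77)
    chosen = rng.choice(2000, size=50, replace=False)
    from cortiscope.simulate import PlantedDeg

    planted = [
        PlantedDeg(ids[i], "tumor", 4.0 if j % 2 == 0 else -4.0)
        for j, i in enumerate(chosen)
    ]
    spec = CohortSpec(
        n_genes=2000,
        groups=[
            GroupSpec("tumor", "case", "tissue", 8),
            GroupSpec("normal", "control", "tissue", 8),
        ],
        dispersion=0.05,
        planted_degs=planted,
        seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def annotation():
    return simulate_annotation(seed=3)


@pytest.fixture()
def tiny_matrix():
    counts = pd.DataFrame(
        {"s1": [1, 0, 7], "s2": [2, 5, 7]},
        index=["g1", "g2", "g3"],
        dtype=np.int64,
    )
    meta = pd.DataFrame(
        {
            "tissue": ["t", "t"],
            "condition": ["case", "control"],
            "group": ["tumor", "normal"],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)
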