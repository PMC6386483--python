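import numpy as np
import pandas as pd
import pytest

from peakmine import FixtureSpec, PeakTable, SampleMetadata, generate_fixture


@pytest.fixture
def toy_table() -> PeakTable:
    """3 molecules x 4 samples with an M/Z annotation column."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [5.0, 0.0, 1.5, 2.25],
        ]
    )
    return PeakTable(
        ["901.7314", "903.7465", "777.1000"],
        ["C01", "C02", "T01", "T02"],
        values,
        {"M/Z": {"901.7314": "901.73", "903.7465": "903.75", "777.1000": "777.10"}},
    )


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    features = pd.DataFrame(
        {"group": ["D", "D", "DE", "DE"], "time": [0.0, 2.0, 0.0, 2.0]},
        index=["C01", "C02", "T01", "T02"],
    )
    return SampleMetadata(["C01", "C02", "T01", "T02"], features, "week")


@pytest.fixture
def cohort_fixture():
    """Default two-cohort time-course fixture with planted structure."""
    spec = FixtureSpec(
        m=60,
        correlation_blocks=((5, 0.95),),
        regulated_sets=((6, 2.5), (6, 0.4)),
        archetypes=0,
        noise_sigma=0.25,
        seed=11,
    )
    return generate_fixture(spec)


def make_separated_profiles(
    n_archetypes: int, per_cluster: int, n_samples: int, seed: int, separation: float = 8.0
):
    """Well-separated profile groups plus their planted labels."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_archetypes, n_samples)) * 4.0
    rows, labels = [], []
    for a in range(n_archetypes):
        for _ in range(per_cluster):
            rows.append(centers[a] + rng.standard_normal(n_samples) * (4.0 / separation))
            labels.append(a)
    return np.array(rows), np.array(labels)
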