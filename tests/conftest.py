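import numpy as np
import pandas as pd
import pytest

from nichepart import SimulationSpec, ThresholdConfig


@pytest.fixture
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def spec() -> SimulationSpec:
    return SimulationSpec(seed=7)


@pytest.fixture
def samples_two_sites() -> pd.DataFrame:
    """Six tongue + six plaque samples from three subjects."""
    rows = []
    for i, subject in enumerate(["s1", "s2", "s3"]):
        for site in ("tongue", "plaque"):
            for day in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{subject}_{site}_d{day}",
                        "subject_id": subject,
                        "site": site,
                        "total_reads": 1_000_000 * (i + 1),
                        "nonhuman_reads": 800_000 * (i + 1),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
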