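from datetime import date

import numpy as np
import pytest

from lucmap import DEFAULT_VOCABULARY, N_STEPS, TimeSeriesSample
from lucmap.data_model import BANDS


@pytest.fixture
def vocab():
    return DEFAULT_VOCABULARY


def make_constant_sample(value: float, label: str) -> TimeSeriesSample:
    """A sample whose four band series are constant at ``value``."""
    return TimeSeriesSample(
        longitude=-55.0,
        latitude=-12.0,
        start_date=date(2013, 9, 1),
        end_date=date(2014, 8, 31),
        label=label,
        series={b: np.full(N_STEPS, value) for b in BANDS},
    )


def make_cluster_samples(
    centers: dict[str, float], n_each: int, sd: float, seed: int
) -> list[TimeSeriesSample]:
    """Well-separated constant-valued clusters, one per label."""
    rng = np.random.default_rng(seed)
    samples = []
    for label, center in centers.items():
        for _ in range(n_each):
            samples.append(
                TimeSeriesSample(
                    longitude=-55.0,
                    latitude=-12.0,
                    start_date=date(2013, 9, 1),
                    end_date=date(2014, 8, 31),
                    label=label,
                    series={
                        b: np.clip(
                            center + rng.normal(0, sd, N_STEPS), -1.0, 1.0
                        )
                        for b in BANDS
                    },
                )
            )
    return samples
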