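import warnings

import numpy as np
import pytest

from soseq.io_core import SyllableSequence
from soseq.synthetic import SyntheticConfig, generate_experiment

warnings.filterwarnings(
    "ignore", message="transition network is not strongly connected"
)


def make_seq(labels, context="solitary", frame_rate=25.0, **kw):
    defaults = dict(
        recording_id="r0",
        animal_id="a0",
        context=context,
        light_cycle="normal",
        labels=np.asarray(labels, dtype=np.int64),
        frame_rate=frame_rate,
    )
    defaults.update(kw)
    return SyllableSequence(**defaults)


@pytest.fixture(scope="session")
def planted():
    """Default planted experiment at seed 11, shared across tests."""
    cfg = SyntheticConfig(seed=11)
    dataset, gt = generate_experiment(cfg)
    return cfg, dataset, gt


@pytest.fixture(scope="session")
def small_planted():
    """A reduced planted experiment for cheap smoke-level checks."""
    cfg = SyntheticConfig(seed=5, n_animals_per_context=6, duration_s=420)
    dataset, gt = generate_experiment(cfg)
    return cfg, dataset, gt
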