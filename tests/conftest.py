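import numpy as np
import pytest

from xspecies.chip_model import ChipLayout, ProbeIntensityTable, ProbePair
from xspecies.synth import SimulationConfig, simulate


@pytest.fixture(scope="session")
def tiny_layout() -> ChipLayout:
    """Two probe-sets: PS1 with 3 pairs, PS2 with 2 pairs."""
    return ChipLayout(
        probe_sets={
            "PS1": [ProbePair(0, 1, 1), ProbePair(2, 3, 2), ProbePair(4, 5, 3)],
            "PS2": [ProbePair(6, 7, 1), ProbePair(8, 9, 2)],
        },
        chip_name="tiny",
    )


def gdna_table(values: dict[int, float], array_id: str = "g1") -> ProbeIntensityTable:
    return ProbeIntensityTable(array_id=array_id, kind="gdna", condition="", intensities=values)


@pytest.fixture(scope="session")
def small_dataset():
    """200 probe-sets under default (cross-species) conditions, seed 1."""
    cfg = SimulationConfig(n_probe_sets=200, seed=1)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """No divergence, no background floor, mild noise: the easy regime."""
    cfg = SimulationConfig(
        n_probe_sets=200, divergence_fraction=0.0, nonspecific_scale=0.0,
        noise_sd=0.1, seed=2,
    )
    return cfg, simulate(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
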