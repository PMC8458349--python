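import numpy as np
import pandas as pd
import pytest

from ploidygate import SimulationConfig, generate_population, load_table1_fixture
from ploidygate.events import EventSet
from ploidygate.stages import StageLabel


@pytest.fixture(scope="session")
def table1_records():
    return load_table1_fixture()


def make_event_set(fluor, area=None, focus=60.0, **morphology) -> EventSet:
    """Small in-memory event set for unit tests."""
    fluor = np.asarray(fluor, dtype=float)
    n = len(fluor)
    df = pd.DataFrame(
        {
            "dna_fluorescence": fluor,
            "cell_area": np.full(n, 10.0) if area is None else np.asarray(area, float),
            "focus_metric": np.full(n, float(focus)),
        }
    )
    for col, vals in morphology.items():
        df[col] = pd.array(vals, dtype="Int64")
    return EventSet(df)


def clean_config(**overrides) -> SimulationConfig:
    """Artifact-free, error-free simulation config for targeted tests."""
    defaults = dict(
        debris_fraction=0.0,
        aggregate_fraction=0.0,
        unfocused_fraction=0.0,
        morphology_error_rate=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


#: Discrete-ploidy mixture: every stage maps to a single DNA content, so
#: gate membership is unambiguous away from measurement noise.
DISCRETE_STAGES = {
    StageLabel.VEGETATIVE: 0.85,
    StageLabel.MITOTIC_DIVIDING: 0.10,
    StageLabel.ZYGOTE: 0.02,
    StageLabel.DYAD: 0.01,
    StageLabel.TRIAD: 0.01,
    StageLabel.TETRAD: 0.01,
}


def hyper_resident_fractions(sexual: float) -> dict:
    """Mixture whose sexual stages all carry DNA content above the 2C gate."""
    per = sexual / 4.0
    return {
        StageLabel.VEGETATIVE: 1.0 - sexual - 0.11,
        StageLabel.MITOTIC_S: 0.05,
        StageLabel.MITOTIC_DIVIDING: 0.06,
        StageLabel.MEIOTIC_S: per,
        StageLabel.DYAD: per,
        StageLabel.TRIAD: per,
        StageLabel.TETRAD: per,
    }


@pytest.fixture(scope="session")
def default_population():
    cfg = SimulationConfig(n_events=40_000, seed=1)
    events, truth = generate_population(cfg)
    return cfg, events, truth
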