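import numpy as np
import pytest

from audthal import pipeline, synth
from audthal.stimuli import build_stimulus_grid


@pytest.fixture(scope="session")
def grid():
    return build_stimulus_grid()


@pytest.fixture(scope="session")
def unit_population(grid):
    """A modest reference unit population shared across neural tests."""
    config = synth.UnitGenConfig(n_units=60)
    spikes, truth = synth.generate_unit_population(config, grid, seed=101)
    return {"config": config, "spikes": spikes, "truth": truth}


@pytest.fixture(scope="session")
def unit_analysis(grid, unit_population):
    """Full FRA -> fits -> CF analysis of the shared population."""
    return pipeline.analyze_units(unit_population["spikes"], grid,
                                  n_starts=8, seed=0)


@pytest.fixture(scope="session")
def behavior_sessions():
    """Reference behavioral sessions at reduced size for unit tests."""
    config = synth.BehaviorGenConfig(n_animals=4, n_sessions=3,
                                     trials_per_session=250)
    trials, truth = synth.generate_behavior_sessions(config, seed=7)
    return {"config": config, "trials": trials, "truth": truth}
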