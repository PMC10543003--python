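import numpy as np
import pandas as pd
import pytest

from brewtime.containers import SampleMetadata
from brewtime.synthetic import (
    BatchShift,
    ComplexPlan,
    SimulationConfig,
    TrajectoryClass,
    simulate_timecourse,
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, fully featured simulation: 300 proteins, 17 time points."""
    base = dict(
        n_proteins=300,
        trajectory_classes=[
            TrajectoryClass("early_peak", 30, 2.0),
            TrajectoryClass("late_rise", 30, 2.0),
            TrajectoryClass("flat_then_drop", 30, 2.0),
            TrajectoryClass("monotone_down", 30, 2.0),
        ],
        batch_shifts=[BatchShift("B15", 20, 1.5)],
        complex_plan=[ComplexPlan(5, 0.9)] * 6,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_simulation():
    return simulate_timecourse(small_config(seed=11))


@pytest.fixture
def two_tp_metadata():
    """Two time points x two replicates in one batch."""
    table = pd.DataFrame(
        {
            "batch": ["B1"] * 4,
            "time_point": ["0h", "0h", "6h", "6h"],
            "phase": ["fermentation"] * 4,
            "replicate": ["R1", "R2", "R1", "R2"],
        },
        index=pd.Index(["B1_0h_R1", "B1_0h_R2", "B1_6h_R1", "B1_6h_R2"], name="sample"),
    )
    return SampleMetadata(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
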