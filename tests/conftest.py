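import numpy as np
import pytest

from morphddm.core_ddm import DDMParams, simulate_trials
from morphddm.synthetic import generate_task_schedule


@pytest.fixture(scope="session")
def task_schedule():
    return generate_task_schedule(seed=20240101)


@pytest.fixture(scope="session")
def reference_observer():
    """The canonical mid-bias observer: s_indiff = 8, moderate caution."""
    return DDMParams(v_int=-0.96, v_slope=0.12, a=1.2, z_r=0.5, t0=0.25)


@pytest.fixture(scope="session")
def reference_trials(reference_observer, task_schedule):
    """450 simulated trials of the reference observer on the task schedule."""
    s, runs = task_schedule.stimulus_sequence()
    return simulate_trials(reference_observer, s, seed=7, runs=runs)
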