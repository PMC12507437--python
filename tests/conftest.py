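import numpy as np
import pytest

import vistune as vt
from vistune.synth import STIM_DURATION


@pytest.fixture(scope="session")
def small_dataset():
    """Two groups x two animals x three units, both batteries, fixed seed."""
    specs = [
        vt.GroupSpec("control", 2, 3),
        vt.GroupSpec(
            "EO1contra", 2, 3,
            parameter_distributions={"lpi": {"loc": 0.35}, "background": {"loc": 6.6}},
        ),
    ]
    records, truth = vt.simulate_dataset(specs, batteries=("B1", "B2"), seed=20240915)
    return records, truth


def make_unit(rate_table, unit_id="u0", animal_id="a0", group="control",
              blank_rate=2.0, n_trials=5, battery="B2", rng=None,
              duration=STIM_DURATION):
    """Build a UnitRecord from {condition: mean_rate}; Poisson noise if rng given."""
    rec = vt.UnitRecord(unit_id=unit_id, animal_id=animal_id,
                        hemisphere="left", group=group)
    drift = "unidirectional" if battery == "B2" else "back_and_forth"
    blank = vt.StimulusCondition(kind="blank", duration=duration, drift_mode=drift)
    table = dict(rate_table)
    table[blank] = blank_rate
    for cond, mu in table.items():
        for r in range(n_trials):
            if rng is None:
                rate = float(mu)
            else:
                rate = rng.poisson(mu * duration) / duration
            rec.trials.append(
                vt.TrialObservation(unit_id=unit_id, condition=cond,
                                    trial_index=r, rate_mean=rate)
            )
    return rec


@pytest.fixture
def unit_factory():
    return make_unit
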