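import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from ibisflight import synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_ecg_400():
    """Noise-free 60 s ECG at a constant 400 bpm, with ground truth."""
    profile = synthetic.HRProfile(breakpoints=[(0.0, 400.0)], seed=11)
    return synthetic.generate_ecg(profile, duration=60.0)


@pytest.fixture(scope="session")
def flap_glide_session():
    """40 s alternating flap/glide plan at 75 % glide, with truth labels."""
    plan = synthetic.plan_for_proportion(0.75, duration=40.0, seed=3)
    return plan, synthetic.generate_accel(plan)


@pytest.fixture(scope="session")
def simple_itinerary_track():
    """stopover, 60 km, 70 km, stopover itinerary with truth."""
    days = [
        synthetic.DayPlan(dt.date(2019, 3, 1), 10.0, "stopover"),
        synthetic.DayPlan(dt.date(2019, 3, 2), 60.0, "migration"),
        synthetic.DayPlan(dt.date(2019, 3, 3), 70.0, "migration"),
        synthetic.DayPlan(dt.date(2019, 3, 4), 10.0, "stopover"),
    ]
    it = synthetic.Itinerary(days=days, start_location=(42.43, 11.21),
                             breeding_site=(48.16, 12.83),
                             fixes_per_day=52, seed=7)
    return it, synthetic.generate_gps_track(it, bird="b1",
                                            attachment="leg_loop")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
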