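import numpy as np
import pytest

from mibci import DEFAULT_MONTAGE
from mibci.protocol import TrialTimeline, build_session_schedule
from mibci.pso import PSOConfig
from mibci.synth import (
    BandEffect,
    ConditionEffects,
    ParticipantProfile,
    generate_session,
)


@pytest.fixture(scope="session")
def montage():
    return DEFAULT_MONTAGE


@pytest.fixture
def timeline():
    return TrialTimeline(relax_duration=4.0)


@pytest.fixture(scope="session")
def fast_pso():
    """Reduced-budget PSO for tests that calibrate the full pipeline."""
    return PSOConfig(swarm_size=10, iterations=10, seed=0)


def make_session(erd_alpha=-0.5, erd_beta=0.0, n_trials=40, seed=0,
                 condition="continuous", phase="calibration",
                 bilateral=True, **profile_kwargs):
    """Synthetic session with a planted alpha/beta ERD, small enough for tests."""
    effects = {
        condition: ConditionEffects(
            alpha=BandEffect(contra=erd_alpha,
                             ipsi=erd_alpha if bilateral else 0.0),
            beta=BandEffect(contra=erd_beta, ipsi=erd_beta),
        )
    }
    profile = ParticipantProfile(effects=effects, seed=seed, **profile_kwargs)
    schedule = build_session_schedule(
        "P01", condition, phase, seed=seed + 1,
        n_runs=1, trials_per_run=n_trials,
    )
    return generate_session(profile, schedule)


@pytest.fixture(scope="session")
def strong_session():
    return make_session(erd_alpha=-0.6, n_trials=40, seed=42)


@pytest.fixture(scope="session")
def null_session():
    return make_session(erd_alpha=0.0, n_trials=40, seed=43)
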