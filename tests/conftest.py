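import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import boarsleep as bs  # noqa: E402


@pytest.fixture(scope="session")
def noiseless_cfg():
    return bs.TraceGenConfig(noise_sd=0.0, posture_angle_jitter=0.0, seed=7)


@pytest.fixture(scope="session")
def mixed_schedule():
    """One hour covering every behaviour and transition class."""
    return bs.make_schedule(
        [
            ("active", 10),
            ("sternal_still", 12),
            ("active", 6),
            ("lateral_still", 8),
            ("sternal_still", 7),
            ("standing_still", 5),
            ("sternal_still", 4),  # below the 5-min minimum
            ("active", 8),
        ]
    )


@pytest.fixture(scope="session")
def mixed_kin(mixed_schedule, noiseless_cfg):
    trace = bs.generate_trace(mixed_schedule, noiseless_cfg)
    return bs.compute_kinematics(trace)


def random_posture_vedba(rng, n):
    """Blocky random posture/VeDBA sequences that exercise the bout rules."""
    posture = np.zeros(n, dtype=np.int8)
    vs = np.full(n, 0.5)
    i = 0
    while i < n:
        ln = int(rng.integers(1, 120))
        state = rng.integers(0, 4)
        j = min(i + ln, n)
        if state > 0:
            posture[i:j] = rng.choice([1, 2])
            vs[i:j] = rng.uniform(0.0, 0.3, j - i)
        i = j
    return posture, vs
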