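import numpy as np
import pytest

from pvchr import (
    BeatRecord,
    LinearRampProfile,
    MechanismConfig,
    MechanismKind,
    NoiseMask,
    SimulationSpec,
    simulate_record,
)


def make_record(times, labels, record_id="R0", mask=(), total_duration=None):
    """Construct a small BeatRecord from explicit times and N/V labels."""
    times = np.asarray(times, dtype=float)
    is_pvc = np.asarray([l == "V" for l in labels], dtype=bool)
    return BeatRecord(
        record_id,
        times,
        is_pvc,
        NoiseMask(tuple(mask)),
        total_duration if total_duration is not None else float(times[-1]) + 1.0,
    )


def bigeminy_minute(minute_start: float, hr: float = 80.0):
    """Times/labels of one fully-bigeminal minute at constant heart rate."""
    period = 60.0 / hr
    times, labels = [], []
    t = minute_start + period
    while t < minute_start + 60.0 - 1e-9:
        times.append(t)
        labels.append("N")
        times.append(t + 0.4)
        labels.append("V")
        t += 2 * period
    return times, labels


@pytest.fixture(scope="session")
def bigeminy_record():
    """10 minutes of strict bigeminy at a constant 80 bpm, no jitter."""
    return simulate_record(
        SimulationSpec(
            record_id="BIG80",
            mechanism=MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=1),
            hr_profile=LinearRampProfile(80, 80, 600.0, jitter_sd=0.0),
            duration_s=600.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def circadian_bigeminy_record():
    """One day of bigeminy under circadian heart-rate variation with jitter."""
    from pvchr import CircadianProfile

    return simulate_record(
        SimulationSpec(
            record_id="BIGC",
            days=1,
            mechanism=MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=1),
            hr_profile=CircadianProfile(75, 12, jitter_sd=2.5),
            seed=13,
        )
    )


@pytest.fixture(scope="session")
def ramp_bigeminy_record():
    """Bigeminy with heart rate ramping 60 to 100 bpm over 4 hours."""
    return simulate_record(
        SimulationSpec(
            record_id="RAMP1",
            mechanism=MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=1),
            hr_profile=LinearRampProfile(60, 100, 4 * 3600.0, jitter_sd=0.0),
            duration_s=4 * 3600.0,
            seed=11,
        )
    )
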