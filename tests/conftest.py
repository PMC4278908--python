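import dataclasses

import pytest

from startlekit.paradigm import ScheduleConfig, build_schedule
from startlekit.synth import ParticipantParams


def small_schedule_config(**overrides) -> ScheduleConfig:
    """Compact session for fast EMG-level tests: 4+4 CS trials per phase,
    all probed, short ITIs and phase gap."""
    base = dict(
        n_habituation_tones=3,
        habituation_itis_s=(4.0,),
        n_cs_plus=4,
        n_cs_minus=4,
        reinforcement_fraction=0.5,
        probe_fraction_cs=1.0,
        n_iti_probes=4,
        iti_durations_s=(4.0,),
        lead_in_s=3.0,
        phase_gap_s=10.0,
        seed=0,
    )
    base.update(overrides)
    return ScheduleConfig(**base)


def clean_participant(**overrides) -> ParticipantParams:
    """Deterministic responder: no noise, no non-responses, no artifacts,
    no habituation, no latency jitter."""
    base = dict(
        baseline_noise_rms=0.0,
        p_nonresponse=0.0,
        p_artifact=0.0,
        habituation_rate=1.0,
        blink_latency_jitter_ms=0.0,
    )
    base.update(overrides)
    return ParticipantParams(**base)


@pytest.fixture
def paper_schedule():
    return build_schedule(ScheduleConfig(seed=11))


@pytest.fixture
def small_schedule():
    return build_schedule(small_schedule_config(seed=7))
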