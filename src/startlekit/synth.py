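"""Synthetic EMG sessions and cohorts with fear-conditioning structure.

The generator emulates what the analysis chain assumes about a real
recording session: a stationary background EMG floor, and at every probed
trial an orbicularis-oculi blink burst — band-limited (≈30–300 Hz) activity
under a gamma-shaped envelope of ≈60 ms width, starting a jittered latency
after probe onset.  Burst size carries the experimental structure: a
participant-specific ITI blink gain, multiplied by a potentiation factor
that depends on (phase, CS type), and by an exponential habituation factor
per probe ordinal across the session.  Occasional non-response trials and
step/drift electrode artifacts are injected at configurable rates.

Every burst uses one fixed band-limited carrier waveform (scaled and
shifted), so with the noise floor switched off the processed blink peaks
are exactly proportional to the generating potentiation factors — which is
what makes the generator usable as an oracle for the scoring chain.

Cohorts come in two layers sharing one parameter model: a fast score-level
layer that draws each participant's *true* per-cell proportional scores
plus measurement noise (for Monte-Carlo calibration at many replicates),
and the full EMG layer that renders those same participants as continuous
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from .paradigm import (ACQUISITION, CS_MINUS, CS_PLUS, EXTINCTION,
                       HABITUATION, ScheduleConfig, SessionSchedule,
                       build_schedule)

RATE_HZ = 1000.0

MDD = "MDD"
CONTROL = "control"
GROUPS = (MDD, CONTROL)


class UnsupportedRateError(ValueError):
    pass


@dataclass
class EmgRecording:
    """Continuous single-channel EMG trace (µV) with its event schedule."""

    sampling_rate: float
    samples: np.ndarray
    events: SessionSchedule | None = None
    channel_label: str = "EMG_OO_L"
    # generator ground truth (burst/artifact bookkeeping) for oracle tests
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class ParticipantParams:
    """Ground-truth generative parameters for one participant."""

    group: str = CONTROL
    baseline_noise_rms: float = 2.0         # µV
    blink_gain_iti: float = 100.0           # µV, peak envelope of ITI blink
    potentiation: dict[tuple[str, str], float] = field(default_factory=dict)
    blink_latency_ms: float = 45.0
    blink_latency_jitter_ms: float = 5.0
    habituation_rate: float = 0.985         # per probe ordinal
    p_nonresponse: float = 0.05
    p_artifact: float = 0.02
    artifact_amplitude_uv: float = 20_000.0
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.potentiation:
            self.potentiation = default_potentiation(self.group)
        if any(v <= 0 for v in self.potentiation.values()):
            raise ValueError("potentiation factors must be > 0")
        for p in (self.p_nonresponse, self.p_artifact):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.habituation_rate <= 1.0:
            raise ValueError("habituation_rate must lie in (0, 1]")

    def factor(self, phase: str, trial_type: str) -> float:
        if trial_type in (CS_PLUS, CS_MINUS):
            return self.potentiation[(phase, trial_type)]
        return 1.0  # ITI probes and habituation tones: baseline startle


def default_potentiation(group: str) -> dict[tuple[str, str], float]:
    """Mean potentiation factors (relative to the ITI blink).

    Both groups acquire a differential CS+ > CS− response during
    acquisition.  During extinction, the control group retains a CS+ > CS−
    differential (the immediate-extinction deficit), whereas the patient
    group extinguishes fully (no differential).
    """
    pot = {
        (ACQUISITION, CS_PLUS): 1.30,
        (ACQUISITION, CS_MINUS): 0.90,
        (EXTINCTION, CS_MINUS): 0.85,
    }
    pot[(EXTINCTION, CS_PLUS)] = 1.15 if group == CONTROL else 0.85
    return pot


# ---------------------------------------------------------------------------
# blink morphology

_ENV_SHAPE = 2.0          # gamma shape
_ENV_SCALE_S = 0.015      # gamma scale: envelope peak 15 ms after onset
_BURST_DUR_S = 0.25       # rendered burst support
_CARRIER_SEED = 0x5EED    # fixed: one carrier waveform shared by all bursts
_CARRIER_BAND_HZ = (30.0, 300.0)


def blink_envelope(rate: float = RATE_HZ) -> np.ndarray:
    """Gamma-shaped burst envelope, peak normalized to 1."""
    t = np.arange(int(_BURST_DUR_S * rate)) / rate
    env = gamma_dist.pdf(t, a=_ENV_SHAPE, scale=_ENV_SCALE_S)
    return env / env.max()


def _carrier(n: int, rate: float) -> np.ndarray:
    rng = np.random.default_rng(_CARRIER_SEED)
    white = rng.standard_normal(n + 200)
    sos = sps.butter(4, _CARRIER_BAND_HZ, btype="bandpass", fs=rate,
                     output="sos")
    band = sps.sosfiltfilt(sos, white)[100:100 + n]
    return band / np.abs(band).max()


def blink_burst(peak_uv: float, rate: float = RATE_HZ) -> np.ndarray:
    """The canonical blink waveform scaled to a given peak envelope (µV)."""
    env = blink_envelope(rate)
    return peak_uv * env * _carrier(env.size, rate)


# ---------------------------------------------------------------------------
# session synthesis

def simulate_emg_session(schedule: SessionSchedule,
                         params: ParticipantParams,
                         seed: int | np.random.Generator = 0
                         ) -> EmgRecording:
    """Render one participant's continuous EMG for a session schedule."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rate = RATE_HZ
    n = int(round((schedule.duration_s + 20.0) * rate))
    x = np.zeros(n)

    if params.baseline_noise_rms > 0:
        sos = sps.butter(4, (1.0, 200.0), btype="bandpass", fs=rate,
                         output="sos")
        noise = sps.sosfiltfilt(sos, rng.standard_normal(n))
        x += noise * (params.baseline_noise_rms / np.std(noise))

    burst_template = blink_burst(1.0, rate)
    bursts: list[dict] = []
    for ordinal, probe in enumerate(schedule.probes()):
        responded = rng.random() >= params.p_nonresponse
        latency = params.blink_latency_ms
        if params.blink_latency_jitter_ms > 0:
            latency += params.blink_latency_jitter_ms * rng.standard_normal()
        latency = float(np.clip(latency, 25.0, 95.0))
        peak = (params.blink_gain_iti
                * params.factor(probe.phase, probe.trial_type)
                * params.habituation_rate ** ordinal)
        if responded:
            i0 = int(round((probe.probe_onset_s + latency / 1000.0) * rate))
            seg = burst_template[:max(0, min(burst_template.size, n - i0))]
            x[i0:i0 + seg.size] += peak * seg
        bursts.append({"probe_onset_s": probe.probe_onset_s,
                       "phase": probe.phase,
                       "trial_type": probe.trial_type,
                       "ordinal": ordinal,
                       "responded": responded,
                       "latency_ms": latency,
                       "peak_uv": peak if responded else 0.0})

    artifacts: list[dict] = []
    if params.p_artifact > 0:
        for e in schedule.events:
            if e.trial_type in (CS_PLUS, CS_MINUS) and \
                    rng.random() < params.p_artifact:
                t0 = e.onset_s + rng.uniform(0.0, schedule.config.cs_duration_s)
                i0 = int(round(t0 * rate))
                width = int(0.2 * rate)
                x[i0:i0 + width] += params.artifact_amplitude_uv
                artifacts.append({"onset_s": t0, "phase": e.phase,
                                  "trial_type": e.trial_type,
                                  "trial_onset_s": e.onset_s})

    return EmgRecording(rate, x, events=schedule,
                        truth={"bursts": bursts, "artifacts": artifacts,
                               "params": params})


# ---------------------------------------------------------------------------
# cohort design and generation

@dataclass
class CohortDesign:
    """Population-level distributions from which participants are drawn.

    True per-participant potentiation factors are Gaussian around group
    means: each phase's CS− level and CS+−CS− differential are drawn
    separately, so group effects live on the differential.  The score-level
    measurement noise approximates the sampling error of a six-trial mean.
    Within the patient group, illness duration is linked linearly to the
    true extinction differential with correlation ``illness_target_r``
    (longer illness → smaller remaining differential).
    """

    n_mdd: int = 37
    n_control: int = 40

    acq_cs_minus_mean: float = 0.90
    acq_differential_mean: dict[str, float] = field(
        default_factory=lambda: {MDD: 0.40, CONTROL: 0.40})
    ext_cs_minus_mean: float = 0.85
    ext_differential_mean: dict[str, float] = field(
        default_factory=lambda: {MDD: 0.00, CONTROL: 0.30})
    cs_level_sd: float = 0.15
    differential_sd: float = 0.35
    score_noise_sd: float = 0.12

    blink_gain_mean_uv: float = 100.0
    blink_gain_sd_uv: float = 25.0
    baseline_noise_rms: float = 2.0
    blink_latency_ms: float = 45.0
    blink_latency_jitter_ms: float = 5.0
    habituation_rate: float = 0.985
    p_nonresponse: float = 0.05
    p_artifact: float = 0.02
    # probability each CS is identified correctly on the contingency quiz
    p_cs_identified: float = 0.95

    illness_duration_mean_y: float = 10.6
    illness_duration_sd_y: float = 9.5
    illness_target_r: float = -0.40
    age_mean: dict[str, float] = field(
        default_factory=lambda: {MDD: 38.4, CONTROL: 37.3})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {MDD: 12.4, CONTROL: 10.5})
    bdi_mean: dict[str, float] = field(
        default_factory=lambda: {MDD: 29.2, CONTROL: 1.9})
    bdi_sd: dict[str, float] = field(
        default_factory=lambda: {MDD: 10.5, CONTROL: 2.9})

    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mdd <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")


def null_design(**overrides) -> CohortDesign:
    """Design with no CS-type or group effect in either phase.

    Under this design the CS-type×Group interaction holds exactly, so its
    test's p-value should be uniform — the type-I calibration target.
    """
    d = CohortDesign(
        acq_differential_mean={MDD: 0.0, CONTROL: 0.0},
        ext_differential_mean={MDD: 0.0, CONTROL: 0.0},
        **overrides,
    )
    return d


_POS_FLOOR = 0.05


def _draw_participant(design: CohortDesign, group: str,
                      rng: np.random.Generator) -> ParticipantParams:
    d = design
    acq_minus = max(_POS_FLOOR,
                    d.acq_cs_minus_mean + d.cs_level_sd * rng.standard_normal())
    ext_minus = max(_POS_FLOOR,
                    d.ext_cs_minus_mean + d.cs_level_sd * rng.standard_normal())
    acq_diff = (d.acq_differential_mean[group]
                + d.differential_sd * rng.standard_normal())
    ext_diff = (d.ext_differential_mean[group]
                + d.differential_sd * rng.standard_normal())
    pot = {
        (ACQUISITION, CS_MINUS): acq_minus,
        (ACQUISITION, CS_PLUS): max(_POS_FLOOR, acq_minus + acq_diff),
        (EXTINCTION, CS_MINUS): ext_minus,
        (EXTINCTION, CS_PLUS): max(_POS_FLOOR, ext_minus + ext_diff),
    }
    true_ext_diff = pot[(EXTINCTION, CS_PLUS)] - pot[(EXTINCTION, CS_MINUS)]

    cov: dict[str, float] = {
        "age": max(18.0, d.age_mean[group]
                   + d.age_sd[group] * rng.standard_normal()),
        "bdi": max(0.0, d.bdi_mean[group]
                   + d.bdi_sd[group] * rng.standard_normal()),
        "cs_plus_correct": int(rng.random() < d.p_cs_identified),
        "cs_minus_correct": int(rng.random() < d.p_cs_identified),
    }
    if group == MDD:
        rho = d.illness_target_r
        z_diff = ((true_ext_diff - d.ext_differential_mean[group])
                  / d.differential_sd)
        z = rho * z_diff + np.sqrt(max(0.0, 1 - rho ** 2)) \
            * rng.standard_normal()
        cov["illness_duration_years"] = max(
            0.25, d.illness_duration_mean_y + d.illness_duration_sd_y * z)

    gain = max(10.0, d.blink_gain_mean_uv
               + d.blink_gain_sd_uv * rng.standard_normal())
    return ParticipantParams(
        group=group,
        baseline_noise_rms=d.baseline_noise_rms,
        blink_gain_iti=gain,
        potentiation=pot,
        blink_latency_ms=d.blink_latency_ms,
        blink_latency_jitter_ms=d.blink_latency_jitter_ms,
        habituation_rate=d.habituation_rate,
        p_nonresponse=d.p_nonresponse,
        p_artifact=d.p_artifact,
        covariates=cov,
    )


def _participant_rngs(design: CohortDesign) -> list[np.random.Generator]:
    n = design.n_mdd + design.n_control
    ss = np.random.SeedSequence(design.seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _group_labels(design: CohortDesign) -> list[str]:
    return [MDD] * design.n_mdd + [CONTROL] * design.n_control


def simulate_cohort_scores(design: CohortDesign) -> pd.DataFrame:
    """Fast score-level cohort: true cell scores plus measurement noise.

    Returns one row per participant with observed proportional scores for
    each (phase, CS type) cell, the true extinction differential, and
    covariates — the same parameter model as the EMG layer, without
    rendering signals.  Used for Monte-Carlo calibration and power checks.
    """
    rows = []
    for pid, (group, rng) in enumerate(
            zip(_group_labels(design), _participant_rngs(design))):
        p = _draw_participant(design, group, rng)
        noise = design.score_noise_sd
        row = {
            "participant_id": f"sub-{pid:03d}",
            "group": group,
            "acq_cs_plus": p.potentiation[(ACQUISITION, CS_PLUS)]
            + noise * rng.standard_normal(),
            "acq_cs_minus": p.potentiation[(ACQUISITION, CS_MINUS)]
            + noise * rng.standard_normal(),
            "ext_cs_plus": p.potentiation[(EXTINCTION, CS_PLUS)]
            + noise * rng.standard_normal(),
            "ext_cs_minus": p.potentiation[(EXTINCTION, CS_MINUS)]
            + noise * rng.standard_normal(),
            "true_ext_differential":
                p.potentiation[(EXTINCTION, CS_PLUS)]
                - p.potentiation[(EXTINCTION, CS_MINUS)],
        }
        row.update(p.covariates)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["acq_differential"] = df["acq_cs_plus"] - df["acq_cs_minus"]
    df["ext_differential"] = df["ext_cs_plus"] - df["ext_cs_minus"]
    return df


@dataclass
class CohortRecord:
    participant_id: str
    params: ParticipantParams
    schedule: SessionSchedule
    recording: EmgRecording


def simulate_cohort(design: CohortDesign) -> list[CohortRecord]:
    """Full EMG cohort: one continuous recording per participant.

    Per-participant generators are spawned deterministically from the
    design seed, so the cohort is reproducible and stable under group-size
    changes of the *other* group.
    """
    records = []
    for pid, (group, rng) in enumerate(
            zip(_group_labels(design), _participant_rngs(design))):
        params = _draw_participant(design, group, rng)
        sched_seed = int(rng.integers(2 ** 31))
        schedule = build_schedule(
            replace(design.schedule, seed=sched_seed))
        rec = simulate_emg_session(schedule, params, rng)
        records.append(CohortRecord(f"sub-{pid:03d}", params, schedule, rec))
    return records
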