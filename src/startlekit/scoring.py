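"""Startle-response detection, validation, and ITI-proportional scoring.

A probe's response is *valid* when the processed response curve first
exceeds an individual threshold — baseline mean + 3 SD of the 500 ms
pre-probe baseline — and falls back below it, both within 20–110 ms after
probe onset (the latency range of the subcortical startle pathway).  The
response amplitude is the curve's peak in a fixed 40–90 ms target window,
baseline-mean-subtracted and floored at zero.

Per-participant scores are cell means over valid trials only.  CS startle
is expressed proportionally: each CS cell mean is divided by the mean
acquisition ITI startle amplitude, so CS responses are fractions of the
individual background startle level.  The acquisition ITI mean (not a
phase-specific one) also serves as the reference for extinction, so that
changes from acquisition to extinction remain visible despite startle
habituation across the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import (ACQUISITION, CS_MINUS, CS_PLUS, EXTINCTION,
                       HABITUATION_TONE, ITI_PROBE, SessionSchedule,
                       TrialEvent)
from .preprocess import ProcessedSignal

ITI = "ITI"

NO_CROSSING = "no_crossing"
LATE_ONSET = "late_onset"
NO_RETURN = "no_return"
ARTIFACT = "artifact"
NONE = "none"


@dataclass(frozen=True)
class ResponseWindowConfig:
    baseline_ms: float = 500.0
    threshold_k: float = 3.0
    validity_window_ms: tuple[float, float] = (20.0, 110.0)
    amplitude_window_ms: tuple[float, float] = (40.0, 90.0)

    def __post_init__(self) -> None:
        lo, hi = self.validity_window_ms
        alo, ahi = self.amplitude_window_ms
        if not (0 <= lo < hi and 0 <= alo < ahi):
            raise ValueError("response windows must be increasing and >= 0")
        if self.baseline_ms <= 0:
            raise ValueError("baseline_ms must be > 0")


@dataclass
class StartleResponse:
    probe_time_s: float
    trial_ref: TrialEvent
    valid: bool
    invalid_reason: str = NONE
    onset_latency_ms: float | None = None
    amplitude: float | None = None
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0


def detect_startle_response(signal: ProcessedSignal, probe: TrialEvent,
                            config: ResponseWindowConfig | None = None
                            ) -> StartleResponse:
    """Classify one probed trial against the threshold/latency rule."""
    cfg = config or ResponseWindowConfig()
    if probe.probe_onset_s is None:
        raise ValueError("event carries no probe")
    fs = signal.sampling_rate
    y = signal.samples
    p = int(round(probe.probe_onset_s * fs))
    nb = int(round(cfg.baseline_ms / 1000.0 * fs))
    if p - nb < 0:
        raise ValueError(
            f"probe at {probe.probe_onset_s}s too close to recording start "
            f"for a {cfg.baseline_ms:.0f} ms baseline")

    lo = p + int(round(cfg.validity_window_ms[0] / 1000.0 * fs))
    hi = p + int(round(cfg.validity_window_ms[1] / 1000.0 * fs))
    alo = p + int(round(cfg.amplitude_window_ms[0] / 1000.0 * fs))
    ahi = p + int(round(cfg.amplitude_window_ms[1] / 1000.0 * fs))
    if hi >= y.size or ahi >= y.size:
        raise ValueError("probe too close to recording end")

    resp = StartleResponse(probe.probe_onset_s, probe, valid=False)
    if signal.mask_overlaps((p - nb) / fs, (hi + 1) / fs):
        resp.invalid_reason = ARTIFACT
        return resp

    base = y[p - nb:p]
    resp.baseline_mean = float(base.mean())
    resp.baseline_sd = float(base.std(ddof=0))
    threshold = resp.baseline_mean + cfg.threshold_k * resp.baseline_sd

    window = y[lo:hi + 1]
    above = window > threshold          # strict: degenerate sd=0 needs a
    if not above.any():                 # strict exceedance of the mean
        # distinguish a genuinely absent response from one arriving after
        # the latency window closes
        tail = y[hi + 1:min(y.size, hi + 1 + int(0.3 * fs))]
        resp.invalid_reason = (LATE_ONSET if (tail > threshold).any()
                               else NO_CROSSING)
        return resp
    onset_ix = int(np.argmax(above))
    returned = window[onset_ix + 1:] <= threshold
    if not returned.any():
        resp.invalid_reason = NO_RETURN
        return resp

    resp.valid = True
    resp.invalid_reason = NONE
    resp.onset_latency_ms = (lo + onset_ix - p) / fs * 1000.0
    resp.amplitude = max(0.0, float(y[alo:ahi + 1].max()) - resp.baseline_mean)
    return resp


def detect_session_responses(signal: ProcessedSignal,
                             schedule: SessionSchedule,
                             config: ResponseWindowConfig | None = None
                             ) -> list[StartleResponse]:
    """Run detection over every probed event of the session."""
    return [detect_startle_response(signal, e, config)
            for e in schedule.probes()]


_CONDITION = {CS_PLUS: CS_PLUS, CS_MINUS: CS_MINUS, ITI_PROBE: ITI}


@dataclass
class ParticipantScores:
    """Per-participant condition means and ITI-proportional scores."""

    n_valid: dict[tuple[str, str], int] = field(default_factory=dict)
    mean_amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    iti_reference: float | None = None
    proportional: dict[tuple[str, str], float] = field(default_factory=dict)
    differential: dict[str, float] = field(default_factory=dict)
    scoreable: bool = True
    unscoreable_reason: str | None = None

    def cell(self, phase: str, condition: str) -> float | None:
        return self.mean_amplitude.get((phase, condition))


def score_participant(responses: list[StartleResponse],
                      schedule: SessionSchedule) -> ParticipantScores:
    """Aggregate validated responses into condition means and scores.

    Habituation-phase probes contribute to no score cell.  Invalid trials
    are excluded (never zero-filled).  A participant with no valid
    acquisition ITI probe has no background reference and is returned
    flagged unscoreable rather than silently zeroed.
    """
    scores = ParticipantScores()
    cells: dict[tuple[str, str], list[float]] = {}
    for r in responses:
        t = r.trial_ref
        if t.trial_type == HABITUATION_TONE or t.phase not in (ACQUISITION,
                                                               EXTINCTION):
            continue
        key = (t.phase, _CONDITION[t.trial_type])
        cells.setdefault(key, [])
        if r.valid and r.amplitude is not None:
            cells[key].append(r.amplitude)

    for key, vals in cells.items():
        scores.n_valid[key] = len(vals)
        if vals:
            scores.mean_amplitude[key] = float(np.mean(vals))

    ref = scores.mean_amplitude.get((ACQUISITION, ITI))
    if ref is None or ref <= 0:
        scores.scoreable = False
        scores.unscoreable_reason = "no valid acquisition ITI startle"
        return scores
    scores.iti_reference = ref

    for phase in (ACQUISITION, EXTINCTION):
        for cs in (CS_PLUS, CS_MINUS):
            amp = scores.mean_amplitude.get((phase, cs))
            if amp is not None:
                scores.proportional[(phase, cs)] = amp / ref
        plus = scores.proportional.get((phase, CS_PLUS))
        minus = scores.proportional.get((phase, CS_MINUS))
        if plus is not None and minus is not None:
            scores.differential[phase] = plus - minus
    return scores


def filter_successful_acquisition(cohort_scores: list[ParticipantScores]
                                  ) -> list[ParticipantScores]:
    """Keep participants whose acquisition differential is strictly > 0."""
    return [s for s in cohort_scores
            if s.scoreable and s.differential.get(ACQUISITION, 0.0) > 0.0]
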