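"""Response detection and proportional scoring: rule edge cases,
brute-force oracle equivalence, gain invariance, false-valid rates."""

import dataclasses

import numpy as np
import pytest

from conftest import clean_participant, small_schedule_config
from startlekit.paradigm import (ACQUISITION, CS_MINUS, CS_PLUS, EXTINCTION,
                                 HABITUATION, TrialEvent, build_schedule)
from startlekit.preprocess import ProcessedSignal, preprocess_emg
from startlekit.scoring import (ARTIFACT, ITI, LATE_ONSET, NO_CROSSING,
                                ResponseWindowConfig, StartleResponse,
                                detect_session_responses,
                                detect_startle_response,
                                filter_successful_acquisition,
                                score_participant)
from startlekit.synth import blink_envelope, simulate_emg_session

FS = 1000.0


def _probe(t_s, trial_type=CS_PLUS, phase=ACQUISITION):
    return TrialEvent(phase, 0, trial_type, None, t_s, False, None)


def _signal(y, mask=None):
    sig = ProcessedSignal(FS, np.asarray(y, float))
    if mask is not None:
        sig.artifact_mask = mask
    return sig


def oracle_detect(y, probe_s, cfg=ResponseWindowConfig()):
    """Independent sample-by-sample re-implementation of the validity rule."""
    p = int(round(probe_s * FS))
    nb = int(round(cfg.baseline_ms / 1000.0 * FS))
    base = y[p - nb:p]
    mean, sd = base.mean(), base.std()
    thr = mean + cfg.threshold_k * sd
    lo = p + int(round(cfg.validity_window_ms[0]))
    hi = p + int(round(cfg.validity_window_ms[1]))
    onset = None
    for i in range(lo, hi + 1):
        if y[i] > thr:
            onset = i
            break
    if onset is None:
        return dict(valid=False, reason=NO_CROSSING)
    returned = any(y[i] <= thr for i in range(onset + 1, hi + 1))
    if not returned:
        return dict(valid=False, reason="no_return")
    alo = p + int(round(cfg.amplitude_window_ms[0]))
    ahi = p + int(round(cfg.amplitude_window_ms[1]))
    amp = max(0.0, max(y[alo:ahi + 1]) - mean)
    return dict(valid=True, onset_ms=(onset - p), amplitude=amp)


class TestDetection:
    def test_flat_zero_signal_is_no_crossing(self):
        r = detect_startle_response(_signal(np.zeros(3000)), _probe(1.0))
        assert not r.valid and r.invalid_reason == NO_CROSSING

    @staticmethod
    def _bump(y, p, onset_ms, peak=80.0):
        # triangular blink surrogate: rises from onset, peaks 15 ms later,
        # back at baseline 35 ms after the peak
        rise, fall = 15, 35
        y[p + onset_ms:p + onset_ms + rise + 1] = np.linspace(0, peak,
                                                              rise + 1)
        y[p + onset_ms + rise:p + onset_ms + rise + fall + 1] = \
            np.linspace(peak, 0, fall + 1)

    def test_embedded_burst_detected_with_known_onset_and_peak(self):
        # quiet baseline, bump with onset 55 ms and peak 80 µV at 70 ms
        y = np.zeros(3000)
        self._bump(y, 1000, 55)
        r = detect_startle_response(_signal(y), _probe(1.0))
        assert r.valid
        assert r.onset_latency_ms == pytest.approx(56.0, abs=2.0)
        assert r.amplitude == pytest.approx(80.0, abs=1e-9)

    def test_identical_burst_after_window_is_late_onset(self):
        y = np.zeros(3000)
        self._bump(y, 1000, 150)
        r = detect_startle_response(_signal(y), _probe(1.0))
        assert not r.valid and r.invalid_reason == LATE_ONSET

    def test_artifact_overlap_invalidates(self):
        y = np.zeros(3000)
        y[1055:1100] = 50.0
        mask = np.zeros(3000, bool)
        mask[1060:1070] = True
        r = detect_startle_response(_signal(y, mask), _probe(1.0))
        assert not r.valid and r.invalid_reason == ARTIFACT

    def test_probe_too_early_for_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_startle_response(_signal(np.zeros(3000)), _probe(0.2))

    def test_oracle_equivalence_on_random_trials(self):
        # 100 random non-negative curves (noise, bursts, flats): the
        # vectorized detector must reproduce the per-sample oracle exactly
        rng = np.random.default_rng(42)
        cfg = ResponseWindowConfig()
        n_checked = 0
        for _ in range(100):
            kind = rng.integers(3)
            y = np.abs(rng.normal(0, rng.uniform(0.1, 3.0), 2000))
            if kind >= 1:  # add a burst at a random latency
                lat = int(rng.uniform(0, 200))
                env = rng.uniform(1, 60) * blink_envelope()
                y[1000 + lat:1000 + lat + env.size] += env
            if kind == 2:  # occasionally flatten the baseline
                y[:1000] = 0.0
            r = detect_startle_response(_signal(y), _probe(1.0), cfg)
            o = oracle_detect(y, 1.0, cfg)
            assert r.valid == o["valid"]
            if r.valid:
                assert r.onset_latency_ms == pytest.approx(o["onset_ms"])
                assert r.amplitude == pytest.approx(o["amplitude"])
                n_checked += 1
        assert n_checked > 10  # the sample covered both outcomes

    def test_false_valid_rate_decreases_with_threshold_k(self):
        # on pure-noise trials the false-valid rate is low and monotone
        # non-increasing in the threshold multiplier
        rng = np.random.default_rng(0)
        from startlekit.synth import EmgRecording
        raw = rng.normal(scale=2.0, size=int(400 * FS))
        proc = preprocess_emg(EmgRecording(FS, raw))
        probes = [_probe(1.0 + i) for i in range(398)]
        rates = []
        for k in (2.0, 3.0, 4.0):
            cfg = ResponseWindowConfig(threshold_k=k)
            valid = sum(detect_startle_response(proc, pr, cfg).valid
                        for pr in probes)
            rates.append(valid / len(probes))
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[1] < 0.25


class TestScoring:
    def _make_responses(self, schedule, amps):
        """Valid responses with amplitudes per (phase, trial_type)."""
        out = []
        for e in schedule.probes():
            amp = amps.get((e.phase, e.trial_type))
            if amp is None:
                continue
            out.append(StartleResponse(e.probe_onset_s, e, valid=True,
                                       onset_latency_ms=50.0, amplitude=amp))
        return out

    def test_self_referencing_gives_unit_scores(self, small_schedule):
        amps = {(ph, tt): 8.0
                for ph in (ACQUISITION, EXTINCTION)
                for tt in (CS_PLUS, CS_MINUS, "ITIprobe")}
        sc = score_participant(self._make_responses(small_schedule, amps),
                               small_schedule)
        for v in sc.proportional.values():
            assert v == pytest.approx(1.0)
        for v in sc.differential.values():
            assert v == pytest.approx(0.0)

    def test_hand_computed_proportional_mean(self):
        # six CS+ amplitudes {2,4,6,8,10,12} µV against ITI reference 8 µV
        # give mean 7 µV, proportional 7/8 = 0.875
        sch = build_schedule(small_schedule_config(
            n_cs_plus=6, n_cs_minus=6, probe_fraction_cs=1.0, seed=2))
        responses = []
        cs_plus_amps = iter([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        for e in sch.probes():
            if e.phase == ACQUISITION and e.trial_type == CS_PLUS:
                amp = next(cs_plus_amps)
            elif e.phase == ACQUISITION and e.trial_type == "ITIprobe":
                amp = 8.0
            else:
                continue
            responses.append(StartleResponse(e.probe_onset_s, e, valid=True,
                                             onset_latency_ms=50.0,
                                             amplitude=amp))
        sc = score_participant(responses, sch)
        assert sc.proportional[(ACQUISITION, CS_PLUS)] \
            == pytest.approx(0.875)

    def test_habituation_probes_enter_no_cell(self, small_schedule):
        amps = {(ph, tt): 5.0
                for ph in (ACQUISITION, EXTINCTION, HABITUATION)
                for tt in (CS_PLUS, CS_MINUS, "ITIprobe",
                           "habituation_tone")}
        sc = score_participant(self._make_responses(small_schedule, amps),
                               small_schedule)
        assert all(phase != HABITUATION for phase, _ in sc.n_valid)

    def test_invalid_trials_excluded_not_zero_filled(self, small_schedule):
        responses = self._make_responses(
            small_schedule, {(ph, tt): 10.0
                             for ph in (ACQUISITION, EXTINCTION)
                             for tt in (CS_PLUS, CS_MINUS, "ITIprobe")})
        # invalidate half the acquisition CS+ trials
        flipped = 0
        for r in responses:
            if (r.trial_ref.phase == ACQUISITION
                    and r.trial_ref.trial_type == CS_PLUS and flipped < 2):
                r.valid = False
                r.amplitude = None
                flipped += 1
        sc = score_participant(responses, small_schedule)
        assert sc.proportional[(ACQUISITION, CS_PLUS)] == pytest.approx(1.0)
        assert sc.n_valid[(ACQUISITION, CS_PLUS)] == 2

    def test_no_valid_iti_reference_flags_unscoreable(self, small_schedule):
        amps = {(ph, tt): 5.0 for ph in (ACQUISITION, EXTINCTION)
                for tt in (CS_PLUS, CS_MINUS)}
        sc = score_participant(self._make_responses(small_schedule, amps),
                               small_schedule)
        assert not sc.scoreable
        assert sc.proportional == {}

    def test_gain_invariance_of_proportional_scores(self, small_schedule):
        p1 = clean_participant(baseline_noise_rms=1.0)
        for c in (0.5, 4.0):
            p2 = dataclasses.replace(
                p1, blink_gain_iti=c * p1.blink_gain_iti,
                baseline_noise_rms=c * p1.baseline_noise_rms)
            out = []
            for p in (p1, p2):
                rec = simulate_emg_session(small_schedule, p, 21)
                proc = preprocess_emg(rec)
                sc = score_participant(
                    detect_session_responses(proc, small_schedule),
                    small_schedule)
                out.append(sc.proportional)
            for key in out[0]:
                assert out[0][key] == pytest.approx(out[1][key], rel=1e-9)


class TestSuccessfulAcquisitionFilter:
    def _scores(self, diff):
        from startlekit.scoring import ParticipantScores
        s = ParticipantScores(scoreable=True, iti_reference=1.0)
        if diff is not None:
            s.differential[ACQUISITION] = diff
        return s

    def test_zero_differential_excluded(self):
        kept = filter_successful_acquisition(
            [self._scores(0.0), self._scores(0.1), self._scores(-0.2)])
        assert len(kept) == 1

    def test_retained_count_matches_brute_force(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.1, 0.3, size=50)
        cohort = [self._scores(d) for d in diffs]
        kept = filter_successful_acquisition(cohort)
        assert len(kept) == int(sum(1 for d in diffs if d > 0))
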