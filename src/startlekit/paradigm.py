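"""Trial-schedule generation for a differential fear-conditioning session.

A session has three phases: a startle *habituation* phase (probe tones only),
an *acquisition* phase in which one conditioned stimulus (CS+) is partially
reinforced by an electric shock (US) while the other (CS−) never is, and an
*extinction* phase that repeats the acquisition trial sequence without any
shock.  Startle probes — brief white-noise bursts eliciting an eye-blink —
are placed on a fixed fraction of each CS type and during a few intertrial
intervals (ITI probes), the latter providing each participant's baseline
startle level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

HABITUATION = "habituation"
ACQUISITION = "acquisition"
EXTINCTION = "extinction"
PHASES = (HABITUATION, ACQUISITION, EXTINCTION)

CS_PLUS = "CSplus"
CS_MINUS = "CSminus"
ITI_PROBE = "ITIprobe"
HABITUATION_TONE = "habituation_tone"


class ConfigurationError(ValueError):
    """Raised when a schedule configuration violates its invariants."""


class SchedulingError(RuntimeError):
    """Raised when no admissible pseudorandom sequence is found."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the conditioning paradigm.

    Defaults reproduce the standard differential-conditioning session:
    9 habituation tones; 10 CS+ and 10 CS− of 8 s per phase; 50 % partial
    reinforcement (acquisition only) with a 100 ms shock co-terminating with
    the CS+; startle probes (50 ms) on 60 % of each CS type at 4.5 or 7 s
    after CS onset; 4 ITI probes per conditioning phase; ITIs of 12/14/16 s.
    """

    n_habituation_tones: int = 9
    habituation_itis_s: tuple[float, ...] = (12.0, 14.0, 16.0)
    n_cs_plus: int = 10
    n_cs_minus: int = 10
    cs_duration_s: float = 8.0
    reinforcement_fraction: float = 0.5
    us_duration_ms: float = 100.0
    probe_fraction_cs: float = 0.6
    probe_offsets_s: tuple[float, ...] = (4.5, 7.0)
    n_iti_probes: int = 4
    iti_durations_s: tuple[float, ...] = (12.0, 14.0, 16.0)
    startle_duration_ms: float = 50.0
    extinction_reinforced: bool = False
    seed: int = 0
    # pseudorandomization: longest admissible run of one CS type
    max_run: int = 2
    # silent lead-in before each phase and gap before extinction
    lead_in_s: float = 10.0
    phase_gap_s: float = 300.0

    def __post_init__(self) -> None:
        if self.extinction_reinforced:
            raise ConfigurationError("extinction is never reinforced")
        for name in ("cs_duration_s", "us_duration_ms", "startle_duration_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("habituation_itis_s", "iti_durations_s"):
            if any(d <= 0 for d in getattr(self, name)):
                raise ConfigurationError(f"all {name} must be > 0")
        if not 0 <= self.reinforcement_fraction <= 1:
            raise ConfigurationError("reinforcement_fraction outside [0, 1]")
        if not 0 <= self.probe_fraction_cs <= 1:
            raise ConfigurationError("probe_fraction_cs outside [0, 1]")
        _integer_count(self.reinforcement_fraction, self.n_cs_plus,
                       "reinforcement_fraction x n_cs_plus")
        _integer_count(self.probe_fraction_cs, self.n_cs_plus,
                       "probe_fraction_cs x n_cs_plus")
        _integer_count(self.probe_fraction_cs, self.n_cs_minus,
                       "probe_fraction_cs x n_cs_minus")

    @property
    def n_reinforced(self) -> int:
        return round(self.reinforcement_fraction * self.n_cs_plus)

    @property
    def n_probed_cs_plus(self) -> int:
        return round(self.probe_fraction_cs * self.n_cs_plus)

    @property
    def n_probed_cs_minus(self) -> int:
        return round(self.probe_fraction_cs * self.n_cs_minus)


def _integer_count(fraction: float, n: int, what: str) -> None:
    if abs(fraction * n - round(fraction * n)) > 1e-9:
        raise ConfigurationError(f"{what} = {fraction * n} is not an integer")


@dataclass(frozen=True)
class TrialEvent:
    """One scheduled event: a CS presentation, an ITI probe, or a tone."""

    phase: str
    index: int
    trial_type: str
    cs_onset_s: float | None
    probe_onset_s: float | None
    reinforced: bool
    us_onset_s: float | None

    @property
    def onset_s(self) -> float:
        if self.cs_onset_s is not None:
            return self.cs_onset_s
        assert self.probe_onset_s is not None
        return self.probe_onset_s

    @property
    def is_probed(self) -> bool:
        return self.probe_onset_s is not None


@dataclass(frozen=True)
class SessionSchedule:
    config: ScheduleConfig
    events: tuple[TrialEvent, ...]
    phase_boundaries_s: dict[str, tuple[float, float]]

    def phase_events(self, phase: str) -> list[TrialEvent]:
        return [e for e in self.events if e.phase == phase]

    def probes(self, phase: str | None = None) -> list[TrialEvent]:
        """Probed events in session order (all phases unless one is named)."""
        return [e for e in self.events
                if e.is_probed and (phase is None or e.phase == phase)]

    @property
    def duration_s(self) -> float:
        return max(end for _, end in self.phase_boundaries_s.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            dur = (self.config.cs_duration_s
                   if e.trial_type in (CS_PLUS, CS_MINUS)
                   else self.config.startle_duration_ms / 1000.0)
            rows.append({
                "onset": e.onset_s,
                "duration": dur,
                "phase": e.phase,
                "trial_type": e.trial_type,
                "probe_onset": e.probe_onset_s,
                "reinforced": int(e.reinforced),
                "us_onset": e.us_onset_s,
            })
        return pd.DataFrame(rows)


def _cs_sequence(rng: np.random.Generator, n_plus: int, n_minus: int,
                 max_run: int) -> list[str]:
    """Pseudorandom CS order with no run of one type longer than max_run.

    Built constructively: at each position a count-weighted random choice
    is made among the types whose selection leaves the remainder packable
    (a two-symbol sequence with counts (a, b), a trailing run r of the
    trailing type, and run limit k can be completed iff the trailing type
    fits (k − r) + k·b slots and the other fits k·(a + 1) slots), so the
    draw never dead-ends and infeasible configurations fail immediately.
    """
    k = max_run
    counts = {CS_PLUS: n_plus, CS_MINUS: n_minus}
    if n_plus > k * (n_minus + 1) or n_minus > k * (n_plus + 1):
        raise SchedulingError(
            f"counts ({n_plus}, {n_minus}) admit no sequence with "
            f"max run {k}")
    seq: list[str] = []
    last, run = None, 0
    while counts[CS_PLUS] + counts[CS_MINUS] > 0:
        cands = []
        for t in (CS_PLUS, CS_MINUS):
            if counts[t] == 0 or (t == last and run == k):
                continue
            other = CS_MINUS if t == CS_PLUS else CS_PLUS
            nt, no = counts[t] - 1, counts[other]
            r = run + 1 if t == last else 1
            if nt <= (k - r) + k * no and no <= k * (nt + 1):
                cands.append(t)
        if not cands:  # unreachable given the feasibility precheck
            raise SchedulingError("pseudorandomization dead end")
        weights = np.array([counts[t] for t in cands], float)
        t = cands[int(rng.choice(len(cands), p=weights / weights.sum()))]
        run = run + 1 if t == last else 1
        last = t
        counts[t] -= 1
        seq.append(t)
    return seq


def _balanced_offsets(rng: np.random.Generator, n: int,
                      offsets: tuple[float, ...]) -> list[float]:
    """Probe offsets assigned as evenly as possible, order shuffled."""
    reps = [offsets[i % len(offsets)] for i in range(n)]
    return list(rng.permutation(np.asarray(reps)))


@dataclass
class _PhasePlan:
    """The per-trial decisions mirrored from acquisition into extinction."""

    cs_order: list[str]
    probed: list[bool]            # per trial
    probe_offset: list[float]     # per trial, nan when unprobed
    reinforced: list[bool]        # per trial
    itis: list[float]             # ITI following each trial
    iti_probe_after: list[bool]   # ITI probe in the ITI following trial i


def _plan_conditioning(rng: np.random.Generator,
                       cfg: ScheduleConfig) -> _PhasePlan:
    order = _cs_sequence(rng, cfg.n_cs_plus, cfg.n_cs_minus, cfg.max_run)
    n = len(order)
    plus_ix = [i for i, t in enumerate(order) if t == CS_PLUS]
    minus_ix = [i for i, t in enumerate(order) if t == CS_MINUS]

    probed = [False] * n
    probe_offset = [float("nan")] * n
    for ix_pool, n_probed in ((plus_ix, cfg.n_probed_cs_plus),
                              (minus_ix, cfg.n_probed_cs_minus)):
        chosen = rng.choice(len(ix_pool), size=n_probed, replace=False) \
            if n_probed else []
        offs = _balanced_offsets(rng, n_probed, cfg.probe_offsets_s)
        for k, j in enumerate(sorted(int(c) for c in np.atleast_1d(chosen))):
            probed[ix_pool[j]] = True
            probe_offset[ix_pool[j]] = offs[k]

    reinforced = [False] * n
    if cfg.n_reinforced:
        chosen = rng.choice(len(plus_ix), size=cfg.n_reinforced, replace=False)
        for j in np.atleast_1d(chosen):
            reinforced[plus_ix[int(j)]] = True

    itis = [float(rng.choice(cfg.iti_durations_s)) for _ in range(n)]
    iti_probe_after = [False] * n
    if cfg.n_iti_probes:
        if cfg.n_iti_probes > n:
            raise ConfigurationError("more ITI probes than ITIs")
        for j in rng.choice(n, size=cfg.n_iti_probes, replace=False):
            iti_probe_after[int(j)] = True
    return _PhasePlan(order, probed, probe_offset, reinforced, itis,
                      iti_probe_after)


def _emit_conditioning(phase: str, plan: _PhasePlan, cfg: ScheduleConfig,
                       t0: float) -> tuple[list[TrialEvent], float]:
    """Lay the planned trials onto the session timeline starting at t0."""
    events: list[TrialEvent] = []
    t = t0 + cfg.lead_in_s
    us_dur = cfg.us_duration_ms / 1000.0
    for i, cs_type in enumerate(plan.cs_order):
        reinforced = plan.reinforced[i] and phase == ACQUISITION
        probe = t + plan.probe_offset[i] if plan.probed[i] else None
        us = t + cfg.cs_duration_s - us_dur if reinforced else None
        events.append(TrialEvent(phase, i, cs_type, t, probe, reinforced, us))
        t += cfg.cs_duration_s
        if plan.iti_probe_after[i]:
            # probe midway through the ITI, clear of CS offset and next onset
            events.append(TrialEvent(phase, i, ITI_PROBE, None,
                                     t + plan.itis[i] / 2.0, False, None))
        t += plan.itis[i]
    return events, t


def build_schedule(config: ScheduleConfig) -> SessionSchedule:
    """Build the full three-phase session schedule.

    The extinction phase mirrors the acquisition phase trial-for-trial
    (same CS order, probe placement and offsets, same ITI durations) with
    every reinforcement flag cleared, matching a design in which the second
    phase repeats the first without any shock.
    """
    rng = np.random.default_rng(config.seed)
    events: list[TrialEvent] = []
    boundaries: dict[str, tuple[float, float]] = {}

    # --- habituation: probe tones only ---
    t = config.lead_in_s
    hab_start = 0.0
    for i in range(config.n_habituation_tones):
        events.append(TrialEvent(HABITUATION, i, HABITUATION_TONE,
                                 None, t, False, None))
        t += float(rng.choice(config.habituation_itis_s))
    boundaries[HABITUATION] = (hab_start, t)

    # --- acquisition, then extinction mirroring it ---
    plan = _plan_conditioning(rng, config)
    acq_events, t_end = _emit_conditioning(ACQUISITION, plan, config, t)
    events.extend(acq_events)
    boundaries[ACQUISITION] = (t, t_end)

    ext_plan = dataclasses.replace(plan, reinforced=[False] * len(plan.cs_order))
    t_ext = t_end + config.phase_gap_s
    ext_events, t_final = _emit_conditioning(EXTINCTION, ext_plan, config,
                                             t_ext)
    events.extend(ext_events)
    boundaries[EXTINCTION] = (t_ext, t_final)

    events.sort(key=lambda e: e.onset_s)
    return SessionSchedule(config, tuple(events), boundaries)


# ---------------------------------------------------------------------------
# events table I/O (tab-separated, BIDS-events-style dialect)

_EVENT_COLUMNS = ["onset", "duration", "phase", "trial_type", "probe_onset",
                  "reinforced", "us_onset"]


def write_events(schedule: SessionSchedule, path) -> None:
    df = schedule.to_frame()[_EVENT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="n/a",
              float_format="%.6f")


class EventsParseError(ValueError):
    pass


def read_events(path) -> pd.DataFrame:
    """Read and validate an events table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise EventsParseError(f"events table missing columns: {missing}")
    if not df["onset"].is_monotonic_increasing:
        raise EventsParseError("events not sorted by onset")
    cs = df[df["trial_type"].isin([CS_PLUS, CS_MINUS])]
    bad = cs["probe_onset"].notna() & (cs["probe_onset"] < cs["onset"])
    if bad.any():
        raise EventsParseError("probe_onset precedes CS onset")
    if ((df["phase"] == EXTINCTION) & df["us_onset"].notna()).any():
        raise EventsParseError("US event inside extinction phase")
    return df


def events_from_frame(df: pd.DataFrame,
                      config: ScheduleConfig | None = None) -> SessionSchedule:
    """Rebuild a SessionSchedule from an events table."""
    config = config or ScheduleConfig()
    events = []
    counters: dict[str, int] = {}
    for _, r in df.iterrows():
        is_cs = r["trial_type"] in (CS_PLUS, CS_MINUS)
        i = counters.get(r["phase"], 0)
        counters[r["phase"]] = i + 1
        events.append(TrialEvent(
            phase=r["phase"],
            index=int(i),
            trial_type=r["trial_type"],
            cs_onset_s=float(r["onset"]) if is_cs else None,
            probe_onset_s=(float(r["probe_onset"])
                           if pd.notna(r["probe_onset"]) else None),
            reinforced=bool(r["reinforced"]),
            us_onset_s=(float(r["us_onset"])
                        if pd.notna(r["us_onset"]) else None),
        ))
    boundaries = {}
    for phase in PHASES:
        sub = [e for e in events if e.phase == phase]
        if sub:
            boundaries[phase] = (min(e.onset_s for e in sub),
                                 max(e.onset_s for e in sub)
                                 + config.cs_duration_s)
    return SessionSchedule(config, tuple(events), boundaries)
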