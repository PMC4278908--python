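"""File formats: headered signal TSV, events tables, EDF reading.

The native signal format is a tab-separated file with ``#``-prefixed
header lines (``sampling_rate_hz``, ``channel``) followed by two columns,
time in seconds and EMG in µV.  Samples are written at full double
precision so a write→read round trip is lossless.  Single-channel EDF
files can additionally be read when :mod:`mne` is available; EDF writing
is not supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import (ScheduleConfig, SessionSchedule, events_from_frame,
                       read_events, write_events)
from .synth import RATE_HZ, EmgRecording


class SignalParseError(ValueError):
    pass


def write_signal_tsv(recording: EmgRecording, path) -> None:
    path = Path(path)
    n = recording.samples.size
    t = np.arange(n) / recording.sampling_rate
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {recording.sampling_rate:g}\n")
        fh.write(f"# channel: {recording.channel_label}\n")
        fh.write("t_s\temg_uv\n")
        for ti, xi in zip(t, recording.samples):
            fh.write(f"{ti:.6f}\t{float(xi)!r}\n")


def read_signal_tsv(path) -> EmgRecording:
    path = Path(path)
    rate = None
    channel = "EMG"
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key == "sampling_rate_hz":
                rate = float(value)
            elif key == "channel":
                channel = value.strip()
    if rate is None:
        raise SignalParseError(
            f"{path}: missing '# sampling_rate_hz:' header line")
    df = pd.read_csv(path, sep="\t", skiprows=header_lines,
                     float_precision="round_trip")
    if "emg_uv" not in df.columns:
        raise SignalParseError(f"{path}: missing 'emg_uv' column")
    return EmgRecording(rate, df["emg_uv"].to_numpy(float),
                        channel_label=channel)


def read_signal_edf(path) -> EmgRecording:
    """Read a single-channel EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if len(raw.ch_names) != 1:
        raise SignalParseError(
            f"{path}: expected a single channel, found {len(raw.ch_names)}")
    data = raw.get_data()[0] * 1e6  # mne loads Volts; convert to µV
    return EmgRecording(float(raw.info["sfreq"]), data,
                        channel_label=raw.ch_names[0])


def read_session(signal_path, events_path,
                 config: ScheduleConfig | None = None
                 ) -> tuple[EmgRecording, SessionSchedule]:
    """Load a recording and its events table into analysis objects."""
    signal_path = Path(signal_path)
    if signal_path.suffix.lower() == ".edf":
        rec = read_signal_edf(signal_path)
    else:
        rec = read_signal_tsv(signal_path)
    schedule = events_from_frame(read_events(events_path), config)
    rec.events = schedule
    return rec, schedule


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


__all__ = [
    "write_signal_tsv", "read_signal_tsv", "read_signal_edf",
    "read_session", "write_events", "read_events", "write_manifest",
    "SignalParseError",
]
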