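"""Offline EMG processing chain for startle-blink quantification.

The raw orbicularis-oculi EMG (1 kHz, µV) is turned into a non-negative
"startle response curve" by, in order: 65 Hz high-pass filtering (removes
low-frequency muscle tonus and motion components while keeping the blink
burst, whose spectral mass sits well above 65 Hz), full-wave rectification,
a 40 ms moving average (envelope smoothing), and a 2 Hz high-pass that
removes residual slow drift.  Small negative residuals left by the final
high-pass are clamped to zero so the curve remains a non-negative envelope.

Both high-pass stages are 4th-order Butterworth filters applied
forward-backward (zero phase), so blink onset latencies are not shifted by
filter group delay.  The moving average uses a centered window with
reflected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

SUPPORTED_RATE_HZ = 1000.0


class UnsupportedRateError(ValueError):
    """Raised for any sampling rate other than 1 kHz (no resampling here)."""


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_hz: float = 65.0
    smooth_ms: float = 40.0
    drift_highpass_hz: float = 2.0
    filter_order: int = 4
    clamp_negative: bool = True
    # the drift high-pass runs after smoothing by default (configurable)
    drift_after_smoothing: bool = True


@dataclass
class ProcessedSignal:
    """Rectified-smoothed startle response curve plus processing provenance."""

    sampling_rate: float
    samples: np.ndarray
    processing_log: list[dict] = field(default_factory=list)
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.size, dtype=bool)

    def mask_overlaps(self, start_s: float, stop_s: float) -> bool:
        i0 = max(0, int(round(start_s * self.sampling_rate)))
        i1 = min(self.samples.size, int(round(stop_s * self.sampling_rate)))
        return bool(self.artifact_mask[i0:i1].any())


def _check_rate(rate: float) -> None:
    if abs(rate - SUPPORTED_RATE_HZ) > 1e-9:
        raise UnsupportedRateError(
            f"sampling rate {rate} Hz unsupported; expected 1000 Hz")


def highpass_sos(cutoff_hz: float, rate: float, order: int = 4) -> np.ndarray:
    return sps.butter(order, cutoff_hz, btype="highpass", fs=rate,
                      output="sos")


def preprocess_emg(recording, config: PreprocessConfig | None = None
                   ) -> ProcessedSignal:
    """Apply the offline chain to an :class:`~startlekit.synth.EmgRecording`.

    Accepts any object with ``sampling_rate`` and ``samples`` attributes.
    Constant input (including all-zero) passes through to all-zero output.
    """
    cfg = config or PreprocessConfig()
    rate = float(recording.sampling_rate)
    _check_rate(rate)
    x = np.asarray(recording.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in recording")
    log: list[dict] = []

    y = sps.sosfiltfilt(highpass_sos(cfg.highpass_hz, rate,
                                     cfg.filter_order), x)
    log.append({"step": "highpass", "cutoff_hz": cfg.highpass_hz,
                "order": cfg.filter_order, "zero_phase": True})

    y = np.abs(y)
    log.append({"step": "rectify"})

    win = max(1, int(round(cfg.smooth_ms / 1000.0 * rate)))
    drift = highpass_sos(cfg.drift_highpass_hz, rate, cfg.filter_order)

    if cfg.drift_after_smoothing:
        y = uniform_filter1d(y, size=win, mode="reflect")
        log.append({"step": "moving_average", "window_ms": cfg.smooth_ms})
        y = sps.sosfiltfilt(drift, y)
        log.append({"step": "highpass", "cutoff_hz": cfg.drift_highpass_hz,
                    "order": cfg.filter_order, "zero_phase": True})
    else:
        y = sps.sosfiltfilt(drift, y)
        log.append({"step": "highpass", "cutoff_hz": cfg.drift_highpass_hz,
                    "order": cfg.filter_order, "zero_phase": True})
        y = uniform_filter1d(y, size=win, mode="reflect")
        log.append({"step": "moving_average", "window_ms": cfg.smooth_ms})

    if cfg.clamp_negative:
        y = np.maximum(y, 0.0)
        log.append({"step": "clamp_nonnegative"})

    return ProcessedSignal(rate, y, log)


@dataclass(frozen=True)
class ArtifactRule:
    """Automated surrogate for visual electrode-artifact rejection.

    Masks samples of the processed curve exceeding an absolute amplitude
    ceiling, or whose sample-to-sample jump exceeds a derivative ceiling.
    Masked regions are dilated by ``pad_ms`` so that windows merely touching
    an artifact are caught.  ``math.inf`` ceilings disable a rule.
    """

    amplitude_ceiling_uv: float = 800.0
    jump_ceiling_uv: float = 100.0
    pad_ms: float = 50.0


def mark_artifacts(processed: ProcessedSignal,
                   rule: ArtifactRule | None = None) -> ProcessedSignal:
    rule = rule or ArtifactRule()
    y = processed.samples
    mask = np.zeros(y.size, dtype=bool)
    if np.isfinite(rule.amplitude_ceiling_uv):
        mask |= np.abs(y) > rule.amplitude_ceiling_uv
    if np.isfinite(rule.jump_ceiling_uv) and y.size > 1:
        jump = np.abs(np.diff(y))
        hit = jump > rule.jump_ceiling_uv
        mask[:-1] |= hit
        mask[1:] |= hit
    if mask.any() and rule.pad_ms > 0:
        pad = int(round(rule.pad_ms / 1000.0 * processed.sampling_rate))
        if pad:
            idx = np.flatnonzero(mask)
            for i in idx:
                mask[max(0, i - pad):i + pad + 1] = True
    processed.artifact_mask = processed.artifact_mask | mask
    processed.processing_log.append({
        "step": "mark_artifacts",
        "amplitude_ceiling_uv": rule.amplitude_ceiling_uv,
        "jump_ceiling_uv": rule.jump_ceiling_uv,
        "masked_samples": int(mask.sum()),
    })
    return processed
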