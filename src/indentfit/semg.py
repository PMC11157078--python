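"""Surface EMG filtering, quantization and MVC normalization.

Trunk-muscle sEMG traces (channels E1 anterior, E2 lateral, E3 paraspinal;
sampled at 1024 Hz) are band-pass filtered between 45 and 500 Hz with an
additional 50 Hz mains notch, quantified as an RMS envelope over a sliding
window of 200 samples (195.3 ms at 1024 Hz), and expressed as percent
activity relative to a maximum voluntary contraction (MVC) recorded in the
matching body position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SEMGTrace",
    "SEMGEnvelope",
    "filter_semg",
    "rms_envelope",
    "normalize_mvc",
]

BAND_HZ = (45.0, 500.0)
NOTCH_HZ = 50.0
NOTCH_Q = 30.0
RMS_WINDOW = 200


@dataclass(frozen=True)
class SEMGTrace:
    channel: str  # E1 | E2 | E3
    fs: float  # Hz
    samples: np.ndarray  # µV

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite sEMG samples")
        object.__setattr__(self, "samples", x)


@dataclass(frozen=True)
class SEMGEnvelope:
    channel: str
    fs: float
    values: np.ndarray  # µV RMS
    window: int = RMS_WINDOW


def filter_semg(trace: SEMGTrace) -> SEMGTrace:
    """Zero-phase 45-500 Hz band-pass plus 50 Hz notch.

    4th-order Butterworth band-pass and a Q=30 IIR notch, both applied
    forward-backward (``filtfilt``) so the envelope stays time-aligned with
    the indenter stroke.
    """
    if trace.fs <= 2 * BAND_HZ[1]:
        raise ValueError("sampling rate too low for a 500 Hz band edge")
    sos = signal.butter(4, BAND_HZ, btype="bandpass", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos, trace.samples)
    b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=trace.fs)
    x = signal.filtfilt(b, a, x)
    return SEMGTrace(channel=trace.channel, fs=trace.fs, samples=x)


def rms_envelope(trace: SEMGTrace, window: int = RMS_WINDOW) -> SEMGEnvelope:
    """RMS of the (filtered) trace over a sliding window of ``window`` samples."""
    x = trace.samples
    if x.size < window:
        raise ValueError("trace shorter than the RMS window")
    sq = x**2
    kernel = np.full(window, 1.0 / window)
    mean_sq = np.convolve(sq, kernel, mode="valid")
    values = np.sqrt(np.maximum(mean_sq, 0.0))
    return SEMGEnvelope(channel=trace.channel, fs=trace.fs, values=values, window=window)


def _mvc_reference(mvc_envelope: SEMGEnvelope, peak_duration_s: float = 0.5) -> float:
    """MVC reference statistic: mean of the top ``peak_duration_s`` of the envelope."""
    n_top = max(1, int(round(peak_duration_s * mvc_envelope.fs)))
    v = np.sort(mvc_envelope.values)[::-1]
    return float(v[: min(n_top, v.size)].mean())


def normalize_mvc(
    envelope: SEMGEnvelope,
    mvc_envelope: SEMGEnvelope,
    baseline_envelope: SEMGEnvelope | None = None,
) -> dict:
    """Express an activity envelope as percent of the MVC reference.

    ``activity_pct = 100 * mean(envelope) / mvc_reference`` with the MVC
    reference taken as the mean of the top 0.5 s of the MVC envelope (a
    robust peak statistic).  The baseline envelope mean, when given, is
    reported alongside but not subtracted.
    """
    mvc_ref = _mvc_reference(mvc_envelope)
    baseline = float(baseline_envelope.values.mean()) if baseline_envelope is not None else 0.0
    if mvc_ref <= baseline:
        raise ValueError("MVC reference does not exceed baseline activity")
    return {
        "channel": envelope.channel,
        "activity_pct": 100.0 * float(envelope.values.mean()) / mvc_ref,
        "mvc_reference_uv": mvc_ref,
        "baseline_uv": baseline,
    }
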