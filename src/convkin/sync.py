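"""Audio cross-correlation synchronization between recording devices.

The annotation time base (video audio) and the motion-capture time base
(device audio) start at different instants. A single constant offset per
recording is estimated as the argmax of the normalized cross-correlation of
the two mean-removed audio streams within a bounded lag window, then applied
to the motion timestamps. No clock-drift correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import correlate, correlation_lags

from .datamodel import SessionRecording, ValidationError


@dataclass(frozen=True)
class OffsetEstimate:
    """Estimated lag of the second stream relative to the first.

    Positive ``offset_s`` means the second stream lags the first (an event is
    heard later in stream B than in stream A). ``peak_correlation`` is the
    normalized cross-correlation at the chosen lag, in [-1, 1];
    ``confident`` marks whether it clears the decision threshold.
    """

    offset_s: float
    peak_correlation: float
    confident: bool

    def negated(self) -> "OffsetEstimate":
        return OffsetEstimate(-self.offset_s, self.peak_correlation, self.confident)


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a mono PCM WAV file as (rate_hz, float64 samples in [-1, 1])."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValidationError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return float(rate), data


def estimate_offset(
    audio_a: np.ndarray,
    audio_b: np.ndarray,
    rate_hz: float,
    max_lag_s: float = 5.0,
    *,
    rate_hz_b: float | None = None,
    confidence_threshold: float = 0.5,
) -> OffsetEstimate:
    """Estimate the lag of stream B behind stream A by cross-correlation.

    Both streams must be mono, share the sampling rate, and be at least one
    second long; an all-zero (silent) stream is rejected. The returned lag is
    the argmax of the overlap-normalized cross-correlation of the
    mean-removed signals within +/- ``max_lag_s``.
    """
    if rate_hz_b is not None and abs(rate_hz_b - rate_hz) > 1e-9:
        raise ValidationError(
            f"sampling rate mismatch: {rate_hz} Hz vs {rate_hz_b} Hz"
        )
    a = np.asarray(audio_a, dtype=float)
    b = np.asarray(audio_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("audio streams must be mono (1-D)")
    if rate_hz <= 0 or max_lag_s <= 0:
        raise ValidationError("rate_hz and max_lag_s must be positive")
    if len(a) < rate_hz or len(b) < rate_hz:
        raise ValidationError("audio streams must be at least 1 s long")
    for name, x in (("A", a), ("B", b)):
        if not np.any(x != 0):
            raise ValidationError(f"stream {name} is silent (all zeros)")

    a = a - a.mean()
    b = b - b.mean()
    # c[lag] = sum_n b[n] * a[n - lag]: a delayed copy of A in B peaks at the
    # positive lag by which B trails A.
    c = correlate(b, a, mode="full", method="fft")
    lags = correlation_lags(len(b), len(a), mode="full")

    # per-lag overlap norms via cumulative sums of squares
    ca = np.concatenate([[0.0], np.cumsum(a * a)])
    cb = np.concatenate([[0.0], np.cumsum(b * b)])
    b_lo = np.clip(lags, 0, len(b))
    b_hi = np.clip(lags + len(a), 0, len(b))
    a_lo = np.clip(-lags, 0, len(a))
    a_hi = np.clip(len(b) - lags, 0, len(a))
    norm = np.sqrt((ca[a_hi] - ca[a_lo]) * (cb[b_hi] - cb[b_lo]))

    max_lag = int(round(max_lag_s * rate_hz))
    window = (np.abs(lags) <= max_lag) & (norm > 0)
    # require at least 1 s of overlap so edge lags cannot win on noise
    window &= np.minimum(a_hi - a_lo, b_hi - b_lo) >= rate_hz
    if not window.any():
        raise ValidationError(
            f"no admissible lags within +/-{max_lag_s} s with >= 1 s overlap"
        )
    score = np.where(window, c / np.where(norm > 0, norm, 1.0), -np.inf)
    best = int(np.argmax(score))
    peak = float(score[best])
    return OffsetEstimate(
        offset_s=float(lags[best] / rate_hz),
        peak_correlation=peak,
        confident=peak >= confidence_threshold,
    )


def apply_offset(
    recording: SessionRecording, offset: OffsetEstimate, *, force: bool = False
) -> SessionRecording:
    """Express motion timestamps in the first (annotation) stream's time base.

    If the device stream lags the annotation stream by ``offset_s``, a motion
    sample logged at device time t happened at annotation time
    t + offset_s; all track timestamps are shifted accordingly. Applying an
    offset and then its negation restores the input. Refuses a non-confident
    estimate unless ``force`` is set.
    """
    if not offset.confident and not force:
        raise ValidationError(
            f"offset estimate not confident (peak correlation "
            f"{offset.peak_correlation:.3f}); pass force=True to apply anyway"
        )
    return recording.shifted(offset.offset_s)
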