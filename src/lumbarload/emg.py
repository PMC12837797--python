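"""Surface-EMG conditioning: DC-offset removal, RMS enveloping, rest thresholding.

The pipeline consumes *envelopes*: a raw channel has its rest-trial DC
offset subtracted and is passed through a centered moving-RMS filter
(default window 51 samples). The rest trial additionally defines a
per-channel rest envelope level; any task/calibration envelope below that
level is treated as zero muscle force downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._exceptions import InputError, ParameterError

DEFAULT_RMS_WINDOW = 51  # samples


@dataclass
class EmgTrace:
    """One raw sEMG channel. ``trial_kind`` is 'rest', 'vct' or 'task'."""

    channel: str
    samples: np.ndarray
    sampling_rate: float
    trial_kind: str = "rest"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InputError(f"{self.channel}: non-finite samples in trace")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class RestBaseline:
    """Per-channel rest statistics.

    ``dc_offset`` is the scalar mean of the rest trace; ``rest_envelope_level``
    the mean RMS-envelope level after offset removal (the zero-force
    threshold); ``noise_sd`` the standard deviation of the offset-removed
    rest trace, usable as an envelope measurement-noise estimate.
    """

    channel: str
    dc_offset: float
    rest_envelope_level: float
    noise_sd: float = 0.0


@dataclass
class Envelope:
    """Non-negative amplitude envelope of one channel."""

    channel: str
    samples: np.ndarray
    sampling_rate: float
    window_width: int = DEFAULT_RMS_WINDOW

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate if self.samples.size else 0.0


def _moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving RMS with the window truncated (not padded) at the edges."""
    n = x.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    mean_sq = (csum[hi] - csum[lo]) / (hi - lo)
    # guard tiny negative round-off before the sqrt
    return np.sqrt(np.maximum(mean_sq, 0.0))


def rms_envelope(trace: EmgTrace, window_width: int = DEFAULT_RMS_WINDOW) -> Envelope:
    """Centered moving-RMS envelope; output length equals input length.

    ``window_width`` must be odd (a centered window) and >= 1; a window of 1
    degenerates to full-wave rectification |x|.
    """
    if window_width < 1 or window_width % 2 == 0:
        raise ParameterError(f"window_width must be odd and >= 1, got {window_width}")
    if trace.samples.size == 0:
        raise InputError(f"{trace.channel}: empty trace")
    return Envelope(
        channel=trace.channel,
        samples=_moving_rms(trace.samples, window_width),
        sampling_rate=trace.sampling_rate,
        window_width=window_width,
    )


def compute_rest_baseline(
    rest_trace: EmgTrace, window_width: int = DEFAULT_RMS_WINDOW
) -> RestBaseline:
    """Summarize a supine rest recording into a :class:`RestBaseline`."""
    if rest_trace.samples.size == 0:
        raise InputError(f"{rest_trace.channel}: empty rest trace")
    dc = float(np.mean(rest_trace.samples))
    centred = replace(rest_trace, samples=rest_trace.samples - dc)
    level = float(np.mean(rms_envelope(centred, window_width).samples))
    noise = float(np.std(centred.samples))
    return RestBaseline(
        channel=rest_trace.channel, dc_offset=dc, rest_envelope_level=level, noise_sd=noise
    )


def remove_dc_offset(trace: EmgTrace, baseline: RestBaseline) -> EmgTrace:
    """Subtract the rest-trial DC offset from a trace (length preserved)."""
    if trace.channel != baseline.channel:
        raise InputError(
            f"channel mismatch: trace {trace.channel!r} vs baseline {baseline.channel!r}"
        )
    return replace(trace, samples=trace.samples - baseline.dc_offset)


def apply_rest_threshold(
    envelope: Envelope, baseline: RestBaseline
) -> tuple[Envelope, np.ndarray]:
    """Mark sub-rest envelope samples as zero-force.

    Returns the (unchanged) envelope and a boolean mask, True where the
    envelope is strictly below the rest envelope level. Masked samples map
    to zero muscle force downstream; the envelope values themselves are
    untouched.
    """
    if envelope.channel != baseline.channel:
        raise InputError(
            f"channel mismatch: envelope {envelope.channel!r} vs baseline {baseline.channel!r}"
        )
    mask = envelope.samples < baseline.rest_envelope_level
    return envelope, mask


def resample_to(envelope: Envelope, target_rate: float) -> Envelope:
    """Linearly interpolate an envelope onto a new uniform timebase.

    The duration and both endpoints are preserved; used to align EMG-rate
    envelopes with kinematic-rate signals.
    """
    if target_rate <= 0:
        raise ParameterError(f"target_rate must be positive, got {target_rate}")
    if envelope.samples.size < 2:
        raise InputError(f"{envelope.channel}: need at least 2 samples to resample")
    duration = envelope.duration
    n_out = int(round(duration * target_rate)) + 1
    t_out = np.linspace(0.0, duration, n_out)
    samples = np.interp(t_out, envelope.time, envelope.samples)
    return replace(envelope, samples=samples, sampling_rate=target_rate)
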