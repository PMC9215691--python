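"""Signal conditioning: downsampling, low-alpha band-pass, average re-reference.

The canonical pipeline order is downsample (to 250 Hz) -> zero-phase 6-9 Hz
Butterworth band-pass -> common-average re-reference, yielding 20 s segments
of Nt = 5000 samples.  The average reference is linear and commutes with the
other two stages, so the order is a documentation convention rather than a
numerical one.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .segment import EEGSegment

__all__ = [
    "downsample",
    "bandpass_low_alpha",
    "rereference_average",
    "pick_segments",
    "preprocess_segment",
]


def downsample(seg: EEGSegment, target_fs: float) -> EEGSegment:
    """Resample to ``target_fs`` with polyphase anti-aliased resampling.

    Non-integer ratios (512 -> 250 Hz is 125/256) are handled by rational
    approximation of the rate ratio.  ``target_fs == fs`` is a pass-through.
    """
    if target_fs > seg.fs:
        raise ValueError(
            f"target_fs ({target_fs} Hz) exceeds segment rate ({seg.fs} Hz)"
        )
    if target_fs == seg.fs:
        return seg.with_data(seg.data.copy())
    frac = Fraction(target_fs / seg.fs).limit_denominator(1000)
    out = signal.resample_poly(seg.data, frac.numerator, frac.denominator, axis=1)
    return seg.with_data(out, fs=target_fs)


def bandpass_low_alpha(
    seg: EEGSegment, low: float = 6.0, high: float = 9.0, order: int = 4
) -> EEGSegment:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    The effective magnitude response is the squared response of a Butterworth
    filter of the stated order; the phase response is identically zero.
    """
    if not (0.0 < low < high):
        raise ValueError("band edges must satisfy 0 < low < high")
    if high >= seg.fs / 2:
        raise ValueError(
            f"band upper edge {high} Hz must lie below Nyquist ({seg.fs / 2} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=seg.fs, output="sos")
    out = signal.sosfiltfilt(sos, seg.data, axis=1)
    return seg.with_data(out)


def rereference_average(seg: EEGSegment) -> EEGSegment:
    """Common-average reference: subtract the instantaneous mean over channels."""
    if seg.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return seg.with_data(seg.data - seg.data.mean(axis=0, keepdims=True))


def pick_segments(
    recording: EEGSegment,
    n: int = 3,
    length: float = 20.0,
    min_gap: float = 60.0,
    max_abs_z: float | None = None,
) -> list[EEGSegment]:
    """Cut ``n`` non-overlapping windows of ``length`` seconds, >= ``min_gap``
    seconds apart (start-to-start separation >= min_gap + length).

    This is a positional stand-in for manual clinical segment selection.  If
    ``max_abs_z`` is given, candidate windows whose amplitude z-score (per
    channel, against the whole recording) exceeds it are vetoed and the search
    slides forward in 1 s steps.
    """
    win = int(round(length * recording.fs))
    stride = int(round((length + min_gap) * recording.fs))
    required = (n - 1) * (length + min_gap) + length
    if recording.duration < required:
        raise ValueError(
            f"recording of {recording.duration:.1f} s too short for {n} "
            f"segments of {length} s with {min_gap} s gaps; "
            f"needs at least {required:.1f} s"
        )
    mu = recording.data.mean(axis=1, keepdims=True)
    sd = recording.data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0

    out: list[EEGSegment] = []
    start = 0
    step_1s = int(round(recording.fs))
    while len(out) < n:
        if start + win > recording.n_samples:
            raise ValueError(
                f"could not place {n} admissible segments of {length} s "
                f"(placed {len(out)}); recording too short or too artifactual"
            )
        chunk = recording.data[:, start : start + win]
        if max_abs_z is not None and np.abs((chunk - mu) / sd).max() > max_abs_z:
            start += step_1s
            continue
        seg = EEGSegment(
            data=chunk.copy(),
            fs=recording.fs,
            channel_labels=recording.channel_labels,
            subject_id=recording.subject_id,
            segment_id=f"seg{len(out) + 1}",
        )
        out.append(seg)
        start += stride
    return out


def preprocess_segment(
    seg: EEGSegment,
    target_fs: float = 250.0,
    band: tuple[float, float] = (6.0, 9.0),
    order: int = 4,
) -> EEGSegment:
    """Canonical conditioning chain: downsample -> band-pass -> re-reference."""
    out = downsample(seg, target_fs)
    out = bandpass_low_alpha(out, band[0], band[1], order)
    return rereference_average(out)
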