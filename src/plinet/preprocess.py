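"""Band filtering, decimation and epoch segmentation.

The standard chain for a 250 Hz resting-state recording is::

    rec -> bandpass_filter(4, 30)  -> downsample(125)
        -> segment(4 s, 50% overlap) -> extract_rhythms(theta/alpha1/alpha2/beta)

All filtering uses a Butterworth design applied forward and backward
(zero-phase).  Because the downstream connectivity measure is built entirely
on phase relations, a causal filter's frequency-dependent group delay —
although identical across channels — is avoided on principle; the effective
magnitude response is the square of the stated order.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .montage import RhythmBand, get_band
from .recording import EEGRecording, EpochSet

DEFAULT_FILTER_ORDER = 4


def _butter_sos(low_hz: float, high_hz: float, order: int, rate: float) -> np.ndarray:
    nyquist = rate / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"band edge {high_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist} Hz for sampling rate {rate} Hz"
        )
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rate, output="sos")


def _filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    # sosfiltfilt needs the signal to exceed its padding length; surface the
    # scipy error as a clearer message.
    padlen = 3 * (2 * (sos.shape[0]) + 1)
    if data.shape[-1] <= padlen:
        raise ValueError(
            f"signal of {data.shape[-1]} samples is too short for stable "
            f"zero-phase filtering (needs > {padlen})"
        )
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass_filter(
    rec: EEGRecording,
    low_hz: float,
    high_hz: float,
    order: int = DEFAULT_FILTER_ORDER,
) -> EEGRecording:
    """Zero-phase Butterworth bandpass of every channel; shape and rate kept."""
    sos = _butter_sos(low_hz, high_hz, order, rec.sampling_rate)
    return rec.with_data(_filtfilt(sos, rec.data))


def downsample(rec: EEGRecording, target_rate_hz: float) -> EEGRecording:
    """Integer-factor decimation.

    The caller must have band-limited the signal below the target Nyquist
    first (the 4-30 Hz broadband filter guards a 125 Hz target).  Resampling
    by a non-integer ratio is deliberately unsupported.
    """
    if not target_rate_hz > 0:
        raise ValueError(f"target rate must be > 0, got {target_rate_hz}")
    factor = rec.sampling_rate / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"cannot downsample {rec.sampling_rate} Hz to {target_rate_hz} Hz: "
            f"the ratio {factor:g} is not an integer; resample-by-ratio is "
            f"unsupported — choose an integer-divisor target rate"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec.with_data(rec.data.copy())
    return rec.with_data(rec.data[:, ::factor], sampling_rate=target_rate_hz)


def segment_count(n_samples: int, window_samples: int, step_samples: int) -> int:
    """Number of full windows: floor((N - window)/step) + 1 (none if N < window)."""
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // step_samples + 1


def segment(
    rec: EEGRecording,
    window_seconds: float,
    overlap_fraction: float,
) -> EpochSet:
    """Cut a recording into fixed-length windows; a trailing partial window is dropped."""
    if not (0 <= overlap_fraction < 1):
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    window_f = window_seconds * rec.sampling_rate
    if abs(window_f - round(window_f)) > 1e-9 or round(window_f) < 1:
        raise ValueError(
            f"window of {window_seconds} s is not a whole positive number of "
            f"samples at {rec.sampling_rate} Hz"
        )
    window = int(round(window_f))
    step = int(round(window * (1 - overlap_fraction)))
    step = max(step, 1)
    n = segment_count(rec.n_samples, window, step)
    if n == 0:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{window}-sample window"
        )
    starts = np.arange(n) * step
    epochs = np.stack([rec.data[:, s : s + window] for s in starts])
    return EpochSet(
        epochs=epochs,
        channel_names=rec.channel_names,
        window_seconds=window_seconds,
        overlap_fraction=overlap_fraction,
        sampling_rate=rec.sampling_rate,
        band="broadband",
        subject_id=rec.subject_id,
        group_label=rec.group_label,
    )


def extract_rhythms(
    epochs: EpochSet,
    bands: Sequence[RhythmBand | str],
    order: int = DEFAULT_FILTER_ORDER,
) -> Mapping[str, EpochSet]:
    """Filter every epoch into each rhythm band; returns ``{band name: EpochSet}``."""
    out: dict[str, EpochSet] = {}
    for band in bands:
        band = get_band(band)
        sos = _butter_sos(band.low_hz, band.high_hz, order, epochs.sampling_rate)
        filtered = _filtfilt(sos, epochs.epochs) if epochs.n_epochs else epochs.epochs
        out[band.name] = EpochSet(
            epochs=filtered,
            channel_names=epochs.channel_names,
            window_seconds=epochs.window_seconds,
            overlap_fraction=epochs.overlap_fraction,
            sampling_rate=epochs.sampling_rate,
            band=band,
            subject_id=epochs.subject_id,
            group_label=epochs.group_label,
        )
    return out
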