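"""Pre-processing: band-pass filtering, average reference, channel repair.

The pipeline mirrors standard resting-state practice: a 1-30 Hz
zero-phase band-pass, interpolation of channels marked bad, and
re-referencing to the whole-head average.  An artifact-removal hook is
provided but defaults to the identity, since the package's synthetic
recordings contain no ocular or cardiac components.
"""
from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import signal

from .io import EEGRecording


def bandpass_filter(rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 30.0,
                    order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied forward and backward.

    ``order`` is the order of each pass (default 4th-order Butterworth);
    the forward-backward application doubles the effective attenuation
    and cancels phase distortion.  Signal length is preserved.
    """
    nyquist = rec.sampling_rate / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist rate {nyquist}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.potentials, axis=1)
    return rec.copy_with(filtered)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: per-sample channel mean becomes 0."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    return rec.copy_with(rec.potentials - rec.potentials.mean(axis=0, keepdims=True))


def interpolate_channels(rec: EEGRecording, bad_labels: list[str],
                         power: float = 2.0) -> EEGRecording:
    """Replace bad channels with inverse-distance-weighted averages.

    Each bad channel is rebuilt as the weighted mean of all good
    channels with weights ``1 / distance**power`` over the electrode
    coordinates.  Good channels are untouched and ordering is preserved.
    """
    if not bad_labels:
        return rec.copy_with(rec.potentials)
    if rec.positions is None:
        raise ValueError("channel interpolation requires electrode positions")
    unknown = set(bad_labels) - set(rec.ch_names)
    if unknown:
        raise ValueError(f"bad labels not in recording: {sorted(unknown)}")
    bad_idx = [rec.ch_names.index(b) for b in bad_labels]
    good_idx = [i for i in range(rec.n_channels) if i not in set(bad_idx)]
    if not good_idx:
        raise ValueError("cannot interpolate: every channel marked bad")

    out = rec.potentials.copy()
    pos = np.asarray(rec.positions, dtype=float)
    for b in bad_idx:
        dist = np.linalg.norm(pos[good_idx] - pos[b], axis=1)
        if np.any(dist < 1e-12):
            # coincident electrode: copy it directly
            out[b] = rec.potentials[good_idx[int(np.argmin(dist))]]
            continue
        w = 1.0 / dist ** power
        out[b] = w @ rec.potentials[good_idx] / w.sum()
    return rec.copy_with(out)


def remove_artifacts(rec: EEGRecording,
                     method: Callable[[EEGRecording], EEGRecording] | None = None
                     ) -> EEGRecording:
    """Artifact-removal hook; identity by default.

    Real-data users can pass any callable (e.g. an ICA-based cleaner);
    the synthetic cohorts shipped with this package are artifact-free.
    """
    if method is None:
        return rec
    return method(rec)


def standard_preprocess(rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 30.0,
                        bad_labels: list[str] | None = None) -> EEGRecording:
    """Band-pass, repair bad channels, and average-reference, in that order."""
    out = bandpass_filter(rec, low_hz, high_hz)
    out = remove_artifacts(out)
    if bad_labels:
        out = interpolate_channels(out, bad_labels)
    return rereference_average(out)
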