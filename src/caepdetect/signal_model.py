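"""Containers and preprocessing for single-channel evoked-potential EEG.

The working unit of every detector in this package is the *epoch ensemble*:
N stimulus-locked EEG segments stacked into an N x T matrix (microvolts).
This module holds the continuous-recording and ensemble containers plus the
standard preprocessing chain: band-pass filtering, absolute-amplitude
artifact rejection, epoching at stimulus onsets, and extraction of the
post-stimulus analysis window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class InvalidFilterError(ValueError):
    """Filter specification incompatible with the sampling rate."""


class EmptyEnsembleError(ValueError):
    """An operation removed every epoch from an ensemble."""


@dataclass(frozen=True)
class ContinuousRecording:
    """A single-channel continuous EEG trace in microvolts.

    Parameters
    ----------
    samples : ndarray
        1-D voltage trace (uV).
    fs : float
        Sampling rate in Hz.
    onsets : ndarray of int, optional
        0-based sample indices of stimulus onsets, strictly increasing.
    """

    samples: np.ndarray
    fs: float
    onsets: np.ndarray | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("recording contains non-finite samples")
        if self.onsets is not None:
            onsets = np.asarray(self.onsets, dtype=int).ravel()
            object.__setattr__(self, "onsets", onsets)
            if onsets.size and (np.any(np.diff(onsets) <= 0)):
                raise ValueError("onsets must be strictly increasing")
            if onsets.size and (onsets[0] < 0 or onsets[-1] >= samples.size):
                raise ValueError("onsets fall outside the recording")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class EpochEnsemble:
    """N stimulus-locked epochs of T samples each (uV), t=0 at column 0."""

    data: np.ndarray
    fs: float

    def __post_init__(self):
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        object.__setattr__(self, "data", data)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError(f"ensemble must be a non-empty 2-D matrix, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("ensemble contains non-finite samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.data.shape[1] / self.fs

    def coherent_average(self) -> np.ndarray:
        """Sample-wise mean across epochs (the averaged evoked response)."""
        return self.data.mean(axis=0)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; defaults follow standard slow-cortical-response practice."""

    low: float = 1.0
    high: float = 15.0
    order: int = 3

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise InvalidFilterError(f"require 0 < low < high, got ({self.low}, {self.high})")
        if self.order < 1:
            raise InvalidFilterError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.high >= fs / 2:
            raise InvalidFilterError(
                f"high cutoff {self.high} Hz must be below Nyquist {fs / 2} Hz"
            )
        return signal.butter(self.order, [self.low, self.high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(rec: ContinuousRecording, spec: FilterSpec = FilterSpec()) -> ContinuousRecording:
    """Zero-phase band-pass filter of a continuous recording.

    The Butterworth filter is applied forward and backward (``sosfiltfilt``),
    so peak latencies are preserved and the effective magnitude response is
    the squared single-pass response.
    """
    filtered = signal.sosfiltfilt(spec.sos(rec.fs), rec.samples)
    return ContinuousRecording(filtered, rec.fs, rec.onsets)


def reject_artifacts(
    ens: EpochEnsemble, threshold_uv: float = 110.0
) -> tuple[EpochEnsemble, int]:
    """Drop epochs containing any sample with ``|x| > threshold_uv``.

    The bound is inclusive: a sample exactly at the threshold is kept.
    Returns the surviving ensemble (original order) and the rejected count.
    """
    if not threshold_uv > 0:
        raise ValueError("threshold must be positive")
    keep = np.all(np.abs(ens.data) <= threshold_uv, axis=1)
    n_rejected = int(np.sum(~keep))
    if not np.any(keep):
        raise EmptyEnsembleError(
            f"all {ens.n_epochs} epochs exceeded the +/-{threshold_uv} uV threshold"
        )
    return EpochEnsemble(ens.data[keep], ens.fs), n_rejected


def epoch_recording(rec: ContinuousRecording, epoch_len_ms: float) -> EpochEnsemble:
    """Cut a continuous recording into stimulus-locked epochs.

    Each onset contributes the half-open sample window
    ``[onset, onset + floor(epoch_len_ms * fs / 1000))``. Onsets whose epoch
    would run past the end of the recording are dropped with a warning.
    """
    if rec.onsets is None or len(rec.onsets) == 0:
        raise ValueError("recording has no stimulus onsets")
    n = int(np.floor(epoch_len_ms * rec.fs / 1000.0))
    if n < 1:
        raise ValueError("epoch length shorter than one sample")
    onsets = rec.onsets
    fits = onsets + n <= rec.n_samples
    n_dropped = int(np.sum(~fits))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} onset(s) whose epoch exceeded the recording end",
            stacklevel=2,
        )
    kept = onsets[fits]
    if kept.size == 0:
        raise EmptyEnsembleError("no complete epoch fits within the recording")
    idx = kept[:, None] + np.arange(n)[None, :]
    return EpochEnsemble(rec.samples[idx], rec.fs)


def analysis_window(ens: EpochEnsemble, window_ms: float = 700.0) -> EpochEnsemble:
    """Truncate each epoch to its first ``floor(window_ms * fs / 1000)`` samples."""
    n = int(np.floor(window_ms * ens.fs / 1000.0))
    if n < 1:
        raise ValueError("window shorter than one sample")
    if n > ens.n_samples:
        raise ValueError(
            f"window of {n} samples exceeds epoch length {ens.n_samples}"
        )
    if n == ens.n_samples:
        return ens
    return EpochEnsemble(ens.data[:, :n], ens.fs)
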