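"""Per-epoch feature extraction for the detection statistics.

Three feature families are supported:

* **voltage means** — the mean voltage over consecutive short (default 50 ms)
  intervals of the analysis window; the time-domain feature vector.
* **Fourier cartesian** — real and imaginary parts of the unnormalized DFT of
  each epoch at a selected set of frequency bins (spectral bands).
* **polar** — amplitudes r_ij and phases a_ij of those same bins, the input
  to the q-sample uniform-scores statistics, optionally rank-transformed with
  ranks pooled across all epochs and bands.

Bands are identified by FFT bin index of the analysis window: with a 700 ms
window at 500 Hz (T = 350 samples) bin k sits at k * 500/350 ~ 1.43 * k Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_model import EpochEnsemble


@dataclass(frozen=True)
class BandSet:
    """A set of FFT bins ("spectral bands") with optional per-band weights.

    ``bins`` are 1-based DFT bin indices of the analysis window (bin k has
    center frequency k * fs / T Hz). Weights lie in (0, 1]; they apply to both
    the real and imaginary feature of their band.
    """

    bins: tuple[int, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        bins = tuple(int(b) for b in self.bins)
        object.__setattr__(self, "bins", bins)
        if len(set(bins)) != len(bins):
            raise ValueError("band bins must be distinct")
        if any(b < 1 for b in bins):
            raise ValueError("band bins are 1-based and must be >= 1")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            object.__setattr__(self, "weights", w)
            if len(w) != len(bins):
                raise ValueError("one weight per band required")
            if any(not (0 < x <= 1) for x in w):
                raise ValueError("weights must lie in (0, 1]")

    @property
    def n_bands(self) -> int:
        return len(self.bins)

    def centers_hz(self, fs: float, n_samples: int) -> np.ndarray:
        """Center frequencies of the bands for a window of ``n_samples`` at ``fs``."""
        return np.asarray(self.bins, dtype=float) * fs / n_samples

    def expanded_weights(self) -> np.ndarray:
        """Weight vector of length 2W: each band's weight repeated for (Re, Im)."""
        w = np.ones(self.n_bands) if self.weights is None else np.asarray(self.weights)
        return np.repeat(w, 2)

    @classmethod
    def from_frequencies(
        cls,
        freqs_hz,
        fs: float,
        n_samples: int,
        weights=None,
    ) -> "BandSet":
        """Build a band set from frequencies in Hz, snapped to the nearest bin."""
        bins = tuple(int(round(f * n_samples / fs)) for f in freqs_hz)
        return cls(bins, None if weights is None else tuple(weights))


def _default_diag_weights(bins: tuple[int, ...], fs: float, n_samples: int) -> tuple[float, ...]:
    # rule of thumb: full weight below 8 Hz, 0.75 for 8-9 Hz, 0.5 for 9-15 Hz
    centers = np.asarray(bins, dtype=float) * fs / n_samples
    w = np.where(centers < 8.0, 1.0, np.where(centers < 9.0, 0.75, 0.5))
    return tuple(w)


def default_t2_freq_bands() -> BandSet:
    """The six bands used by the frequency-domain T2 test, in SNR rank order.

    For the standard 700 ms / 500 Hz window these are the bins at
    5.7, 4.3, 7.1, 2.9, 1.4 and 8.6 Hz.
    """
    return BandSet(bins=(4, 3, 5, 2, 1, 6))


def default_qmod_bands() -> BandSet:
    """Bands for the q-sample statistics: 1.4-10 Hz (bins 1-7 of the 700 ms window)."""
    return BandSet(bins=tuple(range(1, 8)))


def default_t2_diag_bands(fs: float = 500.0, n_samples: int = 350) -> BandSet:
    """Bands and rule-of-thumb weights for the diagonal-covariance T2 test.

    All bins with centers up to 15 Hz (bins 1-10 of the 700 ms window),
    weighted 1 below 8 Hz, 0.75 for 8-9 Hz and 0.5 for 9-15 Hz.
    """
    nyq_bin = int(np.floor(15.0 * n_samples / fs))
    bins = tuple(range(1, nyq_bin + 1))
    return BandSet(bins=bins, weights=_default_diag_weights(bins, fs, n_samples))


@dataclass(frozen=True)
class FeatureMatrix:
    """An N x P matrix of per-epoch features.

    ``kind`` is ``"voltage-mean"`` (P = Q interval means) or
    ``"fourier-cartesian"`` (P = 2W, columns interleaved Re1, Im1, Re2, Im2, ...).
    """

    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("features contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def mean_vector(self) -> np.ndarray:
        """Column means x-bar, the tested quantity of every T2 statistic."""
        return self.values.mean(axis=0)


@dataclass(frozen=True)
class PolarFeatures:
    """Amplitudes (N x W, >= 0) and phases (N x W, radians in [-pi, pi])."""

    amplitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self):
        amp = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        ph = np.atleast_2d(np.asarray(self.phases, dtype=float))
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "phases", ph)
        if amp.shape != ph.shape:
            raise ValueError("amplitude and phase matrices must share a shape")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_epochs(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_bands(self) -> int:
        return self.amplitudes.shape[1]


def voltage_means(ens: EpochEnsemble, interval_ms: float = 50.0) -> FeatureMatrix:
    """Mean voltages over consecutive ``interval_ms`` blocks of each epoch.

    With the default 50 ms intervals a 700 ms window yields Q = 14 features.
    Trailing samples that do not fill a complete interval are discarded.
    """
    length = int(np.floor(interval_ms * ens.fs / 1000.0))
    if length < 1:
        raise ValueError("interval shorter than one sample")
    q = ens.n_samples // length
    if q < 1:
        raise ValueError(
            f"interval of {interval_ms} ms exceeds the {ens.duration_ms} ms window"
        )
    blocks = ens.data[:, : q * length].reshape(ens.n_epochs, q, length)
    return FeatureMatrix(
        blocks.mean(axis=2), kind="voltage-mean", meta={"interval_ms": interval_ms}
    )


def _band_spectrum(data: np.ndarray, bins: tuple[int, ...]) -> np.ndarray:
    """Unnormalized DFT of each row, restricted to the requested 1-based bins."""
    n = data.shape[1]
    max_bin = max(bins)
    if max_bin >= n / 2:
        raise ValueError(
            f"band bin {max_bin} at or above the Nyquist bin for a {n}-sample window"
        )
    spec = np.fft.rfft(data, axis=1)
    return spec[:, list(bins)]


def fourier_features(ens: EpochEnsemble, bands: BandSet) -> FeatureMatrix:
    """Real/imaginary DFT parts of each epoch at the selected bands.

    The transform is applied per epoch (never to the coherent average) and is
    unnormalized; columns are interleaved (Re1, Im1, Re2, Im2, ...) following
    the order of ``bands.bins``.
    """
    spec = _band_spectrum(ens.data, bands.bins)
    out = np.empty((ens.n_epochs, 2 * bands.n_bands))
    out[:, 0::2] = spec.real
    out[:, 1::2] = spec.imag
    return FeatureMatrix(out, kind="fourier-cartesian", meta={"bins": bands.bins})


def polar_features(ens: EpochEnsemble, bands: BandSet) -> PolarFeatures:
    """Amplitude and phase of each epoch's DFT at the selected bands.

    Phases use ``atan2(Im, Re)`` in [-pi, pi]; a zero-amplitude component is
    assigned phase 0 by convention.
    """
    spec = _band_spectrum(ens.data, bands.bins)
    amp = np.abs(spec)
    phase = np.where(amp > 0, np.angle(spec), 0.0)
    return PolarFeatures(amp, phase)


def pooled_ranks(values: np.ndarray) -> np.ndarray:
    """Rank matrix entries jointly across all epochs and bands.

    Ranks run from 1 to N*W over the flattened matrix; ties receive average
    ranks. Pooling across bands (rather than ranking within each band) is what
    lets amplitude ranks carry between-band SNR information.
    """
    values = np.asarray(values, dtype=float)
    return stats.rankdata(values, axis=None).reshape(values.shape)
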