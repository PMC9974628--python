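"""Frequency-domain bootstrap (FDB) inference for detection statistics.

The modified T2 statistics and the q-sample statistics have no convenient
closed-form null distribution, so significance is evaluated against
surrogate recordings that satisfy the null hypothesis of "no response" while
preserving the power and serial correlation of the observed data:

1. estimate the recording's power spectral density P_j with Welch's method
   (2 s Hann windows, 50% overlap by default — the window length is the
   binding smoothing parameter, chosen long enough to wash out
   stimulus-locked spectral peaks);
2. perturb each bin with an independent standard-exponential multiplier
   (unit mean), matching the chi-squared_2 fluctuation of raw periodogram
   ordinates;
3. convert to magnitudes, attach independent uniform [-pi, pi] phases, and
   invert the FFT to obtain a real surrogate series of the same length as
   the observed recording;
4. epoch each surrogate exactly as the observed data and apply the detector,
   building the bootstrapped null distribution of the statistic.

Surrogates are generated at the level of the continuous recording (not per
epoch), so any serial correlation that crosses epoch boundaries is seen by
the statistic. The bootstrap p-value uses the +1 convention,
p = (1 + #{null >= observed}) / (B + 1), which is strictly positive and
valid for finite B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import next_fast_len

from .signal_model import ContinuousRecording, EpochEnsemble

_CHUNK = 100  # surrogates generated per vectorized batch


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided Welch PSD (power per Hz) of a continuous recording."""

    values: np.ndarray
    freqs: np.ndarray
    welch_window_s: float
    n_segments: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "freqs", f)
        if np.any(v < 0):
            raise ValueError("PSD values must be nonnegative")
        if np.any(np.diff(f) <= 0):
            raise ValueError("PSD frequencies must be ascending")


@dataclass(frozen=True)
class SurrogateSpec:
    """Bootstrap configuration: surrogate count, length, and RNG seed."""

    b: int = 1000
    target_len: int | None = None
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self):
        if self.b < 1:
            raise ValueError("need at least one surrogate")
        if self.target_len is not None and self.target_len < 1:
            raise ValueError("target length must be positive")


@dataclass(frozen=True)
class EnsembleGeometry:
    """How a continuous recording maps onto an epoch ensemble.

    ``onsets`` are 0-based stimulus sample indices; each epoch spans
    ``epoch_samples`` from its onset, and detectors see the first
    ``window_samples`` of each epoch.
    """

    onsets: np.ndarray
    epoch_samples: int
    window_samples: int
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=int))
        if self.window_samples > self.epoch_samples:
            raise ValueError("analysis window cannot exceed the epoch")

    @classmethod
    def from_stimulus_rate(
        cls,
        n_epochs: int,
        fs: float = 500.0,
        stimulus_rate: float = 0.9,
        epoch_ms: float | None = None,
        window_ms: float = 700.0,
    ) -> "EnsembleGeometry":
        """Geometry of a periodic-stimulation experiment.

        Onset i falls at sample floor(i * fs / rate); the default epoch spans
        one full inter-stimulus interval (~1111 ms at 0.9 Hz).
        """
        if epoch_ms is None:
            epoch_ms = 1000.0 / stimulus_rate
        onsets = np.floor(np.arange(n_epochs) * fs / stimulus_rate).astype(int)
        return cls(
            onsets=onsets,
            epoch_samples=int(np.floor(epoch_ms * fs / 1000.0)),
            window_samples=int(np.floor(window_ms * fs / 1000.0)),
            fs=fs,
        )

    @property
    def n_epochs(self) -> int:
        return self.onsets.size

    @property
    def required_len(self) -> int:
        return int(self.onsets[-1] + self.epoch_samples)

    def window_ensemble(self, samples: np.ndarray) -> EpochEnsemble:
        """Extract the windowed ensemble a detector consumes."""
        idx = self.onsets[:, None] + np.arange(self.window_samples)[None, :]
        return EpochEnsemble(samples[idx], self.fs)


def welch_psd(rec: ContinuousRecording, window_s: float = 2.0) -> PSDEstimate:
    """Welch PSD with Hann taper and 50% overlap.

    Uses density normalization, so the PSD integrates (over 0..Nyquist) to
    approximately the signal variance.
    """
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than the {nperseg}-sample Welch window"
        )
    freqs, psd = sp_signal.welch(
        rec.samples, fs=rec.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    n_segments = 1 + (rec.n_samples - nperseg) // (nperseg - nperseg // 2)
    return PSDEstimate(values=psd, freqs=freqs, welch_window_s=window_s, n_segments=n_segments)


def _bin_power_scale(n: int, fs: float, nbins: int) -> np.ndarray:
    # |X_j|^2 = P_j * fs * n / 2 for interior bins of a one-sided density PSD
    scale = np.full(nbins, fs * n / 2.0)
    scale[0] = fs * n
    if n % 2 == 0:
        scale[-1] = fs * n
    return scale


def _surrogate_batch(
    psd_target: np.ndarray,
    n: int,
    fs: float,
    count: int,
    rng: np.random.Generator,
    method: str = "gaussian",
) -> np.ndarray:
    """Draw ``count`` surrogates of length ``n`` as rows of a matrix.

    ``psd_target`` is the PSD already interpolated onto the length-n rfft
    grid. Two sampling routes produce the surrogate spectrum:

    * ``"exponential-phase"`` — the literal algorithm: perturb each bin's
      power with an independent Exp(1) multiplier, convert to a magnitude
      and attach an independent uniform phase (DC/Nyquist stay real with a
      random sign);
    * ``"gaussian"`` (default) — draw each interior bin as a circular
      complex Gaussian with variance P_j * scale. For interior bins this is
      *exactly* the same distribution: a complex Gaussian has Exp-distributed
      power and uniform phase. Only the two real bins (DC, Nyquist) differ
      in fluctuation law (chi2_1 vs Exp power, equal means) — both carry
      essentially zero power for band-passed EEG. The Gaussian route avoids
      the trig calls and is used in the bootstrap hot path.
    """
    nbins = psd_target.size
    scale = _bin_power_scale(n, fs, nbins)
    if method == "gaussian":
        sd = np.sqrt(psd_target * scale / 2.0)
        z = rng.standard_normal((count, 2 * nbins))
        spec = (z[:, :nbins] + 1j * z[:, nbins:]) * sd
        spec[:, 0] = z[:, 0] * np.sqrt(psd_target[0] * scale[0])
        if n % 2 == 0:
            spec[:, -1] = z[:, nbins - 1] * np.sqrt(psd_target[-1] * scale[-1])
    elif method == "exponential-phase":
        eps = rng.standard_exponential((count, nbins))
        mag = np.sqrt(psd_target * eps * scale)
        phases = rng.uniform(-np.pi, np.pi, (count, nbins))
        spec = mag * np.exp(1j * phases)
        spec[:, 0] = mag[:, 0] * np.sign(np.cos(phases[:, 0]))
        if n % 2 == 0:
            spec[:, -1] = mag[:, -1] * np.sign(np.cos(phases[:, -1]))
    else:
        raise ValueError(f"unknown surrogate sampling method {method!r}")
    return np.fft.irfft(spec, n=n, axis=1)


def _interp_psd(psd: PSDEstimate, n: int, fs: float) -> np.ndarray:
    grid = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.interp(grid, psd.freqs, psd.values)


def draw_surrogate(
    psd: PSDEstimate, spec: SurrogateSpec, rng: np.random.Generator
) -> ContinuousRecording:
    """Draw a single null-hypothesis surrogate recording from a PSD."""
    if spec.target_len is None:
        raise ValueError("spec.target_len required to draw a surrogate")
    fs = 2.0 * psd.freqs[-1]
    x = _surrogate_batch(
        _interp_psd(psd, spec.target_len, fs),
        spec.target_len,
        fs,
        1,
        rng,
        method="exponential-phase",
    )[0]
    return ContinuousRecording(x, fs)


def bootstrap_p(null_stats: np.ndarray, observed: float) -> float:
    """One-sided bootstrap p-value, p = (1 + #{null >= obs}) / (B + 1)."""
    null_stats = np.asarray(null_stats, dtype=float)
    b = null_stats.size
    if b < 1:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null_stats >= observed)) / (b + 1))


@dataclass(frozen=True)
class BootstrapResult:
    """Observed statistic with its bootstrap p-value."""

    statistic: float
    p_value: float
    b: int


def null_statistics(
    rec: ContinuousRecording,
    geometry: EnsembleGeometry,
    stat_fns: dict,
    spec: SurrogateSpec,
    welch_window_s: float = 2.0,
) -> dict[str, np.ndarray]:
    """Bootstrapped null distributions for one or more detectors.

    Surrogate recordings are generated once (in vectorized batches) and
    shared across all ``stat_fns``; each entry maps a name to a callable
    ``fn(ens, rec) -> float`` taking the windowed surrogate ensemble and the
    surrogate continuous trace. A callable carrying a ``batch`` attribute
    (``fn.batch(windows, traces, fs) -> (B,)``, see ``caepdetect._fast``) is
    evaluated chunk-wise instead of per surrogate. Returns
    ``{name: B null statistics}``. Individual surrogate failures are
    tolerated up to 1% of B, after which the bootstrap aborts.
    """
    psd = welch_psd(rec, welch_window_s)
    n = spec.target_len if spec.target_len is not None else rec.n_samples
    if n < geometry.required_len:
        raise ValueError("surrogate length too short for the ensemble geometry")
    # generate at the next fast FFT length and keep the first n samples; the
    # surrogate process is stationary, so a truncated draw is still a draw
    nfft = next_fast_len(n)
    psd_target = _interp_psd(psd, nfft, rec.fs)
    rng = np.random.default_rng(spec.seed)
    win_idx = geometry.onsets[:, None] + np.arange(geometry.window_samples)[None, :]
    batched = {name: fn for name, fn in stat_fns.items() if hasattr(fn, "batch")}
    scalar = {name: fn for name, fn in stat_fns.items() if name not in batched}
    out = {name: np.empty(spec.b) for name in stat_fns}
    failures = 0
    max_failures = max(1, int(0.01 * spec.b))
    done = 0
    while done < spec.b:
        count = min(_CHUNK, spec.b - done)
        batch = _surrogate_batch(psd_target, nfft, rec.fs, count, rng)[:, :n]
        windows = batch[:, win_idx] if batched else None
        cache: dict = {}
        for name, fn in batched.items():
            try:
                out[name][done : done + count] = fn.batch(
                    windows, batch, geometry.fs, cache
                )
            except Exception:
                # fall back to the scalar path so one bad surrogate is isolated
                for k, row in enumerate(batch):
                    try:
                        out[name][done + k] = fn(
                            EpochEnsemble(row[win_idx], geometry.fs),
                            ContinuousRecording(row, rec.fs),
                        )
                    except Exception:
                        failures += 1
                        if failures > max_failures:
                            raise RuntimeError(
                                f"more than 1% of surrogates failed ({failures}/{spec.b})"
                            )
                        out[name][done + k] = np.nan
        if scalar:
            for k, row in enumerate(batch):
                ens = EpochEnsemble(row[win_idx], geometry.fs)
                surr_rec = ContinuousRecording(row, rec.fs)
                for name, fn in scalar.items():
                    try:
                        out[name][done + k] = fn(ens, surr_rec)
                    except Exception:
                        failures += 1
                        if failures > max_failures:
                            raise RuntimeError(
                                f"more than 1% of surrogates failed ({failures}/{spec.b})"
                            )
                        out[name][done + k] = np.nan
        done += count
    for name in out:
        bad = np.isnan(out[name])
        if bad.any():
            out[name] = out[name][~bad]
    return out


def bootstrap_null(
    stat_fn,
    rec: ContinuousRecording,
    geometry: EnsembleGeometry,
    spec: SurrogateSpec,
    welch_window_s: float = 2.0,
) -> np.ndarray:
    """Null distribution of a single detector statistic (see ``null_statistics``)."""
    return null_statistics(rec, geometry, {"stat": stat_fn}, spec, welch_window_s)["stat"]


def fdb_pvalues(
    rec: ContinuousRecording,
    geometry: EnsembleGeometry,
    stat_fns: dict,
    spec: SurrogateSpec,
    welch_window_s: float = 2.0,
) -> dict[str, BootstrapResult]:
    """Observed statistics and bootstrap p-values for one recording.

    The observed ensemble is extracted from ``rec`` with ``geometry``; the
    same geometry is applied to every surrogate, and for statistics that
    re-estimate a covariance from the continuous trace (the Toeplitz T2) the
    estimate is re-done per surrogate.
    """
    ens = geometry.window_ensemble(rec.samples)
    observed = {name: fn(ens, rec) for name, fn in stat_fns.items()}
    nulls = null_statistics(rec, geometry, stat_fns, spec, welch_window_s)
    return {
        name: BootstrapResult(
            statistic=observed[name],
            p_value=bootstrap_p(nulls[name], observed[name]),
            b=nulls[name].size,
        )
        for name in stat_fns
    }
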