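"""The five CAEP detection statistics.

All detectors test the null hypothesis of "no evoked response": the mean
feature vector of an epoch ensemble equals zero (the recordings are
zero-mean after high-pass filtering, and under stationary noise the spectral
phases are uniform).

* ``T2_Time`` — one-sample Hotelling's T2 on Q voltage means, F inference.
* ``T2_Freq`` — Hotelling's T2 on 2W Fourier real/imaginary parts, F inference.
* ``T2_Toep`` — T2 with the covariance constrained to Toeplitz structure,
  estimated from the autocovariance of the continuous recording's interval
  means; inference by the frequency-domain bootstrap.
* ``T2_Diag`` — T2 with a diagonal covariance (spectral bands asymptotically
  independent for stationary noise) and per-band SNR weights; bootstrap
  inference.
* ``QMod`` — modified q-sample uniform-scores statistics V1-V4 on spectral
  phases and amplitudes, with optional rank transforms pooled across epochs
  and bands; bootstrap inference.

The Toeplitz and diagonal statistics are plain quadratic forms without the
leading N of the classical T2. That factor is irrelevant here: their null
distributions are obtained by applying the *identical* functional to
bootstrap surrogates, so any fixed scale cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .features import (
    BandSet,
    FeatureMatrix,
    PolarFeatures,
    default_qmod_bands,
    default_t2_diag_bands,
    default_t2_freq_bands,
    fourier_features,
    polar_features,
    pooled_ranks,
    voltage_means,
)
from .signal_model import ContinuousRecording, EpochEnsemble

QMOD_VARIANTS = ("V1", "V2", "V3", "V4")
# variant -> (phases as ranks?, amplitudes as ranks?)
_QMOD_MODES = {"V1": (True, False), "V2": (True, True), "V3": (False, True), "V4": (False, False)}

_RIDGE_CONDITION_LIMIT = 1e8


class RankDeficiencyError(np.linalg.LinAlgError):
    """Feature covariance not invertible (N <= P or degenerate features)."""


@dataclass(frozen=True)
class CovarianceModel:
    """A feature covariance estimate: full sample, Toeplitz, or diagonal.

    For ``kind="toeplitz"`` the generating autocovariance lags gamma(0..Q-1)
    are kept alongside the assembled matrix; for ``kind="diagonal"`` only the
    per-feature variances are stored.
    """

    kind: str
    matrix: np.ndarray | None = None
    gamma: np.ndarray | None = None
    variances: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("sample", "toeplitz", "diagonal"):
            raise ValueError(f"unknown covariance kind {self.kind!r}")


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of one detector applied to one ensemble."""

    statistic: float
    method: str
    inference: str  # "F" or "bootstrap"
    p_value: float
    alpha: float
    dof: tuple[int, int] | None = None

    @property
    def detected(self) -> bool:
        return self.p_value <= self.alpha


# ---------------------------------------------------------------------------
# Hotelling's T2 with F inference
# ---------------------------------------------------------------------------

def hotelling_t2(features: FeatureMatrix | np.ndarray, mu: np.ndarray | None = None) -> float:
    """One-sample Hotelling's T2 statistic, N (x-bar - mu) S^-1 (x-bar - mu)'.

    S is the sample covariance of the N x P feature matrix (N-1 denominator).
    ``mu`` defaults to the zero vector.
    """
    v = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(np.asarray(features, dtype=float))
    n, p = v.shape
    if n <= p:
        raise RankDeficiencyError(
            f"need more epochs than features for an invertible covariance (N={n}, P={p})"
        )
    xbar = v.mean(axis=0)
    d = xbar if mu is None else xbar - np.asarray(mu, dtype=float)
    s = np.cov(v, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    try:
        sol = linalg.solve(s, d, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - degenerate features
        raise RankDeficiencyError("singular feature covariance") from exc
    return float(n * d @ sol)


@dataclass(frozen=True)
class FInference:
    f_stat: float
    v1: int
    v2: int
    p_value: float


def f_inference(t2: float, n: int, p: int) -> FInference:
    """Exact F transform of T2 under Gaussian theory.

    F = (N - p) / (p (N - 1)) * T2 follows F(v1 = p, v2 = N - p) under the
    null; the p-value is the upper tail.
    """
    if n <= p:
        raise ValueError(f"F transform requires N > p (N={n}, p={p})")
    f_stat = (n - p) / (p * (n - 1)) * t2
    p_value = float(stats.f.sf(f_stat, p, n - p))
    return FInference(float(f_stat), p, n - p, p_value)


# ---------------------------------------------------------------------------
# Toeplitz-covariance T2
# ---------------------------------------------------------------------------

def toeplitz_cov(
    rec: ContinuousRecording | np.ndarray,
    interval_ms: float,
    q: int,
    fs: float | None = None,
) -> CovarianceModel:
    """Toeplitz covariance of interval means, from a continuous recording.

    The recording is reduced to its sequence of consecutive non-overlapping
    ``interval_ms`` means; the biased, mean-subtracted autocovariance
    gamma(0..Q-1) of that sequence fills the constant diagonals of the Q x Q
    matrix. The biased estimator (1/M denominator) guarantees the assembled
    matrix is positive semidefinite.
    """
    if isinstance(rec, ContinuousRecording):
        samples, fs = rec.samples, rec.fs
    else:
        samples = np.asarray(rec, dtype=float).ravel()
        if fs is None:
            raise ValueError("fs required when passing a bare sample array")
    length = int(np.floor(interval_ms * fs / 1000.0))
    if length < 1:
        raise ValueError("interval shorter than one sample")
    m = samples.size // length
    if m < 2 * q:
        raise ValueError(
            f"need at least {2 * q} interval means to estimate {q} autocovariance lags, got {m}"
        )
    means = samples[: m * length].reshape(m, length).mean(axis=1)
    c = means - means.mean()
    gamma = np.array([c[: m - lag] @ c[lag:] for lag in range(q)]) / m
    return CovarianceModel(kind="toeplitz", matrix=linalg.toeplitz(gamma), gamma=gamma)


def t2_toeplitz(
    xbar: np.ndarray, cov: CovarianceModel, mu: np.ndarray | None = None
) -> float:
    """Quadratic form (x-bar - mu) S_Toep^-1 (x-bar - mu)'.

    No leading N (see module docstring). If the Toeplitz matrix is
    numerically ill-conditioned (condition number above 1e8) a small ridge of
    1e-8 gamma(0) is added to the diagonal before solving.
    """
    if cov.kind != "toeplitz":
        raise ValueError("t2_toeplitz requires a toeplitz CovarianceModel")
    xbar = np.asarray(xbar, dtype=float).ravel()
    d = xbar if mu is None else xbar - np.asarray(mu, dtype=float)
    s = cov.matrix
    if np.linalg.cond(s) > _RIDGE_CONDITION_LIMIT:
        s = s + np.eye(s.shape[0]) * (1e-8 * cov.gamma[0])
        if np.linalg.cond(s) > _RIDGE_CONDITION_LIMIT:
            raise RankDeficiencyError("Toeplitz covariance not invertible after ridge")
    return float(d @ linalg.solve(s, d, assume_a="pos"))


# ---------------------------------------------------------------------------
# Diagonal-covariance T2
# ---------------------------------------------------------------------------

def t2_diag(
    xbar: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray | None = None,
    mu: np.ndarray | None = None,
) -> float:
    """Weighted diagonal-covariance T2: sum_i (w_i x-bar_i - mu_i)^2 / S_i.

    ``variances`` are the per-feature sample variances of the *unweighted*
    features; ``weights`` (length 2W, each band's weight repeated for its Re
    and Im entries) rescale only the mean vector.
    """
    xbar = np.asarray(xbar, dtype=float).ravel()
    s = np.asarray(variances, dtype=float).ravel()
    if np.any(s <= 0):
        raise ValueError("feature variances must be positive")
    wx = xbar if weights is None else np.asarray(weights, dtype=float).ravel() * xbar
    d = wx if mu is None else wx - np.asarray(mu, dtype=float)
    return float(np.sum(d * d / s))


# ---------------------------------------------------------------------------
# Modified q-sample uniform-scores statistics
# ---------------------------------------------------------------------------

def qmod(pol: PolarFeatures, variant: str = "V3") -> float:
    """Modified q-sample uniform-scores statistic.

    For each band j the statistic accumulates the squared resultant of the
    amplitude-weighted phase vectors,

        sum_j [ (sum_i r_ij cos theta_ij)^2 + (sum_i r_ij sin theta_ij)^2 ],

    where r_ij is the amplitude (or its pooled rank) and theta_ij the phase
    (or its pooled rank mapped to angles rank * 2 pi / (N W)). Variants:
    V1 phase ranks + amplitude values, V2 both ranks, V3 phase values +
    amplitude ranks, V4 both values. Ranks are pooled across all epochs and
    bands (1 .. N*W). Raw phases enter as angles directly; the
    2 pi / (N W) mapping applies only to ranks, which is what turns a rank
    into an angle on the circle.
    """
    if variant not in _QMOD_MODES:
        raise ValueError(f"variant must be one of {QMOD_VARIANTS}, got {variant!r}")
    phase_ranks, amp_ranks = _QMOD_MODES[variant]
    n, w = pol.amplitudes.shape
    r = pooled_ranks(pol.amplitudes) if amp_ranks else pol.amplitudes
    if phase_ranks:
        theta = pooled_ranks(pol.phases) * (2.0 * np.pi / (n * w))
    else:
        theta = pol.phases
    c = np.sum(r * np.cos(theta), axis=0)
    s = np.sum(r * np.sin(theta), axis=0)
    return float(np.sum(c * c + s * s))


# ---------------------------------------------------------------------------
# Ensemble-level detector pipelines
# ---------------------------------------------------------------------------

def t2_time_statistic(ens: EpochEnsemble, interval_ms: float = 50.0) -> float:
    """Hotelling's T2 on voltage means of the analysis-window ensemble."""
    return hotelling_t2(voltage_means(ens, interval_ms))


def t2_freq_statistic(ens: EpochEnsemble, bands: BandSet | None = None) -> float:
    """Hotelling's T2 on Fourier real/imaginary features."""
    bands = default_t2_freq_bands() if bands is None else bands
    return hotelling_t2(fourier_features(ens, bands))


def t2_toep_statistic(
    ens: EpochEnsemble,
    rec: ContinuousRecording | None = None,
    interval_ms: float = 50.0,
) -> float:
    """Toeplitz-covariance T2 of the windowed ensemble.

    The mean vector comes from the ensemble's voltage means; the covariance
    from the continuous recording's interval-mean autocovariance. When no
    continuous trace is supplied, the concatenation of the (full) epochs in
    order stands in for it.
    """
    fm = voltage_means(ens, interval_ms)
    source = rec if rec is not None else ens.data.ravel()
    cov = toeplitz_cov(source, interval_ms, fm.n_features, fs=ens.fs)
    return t2_toeplitz(fm.mean_vector(), cov)


def t2_diag_statistic(ens: EpochEnsemble, bands: BandSet | None = None) -> float:
    """Weighted diagonal-covariance T2 on Fourier features."""
    if bands is None:
        bands = default_t2_diag_bands(ens.fs, ens.n_samples)
    fm = fourier_features(ens, bands)
    variances = fm.values.var(axis=0, ddof=1)
    return t2_diag(fm.mean_vector(), variances, bands.expanded_weights())


def qmod_statistic(ens: EpochEnsemble, bands: BandSet | None = None, variant: str = "V3") -> float:
    """q-sample uniform-scores statistic on the ensemble's polar features."""
    bands = default_qmod_bands() if bands is None else bands
    return qmod(polar_features(ens, bands), variant)


def detect_f(
    ens: EpochEnsemble,
    method: str = "t2_time",
    alpha: float = 0.01,
    interval_ms: float = 50.0,
    bands: BandSet | None = None,
) -> DetectionResult:
    """Run an F-calibrated Hotelling detector on an ensemble.

    ``method`` is ``"t2_time"`` (Q voltage means, dof (Q, N-Q)) or
    ``"t2_freq"`` (2W Fourier features, dof (2W, N-2W)).
    """
    if method == "t2_time":
        fm = voltage_means(ens, interval_ms)
    elif method == "t2_freq":
        fm = fourier_features(ens, default_t2_freq_bands() if bands is None else bands)
    else:
        raise ValueError(f"F inference applies to t2_time/t2_freq, not {method!r}")
    t2 = hotelling_t2(fm)
    inf = f_inference(t2, fm.n_epochs, fm.n_features)
    return DetectionResult(
        statistic=t2,
        method=method,
        inference="F",
        p_value=inf.p_value,
        alpha=alpha,
        dof=(inf.v1, inf.v2),
    )
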