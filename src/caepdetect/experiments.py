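"""Drivers for simulation studies of detector specificity and sensitivity.

These functions tie the simulator, detectors and bootstrap together into the
two canonical experiments:

* **specificity** — simulate many null (noise-only) ensembles, apply each
  detector, and measure the false-positive rate at a nominal alpha;
* **sensitivity** — inject a response template at a target SNR and measure
  detection rates, optionally at alpha levels re-adjusted so every method's
  empirical false-positive rate matches the target.

Each simulated ensemble draws its background-noise AR model at random from
the preset library and (under H1) its response template at random from the
template library, emulating the across-subject variability of a real cohort.
All randomness descends from a single integer seed via spawned substreams,
so every study is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fast
from .detectors import (
    detect_f,
    qmod_statistic,
    t2_diag_statistic,
    t2_freq_statistic,
    t2_time_statistic,
    t2_toep_statistic,
)
from .fdb import SurrogateSpec, fdb_pvalues
from .simulate import SimulationConfig, default_ar_presets, simulate_ensemble

F_METHODS = ("t2_time", "t2_freq")
BOOTSTRAP_METHODS = ("t2_toep", "t2_diag", "qmod_v1", "qmod_v2", "qmod_v3", "qmod_v4")


def statistic_fn(method: str, interval_ms: float = 50.0):
    """The ensemble-level statistic ``fn(ens, rec) -> float`` for a method name.

    Bootstrap-inferred statistics additionally carry a ``batch`` attribute
    (their vectorization over surrogate batches, from ``caepdetect._fast``)
    which the bootstrap machinery exploits automatically.
    """
    if method == "t2_time":
        return lambda ens, rec: t2_time_statistic(ens, interval_ms)
    if method == "t2_freq":
        return lambda ens, rec: t2_freq_statistic(ens)
    if method == "t2_toep":
        fn = lambda ens, rec: t2_toep_statistic(ens, rec, interval_ms)
        fn.batch = lambda windows, traces, fs, cache=None: _fast.t2_toep_batch(
            windows, traces, fs, interval_ms, cache
        )
        return fn
    if method == "t2_diag":
        fn = lambda ens, rec: t2_diag_statistic(ens)
        fn.batch = _fast.t2_diag_batch
        return fn
    if method.startswith("qmod_"):
        variant = method.split("_")[1].upper()
        fn = lambda ens, rec: qmod_statistic(ens, variant=variant)
        fn.batch = lambda windows, traces, fs, cache=None: _fast.qmod_batch(
            windows, traces, fs, variant, cache
        )
        return fn
    raise ValueError(f"unknown method {method!r}")


def _spawn(seed, n):
    return np.random.SeedSequence(seed).spawn(n)


def _draw_config(n_epochs, snr_db, presets, rng) -> SimulationConfig:
    model = presets[rng.integers(len(presets))]
    return SimulationConfig(n_epochs=n_epochs, snr_db=snr_db, ar_model=model)


@dataclass(frozen=True)
class StudyResult:
    """Per-ensemble p-values (methods x ensembles) from one simulation study."""

    p_values: dict[str, np.ndarray]
    n_ensembles: int

    def rejection_rate(self, alpha: float | dict[str, float] = 0.01) -> dict[str, float]:
        """Fraction of ensembles rejected at alpha (scalar or per-method)."""
        out = {}
        for m, p in self.p_values.items():
            a = alpha[m] if isinstance(alpha, dict) else alpha
            out[m] = float(np.mean(p <= a))
        return out


def run_f_study(
    n_epochs: int,
    n_ensembles: int,
    seed: int,
    snr_db: float | None = None,
    methods: tuple[str, ...] = F_METHODS,
) -> StudyResult:
    """Simulate ensembles and apply the F-calibrated Hotelling detectors."""
    for m in methods:
        if m not in F_METHODS:
            raise ValueError(f"{m!r} is not an F-inference method")
    presets = default_ar_presets()
    pvals = {m: np.empty(n_ensembles) for m in methods}
    for i, child in enumerate(_spawn(seed, n_ensembles)):
        rng = np.random.default_rng(child)
        cfg = _draw_config(n_epochs, snr_db, presets, rng)
        _, ens = simulate_ensemble(cfg, rng)
        for m in methods:
            pvals[m][i] = detect_f(ens, method=m).p_value
    return StudyResult(p_values=pvals, n_ensembles=n_ensembles)


def run_bootstrap_study(
    n_epochs: int,
    n_ensembles: int,
    seed: int,
    snr_db: float | None = None,
    methods: tuple[str, ...] = ("t2_toep", "t2_diag", "qmod_v3"),
    b: int = 1000,
    welch_window_s: float = 2.0,
) -> StudyResult:
    """Simulate ensembles and apply bootstrap-calibrated detectors.

    One set of B surrogates per ensemble is shared across all requested
    methods, exactly as a single recording would be bootstrapped once and
    analyzed with every statistic.
    """
    presets = default_ar_presets()
    stat_fns = {m: statistic_fn(m) for m in methods}
    pvals = {m: np.empty(n_ensembles) for m in methods}
    for i, child in enumerate(_spawn(seed, n_ensembles)):
        sim_seed, boot_seed = child.spawn(2)
        rng = np.random.default_rng(sim_seed)
        cfg = _draw_config(n_epochs, snr_db, presets, rng)
        rec, _ = simulate_ensemble(cfg, rng)
        geometry = cfg.geometry()
        results = fdb_pvalues(
            rec, geometry, stat_fns, SurrogateSpec(b=b, seed=boot_seed), welch_window_s
        )
        for m in methods:
            pvals[m][i] = results[m].p_value
    return StudyResult(p_values=pvals, n_ensembles=n_ensembles)


def null_statistic_sample(
    n_epochs: int,
    n_ensembles: int,
    seed: int,
    methods: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Raw detector statistics under H0, for threshold-based alpha adjustment.

    Pooling statistics across many independent null simulations gives the
    marginal null distribution over the noise-model library; its upper
    quantile is the decision threshold whose false-positive rate equals the
    target. This sidesteps a per-ensemble bootstrap when only calibrated
    *decisions* (not p-values) are needed, e.g. in power studies.
    """
    presets = default_ar_presets()
    stat_fns = {m: statistic_fn(m) for m in methods}
    stats = {m: np.empty(n_ensembles) for m in methods}
    for i, child in enumerate(_spawn(seed, n_ensembles)):
        rng = np.random.default_rng(child)
        cfg = _draw_config(n_epochs, None, presets, rng)
        rec, ens = simulate_ensemble(cfg, rng)
        for m in methods:
            stats[m][i] = stat_fns[m](ens, rec)
    return stats


def detection_rate_at_threshold(
    n_epochs: int,
    snr_db: float | None,
    n_ensembles: int,
    seed: int,
    thresholds: dict[str, float],
) -> dict[str, float]:
    """Fraction of simulated ensembles whose statistic exceeds its threshold."""
    presets = default_ar_presets()
    methods = tuple(thresholds)
    stat_fns = {m: statistic_fn(m) for m in methods}
    hits = {m: 0 for m in methods}
    for child in _spawn(seed, n_ensembles):
        rng = np.random.default_rng(child)
        cfg = _draw_config(n_epochs, snr_db, presets, rng)
        rec, ens = simulate_ensemble(cfg, rng)
        for m in methods:
            if stat_fns[m](ens, rec) > thresholds[m]:
                hits[m] += 1
    return {m: hits[m] / n_ensembles for m in methods}
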