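"""Delimited-text file formats and run configuration.

Ensembles and continuous recordings travel as plain tab-separated text with
a small JSON sidecar (``<file>.json``) carrying the sampling rate and
geometry. Inputs are small (at most a few hundred epochs of a few hundred
samples), so diffable text beats a binary container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_model import ContinuousRecording, EpochEnsemble


class FormatError(ValueError):
    """Malformed input file (bad cell, dimension mismatch, missing sidecar)."""


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _read_sidecar(path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        return json.load(fh)


def _parse_matrix(path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split("\t")
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell at row {lineno}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: row {lineno} has {len(row)} columns, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty matrix")
    return np.asarray(rows)


def write_ensemble(path, ens: EpochEnsemble, epoch_ms: float | None = None) -> None:
    """Write an ensemble as a TSV matrix (rows = epochs) plus JSON sidecar."""
    np.savetxt(path, ens.data, delimiter="\t", fmt="%.10g")
    meta = {
        "fs_hz": ens.fs,
        "n_epochs": ens.n_epochs,
        "epoch_ms": epoch_ms if epoch_ms is not None else ens.duration_ms,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_ensemble(path) -> EpochEnsemble:
    """Read a TSV ensemble written by ``write_ensemble`` (lossless round trip)."""
    meta = _read_sidecar(path)
    data = _parse_matrix(path)
    n_declared = int(meta["n_epochs"])
    if data.shape[0] != n_declared:
        raise FormatError(
            f"{path}: sidecar declares {n_declared} epochs but matrix has {data.shape[0]} rows"
        )
    return EpochEnsemble(data, fs=float(meta["fs_hz"]))


def write_recording(path, rec: ContinuousRecording) -> None:
    """Write a continuous recording as one sample per line plus JSON sidecar."""
    np.savetxt(path, rec.samples, fmt="%.10g")
    meta = {"fs_hz": rec.fs}
    if rec.onsets is not None:
        meta["onsets"] = [int(o) for o in rec.onsets]
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_recording(path) -> ContinuousRecording:
    """Read a single-column recording with its {fs_hz, onsets} sidecar."""
    meta = _read_sidecar(path)
    data = _parse_matrix(path)
    if data.shape[1] != 1:
        raise FormatError(f"{path}: expected a single column, got {data.shape[1]}")
    onsets = meta.get("onsets")
    return ContinuousRecording(
        data[:, 0],
        fs=float(meta["fs_hz"]),
        onsets=None if onsets is None else np.asarray(onsets, dtype=int),
    )


_KNOWN_DETECTORS = ("t2_time", "t2_freq", "t2_toep", "t2_diag", "qmod_v1", "qmod_v2", "qmod_v3", "qmod_v4")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a detection run.

    Defaults encode the standard protocol: 500 Hz sampling, 0.9 Hz stimulus
    rate, 700 ms analysis window, 50 ms voltage-mean intervals, 1000
    bootstrap surrogates, alpha = 0.01.
    """

    detectors: tuple[str, ...] = ("t2_time",)
    alpha: float = 0.01
    seed: int | None = None
    interval_ms: float = 50.0
    window_ms: float = 700.0
    artifact_threshold_uv: float | None = 110.0
    n_surrogates: int = 1000
    welch_window_s: float = 2.0

    def __post_init__(self):
        for d in self.detectors:
            if d not in _KNOWN_DETECTORS:
                raise ValueError(f"unknown detector {d!r}; choose from {_KNOWN_DETECTORS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.needs_bootstrap and self.seed is None:
            raise ValueError("a seed is mandatory for bootstrap-inferred detectors")

    @property
    def needs_bootstrap(self) -> bool:
        return any(d not in ("t2_time", "t2_freq") for d in self.detectors)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "detectors" in d:
            d = dict(d, detectors=tuple(d["detectors"]))
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
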