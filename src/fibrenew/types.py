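"""Core containers shared across the analysis pipeline.

The central objects are

* :class:`EventTable` — the look-up table of tracked entities (phase
  singularities or wavelets) with onset/offset times, locations,
  chirality and epoch-boundary censoring flags;
* :class:`PhaseMovie` — a T x H x W grid of instantaneous phase in
  radians, the substrate on which singularities and wavefronts are
  detected;
* :class:`EgmSet` — multichannel unipolar electrograms with electrode
  geometry;
* :class:`RateFit`, :class:`PopulationSeries`, :class:`BDSpectrum` —
  the statistical outputs: renewal-rate estimates, running entity
  counts, and the empirical birth-death transition-matrix spectrum.

Conventions: time is milliseconds everywhere and rates are per ms;
intervals are half-open ``[onset, offset)`` so a single-frame entity has
lifetime ``dt_ms``; pixel coordinates are 0-based with ``x`` = column
and ``y`` = row; phase values live in ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "MMInfParams",
    "EventTable",
    "PhaseMovie",
    "SpiralDefect",
    "SpiralScript",
    "EgmSet",
    "FilterSpec",
    "DominantFrequency",
    "PSDetection",
    "WavefrontDetection",
    "TrackConfig",
    "IntervalSample",
    "RateFit",
    "MMInfPrediction",
    "PopulationSeries",
    "BDSpectrum",
    "ParameterError",
]


class ParameterError(ValueError):
    """Invalid parameter or malformed input."""


#: Exact column order of the EventTable CSV interface.
EVENT_COLUMNS = [
    "id",
    "kind",
    "onset_ms",
    "offset_ms",
    "x",
    "y",
    "chirality",
    "censored_left",
    "censored_right",
]


@dataclass(frozen=True)
class MMInfParams:
    """Parameters of the M/M/inf event-stream simulator.

    ``lambda_f`` is the Poisson formation rate (events per ms),
    ``lambda_d`` the per-entity exponential destruction rate (per ms),
    ``duration_ms`` the epoch length and ``seed`` the RNG seed.
    """

    lambda_f: float
    lambda_d: float
    duration_ms: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_f < 0:
            raise ParameterError(f"lambda_f must be >= 0, got {self.lambda_f}")
        if self.lambda_d <= 0:
            raise ParameterError(f"lambda_d must be > 0, got {self.lambda_d}")
        if self.duration_ms <= 0:
            raise ParameterError(f"duration_ms must be > 0, got {self.duration_ms}")

    @property
    def rho(self) -> float:
        """Offered load lambda_f / lambda_d — the M/M/inf mean count."""
        return self.lambda_f / self.lambda_d


class EventTable:
    """Tracked entities with onsets, offsets, locations and chirality.

    Wraps a :class:`pandas.DataFrame` with the canonical columns
    :data:`EVENT_COLUMNS`. ``chirality`` is +1/-1 for phase
    singularities and 0 for wavelets ("none"). ``censored_left`` /
    ``censored_right`` mark entities truncated by the epoch boundary.
    """

    def __init__(self, records: pd.DataFrame, epoch_ms: float, metadata: dict | None = None):
        records = records.copy()
        if len(records) == 0:
            records = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                EVENT_COLUMNS,
                ["int64", "object", "float64", "float64", "float64", "float64",
                 "int64", "bool", "bool"])})
        missing = [c for c in EVENT_COLUMNS if c not in records.columns]
        if missing:
            raise ParameterError(f"EventTable missing columns: {missing}")
        records = records[EVENT_COLUMNS].reset_index(drop=True)
        if len(records):
            if records["id"].duplicated().any():
                raise ParameterError("EventTable ids must be unique")
            bad = records["offset_ms"] < records["onset_ms"]
            if bad.any():
                raise ParameterError("offset_ms must be >= onset_ms for all records")
        self.records = records
        self.epoch_ms = float(epoch_ms)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return f"EventTable(n={len(self)}, epoch_ms={self.epoch_ms})"

    def of_kind(self, kind: str) -> "EventTable":
        return EventTable(self.records[self.records["kind"] == kind],
                          self.epoch_ms, self.metadata)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch_ms: float, metadata: dict | None = None) -> "EventTable":
        df = pd.read_csv(path)
        df["censored_left"] = df["censored_left"].astype(bool)
        df["censored_right"] = df["censored_right"].astype(bool)
        return cls(df, epoch_ms, metadata)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into ``(-pi, pi]``."""
    out = np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)
    return np.pi - out


@dataclass
class PhaseMovie:
    """A spatiotemporal phase grid: ``values[t, row, col]`` in radians."""

    values: np.ndarray
    dt_ms: float
    pixel_mm: float = 1.0
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ParameterError("PhaseMovie values must be T x H x W")
        if self.dt_ms <= 0:
            raise ParameterError("dt_ms must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape[1:]:
                raise ParameterError("mask shape must match frame shape")
        v = self.values[:, self.mask]
        if v.size and (v.min() <= -np.pi - 1e-9 or v.max() > np.pi + 1e-9):
            raise ParameterError("phase values must lie in (-pi, pi]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.dt_ms


@dataclass(frozen=True)
class SpiralDefect:
    """One planted phase defect: static or moving along ``path``."""

    birth_frame: int
    death_frame: int  # exclusive, half-open [birth, death)
    path: np.ndarray  # (n_frames_alive, 2) of (x, y), or (2,) if static
    chirality: int

    def __post_init__(self) -> None:
        if self.death_frame < self.birth_frame:
            raise ParameterError("death_frame must be >= birth_frame")
        if self.chirality not in (-1, 1):
            raise ParameterError("chirality must be +1 or -1")
        p = np.atleast_2d(np.asarray(self.path, dtype=float))
        n_alive = self.death_frame - self.birth_frame
        if len(p) == 1:
            p = np.repeat(p, max(n_alive, 1), axis=0)
        elif len(p) != n_alive:
            raise ParameterError("path length must equal death_frame - birth_frame")
        object.__setattr__(self, "path", p)

    def position(self, frame: int) -> np.ndarray:
        return self.path[frame - self.birth_frame]

    def alive(self, frame: int) -> bool:
        return self.birth_frame <= frame < self.death_frame


@dataclass
class SpiralScript:
    """Ground-truth screenplay for a synthetic phase movie."""

    defects: list[SpiralDefect]
    n_frames: int
    omega: float = 0.05  # background rotation rate, rad per ms
    pair_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.pair_mode:
            charge = None
            for f in range(self.n_frames):
                c = sum(d.chirality for d in self.defects if d.alive(f))
                if charge is None:
                    charge = c
                elif c != charge:
                    raise ParameterError(
                        "pair_mode requires constant net planted charge")


@dataclass
class EgmSet:
    """Multichannel unipolar electrograms with electrode geometry."""

    signals: np.ndarray  # channels x samples
    fs_hz: float
    coords_mm: np.ndarray  # channels x 2
    r_times_ms: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be > 0")
        if len(self.coords_mm) != self.signals.shape[0]:
            raise ParameterError("coords count must equal channel count")
        if self.r_times_ms is not None:
            self.r_times_ms = np.asarray(self.r_times_ms, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs_hz


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band edges; applied forward-reverse when zero_phase."""

    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs_hz: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs_hz / 2:
            raise ParameterError(
                f"high_hz={self.high_hz} must be below Nyquist {fs_hz / 2}")


@dataclass(frozen=True)
class DominantFrequency:
    df_hz: float
    power_fraction: float
    reliable: bool = True

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.df_hz


@dataclass(frozen=True)
class PSDetection:
    """A phase singularity found in a single frame."""

    frame: int
    x: float
    y: float
    chirality: int
    method: str = "kernel"


@dataclass(frozen=True)
class WavefrontDetection:
    """A zero-phase isoline found in a single frame."""

    frame: int
    polyline: np.ndarray  # (n, 2) of (x, y)
    endpoints: tuple = ()  # free ends not touching the boundary

    def pixel_set(self) -> frozenset:
        # rasterize each vertex to the 4 pixels of its unit cell so that
        # sub-pixel drift between frames still yields shared pixels
        lo = np.floor(self.polyline).astype(int)
        pts = {(x + dx, y + dy) for x, y in map(tuple, lo)
               for dx in (0, 1) for dy in (0, 1)}
        return frozenset(pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.polyline.mean(axis=0)


@dataclass(frozen=True)
class TrackConfig:
    """Tracking parameters: association radius r and minimum lifetime tau."""

    r: float = 4.0
    r_unit: str = "mm"  # "mm" or "px"
    tau_ms: float = 10.0
    match_chirality: bool = True
    assignment: str = "optimal"  # or "greedy"
    min_overlap: int = 1  # wavefront shared-pixel threshold

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ParameterError("r must be > 0")
        if self.tau_ms < 0:
            raise ParameterError("tau_ms must be >= 0")
        if self.r_unit not in ("mm", "px"):
            raise ParameterError("r_unit must be 'mm' or 'px'")
        if self.assignment not in ("optimal", "greedy"):
            raise ParameterError("assignment must be 'optimal' or 'greedy'")

    def radius_px(self, pixel_mm: float) -> float:
        return self.r / pixel_mm if self.r_unit == "mm" else self.r


@dataclass
class IntervalSample:
    """Durations (ms) feeding an exponential fit."""

    values: np.ndarray
    kind: str  # "interformation" | "lifetime"
    source: str = "PS"  # entity kind
    n_censored_excluded: int = 0
    shift_ms: float = 0.0  # known left truncation (tracking tau)
    quantum_ms: float = 0.0  # frame quantization step (0 = continuous times)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < 0:
            raise ParameterError("interval values must be >= 0")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class RateFit:
    """Exponential renewal-rate estimate with CI and chi-square GOF."""

    lambda_per_ms: float
    ci95: tuple[float, float]
    n: int
    chi2_stat: float = float("nan")
    chi2_p: float = float("nan")
    ci_method: str = "gamma-exact"
    kind: str = ""
    source: str = ""
    shift_ms: float = 0.0

    @property
    def se(self) -> float:
        return self.lambda_per_ms / np.sqrt(self.n)

    def to_dict(self) -> dict:
        return {
            "lambda_per_ms": self.lambda_per_ms,
            "ci95": list(self.ci95),
            "n": self.n,
            "chi2_stat": self.chi2_stat,
            "chi2_p": self.chi2_p,
            "ci_method": self.ci_method,
            "kind": self.kind,
            "source": self.source,
            "shift_ms": self.shift_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateFit":
        d = dict(d)
        d["ci95"] = tuple(d["ci95"])
        return cls(**d)


@dataclass
class MMInfPrediction:
    """Steady-state M/M/inf prediction: mean count and Poisson pmf."""

    rho: float
    pmf: np.ndarray  # P_0 .. P_nmax

    @property
    def mean_n(self) -> float:
        return self.rho

    @property
    def n_max(self) -> int:
        return len(self.pmf) - 1


@dataclass
class PopulationSeries:
    """Concurrent entity count per frame — the running count."""

    counts: np.ndarray
    dt_ms: float
    kind: str = "PS"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.dt_ms <= 0:
            raise ParameterError("dt_ms must be > 0")
        if self.counts.size and (self.counts < 0).any():
            raise ParameterError("counts must be non-negative")
        self.counts = self.counts.astype(int)

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def subsample(self, stride: int) -> "PopulationSeries":
        return PopulationSeries(self.counts[::stride], self.dt_ms * stride, self.kind)


@dataclass
class BDSpectrum:
    """Empirical birth-death transition matrix and its eigen-spectrum.

    ``slem`` is the second largest eigenvalue modulus; the spectral gap
    ``1 - slem`` is identified with the mixing rate — the speed at which
    the chain approaches its quasi-stationary count distribution.
    """

    states: np.ndarray
    matrix: np.ndarray
    eigen_moduli: np.ndarray
    dt_ms: float
    unvisited_states: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def slem(self) -> float:
        return float(self.eigen_moduli[1]) if len(self.eigen_moduli) > 1 else float("nan")

    @property
    def spectral_gap(self) -> float:
        return 1.0 - self.slem

    @property
    def mixing_rate(self) -> float:
        return self.spectral_gap

    def to_dict(self) -> dict:
        return {
            "states": self.states.tolist(),
            "matrix": self.matrix.tolist(),
            "eigen_moduli": self.eigen_moduli.tolist(),
            "slem": self.slem,
            "spectral_gap": self.spectral_gap,
            "mixing_rate": self.mixing_rate,
            "dt_ms": self.dt_ms,
            "unvisited_states": self.unvisited_states.tolist(),
        }
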