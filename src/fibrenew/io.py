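"""Readers and writers for the on-disk interchange formats.

* PhaseMovie — NPY (T x H x W radians) or HDF5 dataset ``"phase"`` with
  attributes ``dt_ms`` and ``pixel_mm`` and an optional ``"mask"``
  dataset;
* EgmSet — HDF5 datasets ``"signals"`` and ``"coords_mm"`` with
  attribute ``fs_hz``, or CSV (samples x channels) plus a JSON sidecar;
* EventTable — CSV with the canonical column set.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import EgmSet, EventTable, ParameterError, PhaseMovie

__all__ = [
    "save_phase_movie",
    "load_phase_movie",
    "save_egm",
    "load_egm",
    "save_events",
    "load_events",
]


def save_phase_movie(movie: PhaseMovie, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, movie.values)
        return
    with h5py.File(path, "w") as f:
        d = f.create_dataset("phase", data=movie.values)
        d.attrs["dt_ms"] = movie.dt_ms
        d.attrs["pixel_mm"] = movie.pixel_mm
        f.create_dataset("mask", data=movie.mask.astype(np.uint8))


def load_phase_movie(path: str | Path, dt_ms: float | None = None,
                     pixel_mm: float = 1.0) -> PhaseMovie:
    path = Path(path)
    if path.suffix == ".npy":
        if dt_ms is None:
            raise ParameterError("dt_ms is required when loading from NPY")
        return PhaseMovie(np.load(path), dt_ms=dt_ms, pixel_mm=pixel_mm,
                          metadata={"path": str(path)})
    with h5py.File(path, "r") as f:
        d = f["phase"]
        values = d[...]
        dt = float(d.attrs.get("dt_ms", dt_ms if dt_ms is not None else 1.0))
        px = float(d.attrs.get("pixel_mm", pixel_mm))
        mask = f["mask"][...].astype(bool) if "mask" in f else None
    return PhaseMovie(values, dt_ms=dt, pixel_mm=px, mask=mask,
                      metadata={"path": str(path)})


def save_egm(egm: EgmSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(egm.signals.T).to_csv(path, index=False)
        sidecar = {
            "fs_hz": egm.fs_hz,
            "coords_mm": egm.coords_mm.tolist(),
            "r_times_ms": (egm.r_times_ms.tolist()
                           if egm.r_times_ms is not None else None),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        return
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signals", data=egm.signals)
        d.attrs["fs_hz"] = egm.fs_hz
        f.create_dataset("coords_mm", data=egm.coords_mm)
        if egm.r_times_ms is not None:
            f.create_dataset("r_times_ms", data=egm.r_times_ms)


def load_egm(path: str | Path) -> EgmSet:
    path = Path(path)
    if path.suffix == ".csv":
        sidecar = json.loads(path.with_suffix(".json").read_text())
        signals = pd.read_csv(path).to_numpy().T
        r = sidecar.get("r_times_ms")
        return EgmSet(signals, fs_hz=sidecar["fs_hz"],
                      coords_mm=np.asarray(sidecar["coords_mm"]),
                      r_times_ms=np.asarray(r) if r is not None else None)
    with h5py.File(path, "r") as f:
        signals = f["signals"][...]
        fs = float(f["signals"].attrs["fs_hz"])
        coords = f["coords_mm"][...]
        r = f["r_times_ms"][...] if "r_times_ms" in f else None
    return EgmSet(signals, fs_hz=fs, coords_mm=coords, r_times_ms=r)


def save_events(events: EventTable, path: str | Path) -> None:
    events.to_csv(path)


def load_events(path: str | Path, epoch_ms: float) -> EventTable:
    return EventTable.from_csv(path, epoch_ms=epoch_ms)
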