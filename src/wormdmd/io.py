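"""HDF5 archives for traces, decompositions and reference modes.

Small, flat layouts: one group-less file per object, datasets named after
the fields, scalar metadata in attributes.  Strings are stored as UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dmd import DMDResult
from .dynamics import VoltageTrace
from .mode_analysis import PLMModes

__all__ = [
    "save_trace", "load_trace",
    "save_dmd", "load_dmd",
    "save_modes", "load_modes",
    "write_manifest",
]


def save_trace(path, trace: VoltageTrace, attrs: dict | None = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("V", data=trace.V, compression="gzip")
        fh.attrs["dt_record"] = trace.dt_record
        fh.attrs["t0"] = trace.t0
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val
    return path


def load_trace(path) -> VoltageTrace:
    with h5py.File(path, "r") as fh:
        return VoltageTrace(fh["V"][...], float(fh.attrs["dt_record"]),
                            float(fh.attrs["t0"]))


def save_dmd(path, result: DMDResult) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("modes", data=result.modes)
        fh.create_dataset("eigenvalues", data=result.eigenvalues)
        fh.create_dataset("taus", data=result.taus)
        fh.create_dataset("singular_values", data=result.singular_values)
        if result.amplitudes is not None:
            fh.create_dataset("amplitudes", data=result.amplitudes)
        fh.attrs["rank"] = result.rank
        fh.attrs["energy_threshold"] = result.energy_threshold
        fh.attrs["dt"] = result.dt
    return path


def load_dmd(path) -> DMDResult:
    with h5py.File(path, "r") as fh:
        amps = fh["amplitudes"][...] if "amplitudes" in fh else None
        return DMDResult(
            modes=fh["modes"][...],
            eigenvalues=fh["eigenvalues"][...],
            taus=fh["taus"][...],
            singular_values=fh["singular_values"][...],
            rank=int(fh.attrs["rank"]),
            energy_threshold=float(fh.attrs["energy_threshold"]),
            dt=float(fh.attrs["dt"]),
            amplitudes=amps,
        )


def save_modes(path, modes: PLMModes) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("d", data=modes.d)
        fh.create_dataset("p1", data=modes.p1)
        fh.create_dataset("p2", data=modes.p2)
    return path


def load_modes(path) -> PLMModes:
    with h5py.File(path, "r") as fh:
        return PLMModes(fh["d"][...], fh["p1"][...], fh["p2"][...])


def write_manifest(path, payload: dict) -> Path:
    """JSON run manifest (config echo, seeds, package version)."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=default, sort_keys=True))
    return path
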