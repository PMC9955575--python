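"""Attractor/trajectory persistence: HDF5 container + JSON summary."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .tissue import TissueAttractor, unique_cellular_attractors

__all__ = [
    "save_attractor",
    "load_attractor",
    "attractor_summary",
    "field_to_csv",
    "write_summary",
]


def field_to_csv(path: str | Path, concentration: np.ndarray) -> None:
    """Export a concentration field as per-voxel CSV rows (x, y, z, C)."""
    c = np.asarray(concentration)
    if c.ndim != 3:
        raise ValueError("concentration must be a 3D voxel array")
    with open(path, "w") as fh:
        fh.write("x,y,z,C\n")
        for (x, y, z), val in np.ndenumerate(c):
            fh.write(f"{x},{y},{z},{val:.10g}\n")


def save_attractor(path: str | Path, attractor: TissueAttractor) -> None:
    """Store a detected attractor: bit-packed cycle states, transient,
    period and the per-cell CA assignment."""
    if not attractor.found:
        raise ValueError("cannot store a timeout result")
    n_cells, n_total = attractor.cycle[0].shape
    packed = np.stack([np.packbits(s, axis=1) for s in attractor.cycle])
    _, assignment = unique_cellular_attractors(attractor)
    with h5py.File(path, "w") as f:
        f.attrs["transient"] = attractor.transient
        f.attrs["period"] = attractor.period
        f.attrs["n_cells"] = n_cells
        f.attrs["n_total"] = n_total
        f.create_dataset("cycle_packed", data=packed, compression="gzip")
        f.create_dataset("ca_assignment", data=assignment)


def load_attractor(path: str | Path) -> TissueAttractor:
    with h5py.File(path, "r") as f:
        n_total = int(f.attrs["n_total"])
        packed = f["cycle_packed"][...]
        cycle = tuple(
            np.unpackbits(p, axis=1, count=n_total).astype(np.uint8) for p in packed
        )
        return TissueAttractor(
            True,
            transient=int(f.attrs["transient"]),
            period=int(f.attrs["period"]),
            cycle=cycle,
        )


def attractor_summary(attractor: TissueAttractor) -> dict:
    """JSON-ready summary: transient, period, number of unique CAs."""
    cas, assignment = unique_cellular_attractors(attractor)
    return {
        "transient": attractor.transient,
        "period": attractor.period,
        "recurrence_time": attractor.recurrence_time,
        "n_unique_cas": len(cas),
        "ca_sizes": [len(ca) for ca in cas],
    }


def write_summary(path: str | Path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2))
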