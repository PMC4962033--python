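"""File formats: NRRD volumes, HDF5 field containers, CSV tables, manifests.

All tabular outputs carry provenance header lines (``# key: value``) with
the run seed and config hash so any file can be traced to the exact run
that produced it; HDF5 datasets are written without modification-time
tracking so reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .expansion import ExpansionMap
from .piv3d import DisplacementField

__all__ = [
    "write_nrrd",
    "read_nrrd",
    "write_manifest",
    "read_manifest",
    "write_fields_h5",
    "read_fields_h5",
    "write_table",
    "read_table",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_nrrd(array: np.ndarray, path, voxel_spacing_um: float = 1.0) -> None:
    """Write a 3D array as uncompressed NRRD with isotropic spacing."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing((float(voxel_spacing_um),) * 3)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_nrrd(path) -> tuple[np.ndarray, float]:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img), float(img.GetSpacing()[0])


def write_manifest(path, frame_files: list[str], frame_times, voxel_spacing_um: float,
                   provenance: dict | None = None) -> None:
    """Volume-series manifest: one file + acquisition time per frame."""
    doc = {
        "voxel_spacing_um": float(voxel_spacing_um),
        "frames": [
            {"file": f, "time_s": float(t)} for f, t in zip(frame_files, frame_times)
        ],
    }
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_fields_h5(path, fields: list[DisplacementField],
                    expansions: list[ExpansionMap] | None = None,
                    provenance: dict | None = None) -> None:
    """Displacement (and optionally expansion) grids for all frame pairs."""
    with h5py.File(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.attrs[k] = v
        for i, f in enumerate(fields):
            g = fh.create_group(f"pair_{i:02d}")
            g.create_dataset("vectors", data=f.vectors, track_times=False)
            g.create_dataset("flags", data=f.flags, track_times=False)
            if f.subpixel_fallback is not None:
                g.create_dataset("fallback", data=f.subpixel_fallback,
                                 track_times=False)
            g.attrs["origin"] = f.origin
            g.attrs["spacing"] = f.spacing
            g.attrs["frame_pair"] = f.frame_pair
            if expansions is not None:
                e = expansions[i]
                g.create_dataset("expansion", data=e.values, track_times=False)
                g.create_dataset("expansion_valid", data=e.valid, track_times=False)


def read_fields_h5(path) -> tuple[list[DisplacementField], list[ExpansionMap]]:
    fields: list[DisplacementField] = []
    expansions: list[ExpansionMap] = []
    with h5py.File(path, "r") as fh:
        for name in sorted(k for k in fh if k.startswith("pair_")):
            g = fh[name]
            pair = tuple(int(v) for v in g.attrs["frame_pair"])
            f = DisplacementField(
                vectors=g["vectors"][()],
                flags=g["flags"][()],
                origin=np.asarray(g.attrs["origin"]),
                spacing=int(g.attrs["spacing"]),
                frame_pair=pair,  # type: ignore[arg-type]
                subpixel_fallback=g["fallback"][()] if "fallback" in g else None,
            )
            fields.append(f)
            if "expansion" in g:
                expansions.append(ExpansionMap(
                    values=g["expansion"][()],
                    valid=g["expansion_valid"][()],
                    origin=f.origin.copy(),
                    spacing=f.spacing,
                    frame_pair=pair,  # type: ignore[arg-type]
                ))
    return fields, expansions


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV with ``# key: value`` provenance header lines."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
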