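"""Readers and writers binding the pipeline stages together.

Formats:

* volumes and maps — multi-page TIFF (32-bit float; one page per B-scan
  or en-face plane) with a JSON sidecar (same stem, ``.json``) holding the
  scan geometry, page order and provenance;
* masks — single/multi-page 8-bit TIFF (0/255);
* cohort and metric tables — CSV (RFC 4180 as written by pandas) with the
  fixed columns ``patient_id, visit, location, bvd, vet_um, vhi, vsq``.

Every writer's output round-trips through its reader with float32
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import PhantomGeometry
from .ibdv import EnFaceMap, VarianceVolume
from .phantom import AcquisitionVolume

__all__ = [
    "write_acquisition", "read_acquisition",
    "write_variance_volume", "read_variance_volume",
    "write_enface", "read_enface",
    "write_mask", "read_mask",
    "write_cohort_csv", "read_cohort_csv",
]

COHORT_COLUMNS = ["patient_id", "visit", "location", "bvd", "vet_um", "vhi", "vsq"]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def _write_json(path, payload: dict) -> None:
    _sidecar(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _read_json(path) -> dict:
    return json.loads(_sidecar(path).read_text())


def write_acquisition(vol: AcquisitionVolume, path) -> None:
    """Write repeated-frame amplitude data as multi-page TIFF + JSON.

    Page order is slow-position-major: page ``y * n_repeats + j`` holds
    frame j at slow position y, stored as an (x, z) float32 image.
    """
    frames = vol.frames.astype(np.float32)
    ny, nrep, nx, nz = frames.shape
    tifffile.imwrite(path, frames.reshape(ny * nrep, nx, nz))
    _write_json(path, {
        "kind": "acquisition",
        "geometry": vol.geometry.to_dict(),
        "page_order": "slow_position_major",
        "page_shape": "(n_fast, n_depth)",
        "params": vol.params,
    })


def read_acquisition(path) -> AcquisitionVolume:
    meta = _read_json(path)
    geom = PhantomGeometry.from_dict(meta["geometry"])
    pages = tifffile.imread(path)
    frames = pages.reshape(geom.n_slow, geom.n_repeats, geom.n_fast, geom.n_depth)
    return AcquisitionVolume(frames=frames, geometry=geom, params=meta.get("params", {}))


def write_variance_volume(vol: VarianceVolume, path) -> None:
    """One float32 page per slow position, each (x, z)."""
    sigma2 = vol.sigma2.astype(np.float32)
    tifffile.imwrite(path, np.moveaxis(sigma2, 1, 0))  # pages over y
    _write_json(path, {
        "kind": "variance_volume",
        "geometry": vol.geometry.to_dict() if vol.geometry else None,
        "provenance": vol.provenance,
    })


def read_variance_volume(path) -> VarianceVolume:
    meta = _read_json(path)
    pages = tifffile.imread(path)
    geom = PhantomGeometry.from_dict(meta["geometry"]) if meta.get("geometry") else None
    return VarianceVolume(np.moveaxis(pages, 0, 1), geometry=geom,
                          provenance=meta.get("provenance", {}))


def write_enface(m: EnFaceMap, path) -> None:
    tifffile.imwrite(path, m.values.astype(np.float32))
    _write_json(path, {
        "kind": "enface",
        "z_bounds": list(m.z_bounds) if m.z_bounds else None,
        "geometry": m.geometry.to_dict() if m.geometry else None,
    })


def read_enface(path) -> EnFaceMap:
    meta = _read_json(path)
    values = tifffile.imread(path)
    zb = tuple(meta["z_bounds"]) if meta.get("z_bounds") else None
    geom = PhantomGeometry.from_dict(meta["geometry"]) if meta.get("geometry") else None
    return EnFaceMap(values, z_bounds=zb, geometry=geom)


def write_mask(mask: np.ndarray, path, provenance: dict | None = None) -> None:
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    _write_json(path, {"kind": "mask", "provenance": provenance or {}})


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a study table with the fixed column set and order."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "location": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df
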