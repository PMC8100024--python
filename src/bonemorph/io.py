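"""File formats for profiles, masks, volumes and result tables.

* section profiles — CSV with one row per vertex (role, index, x_um, y_um)
  plus a JSON sidecar holding specimen metadata;
* 2D masks — PNG or TIFF (8-bit, bone=255) with pixel size and site in a
  JSON sidecar;
* 3D volumes — multi-page TIFF stacks (8-bit, bone=255) with voxel size,
  origin and site in a JSON sidecar;
* measurement and cohort tables — tidy CSV, one row per
  specimen x compartment x zone x parameter.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cartilage import BoundaryTrace, SectionProfile
from .trab2d import TrabMask2D
from .trab3d import TrabVolume3D

__all__ = [
    "write_section_profile",
    "read_section_profile",
    "write_mask2d",
    "read_mask2d",
    "write_volume3d",
    "read_volume3d",
    "write_table",
    "read_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_section_profile(profile: SectionProfile, path) -> Path:
    """Write a profile as vertex CSV + JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for role, trace in profile.traces.items():
        for i, (x, y) in enumerate(trace.vertices):
            rows.append({"role": role, "index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        "compartment": profile.compartment,
        "specimen": profile.specimen,
        "group": profile.group,
        "joint": profile.joint,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_section_profile(path) -> SectionProfile:
    path = Path(path)
    df = pd.read_csv(path)
    traces = {}
    for role, sub in df.groupby("role"):
        sub = sub.sort_values("index")
        traces[role] = BoundaryTrace(role, sub[["x_um", "y_um"]].to_numpy(float))
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return SectionProfile(traces=traces, **{k: v for k, v in meta.items() if v})


def write_mask2d(mask: TrabMask2D, path) -> Path:
    path = Path(path)
    img = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    _sidecar(path).write_text(
        json.dumps({"pixel_size_mm": mask.pixel_size_mm, "site": mask.site})
    )
    return path


def read_mask2d(path) -> TrabMask2D:
    path = Path(path)
    img = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return TrabMask2D(np.asarray(img) > 0, meta["pixel_size_mm"], meta.get("site", "tibia"))


def write_volume3d(volume: TrabVolume3D, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, volume.volume.astype(np.uint8) * 255)
    _sidecar(path).write_text(
        json.dumps(
            {
                "voxel_size_mm": volume.voxel_size_mm,
                "origin_mm": list(volume.origin_mm),
                "site": volume.site,
            }
        )
    )
    return path


def read_volume3d(path) -> TrabVolume3D:
    path = Path(path)
    vol = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return TrabVolume3D(
        np.asarray(vol) > 0,
        meta["voxel_size_mm"],
        tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        meta.get("site", "tibia"),
    )


def write_table(df: pd.DataFrame, path) -> Path:
    """Tidy CSV with stable float formatting (deterministic byte output)."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
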