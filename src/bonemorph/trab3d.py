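"""3D trabecular microarchitecture in cylindrical VOIs of micro-CT volumes.

Volumes are binary voxel grids (bone=True) with isotropic voxel size,
analysed inside cylindrical volumes of interest placed per anatomical
convention: diameter 2.5 mm with 2.5 mm depth for femoral compartments and
1.5 mm depth for tibial compartments, at anterior/central/posterior
positions on the medial or lateral side.  Indices:

* ``BV/TV`` (%)  — bone voxels over in-VOI voxels,
* ``Tb.Th`` (mm) — volume-weighted mean maximal-inscribed-sphere thickness
  of the bone phase,
* ``Tb.Sp`` (mm) — the same measure on the marrow phase,
* ``Tb.N`` (1/mm) — by default the plate-model identity (BV/TV)/Tb.Th; the
  alternative 1/(Tb.Th + Tb.Sp) is available.

Voxels outside the cylinder belong to neither phase: they terminate both
distance transforms, so inscribed spheres never extend across the VOI wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._localthickness import local_thickness_map
from .trab2d import ROI_SIZES_MM, TrabMask2D

__all__ = [
    "VOI_DEPTH_MM",
    "VOI_DIAMETER_MM",
    "TrabVolume3D",
    "CylVOI",
    "MaskedVOI",
    "Trab3DResult",
    "extract_voi",
    "bv_tv",
    "local_thickness",
    "tb_n",
    "central_plane_section",
    "measure_voi",
]

VOI_DIAMETER_MM = 2.5
VOI_DEPTH_MM = {"femur": 2.5, "tibia": 1.5}


@dataclass
class TrabVolume3D:
    """Binary voxel volume (bone=True), isotropic voxel size, (z, y, x) order."""

    volume: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) of voxel (0,0,0) corner
    site: str = "tibia"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume).astype(bool)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def size_mm(self) -> tuple[float, float, float]:
        nz, ny, nx = self.volume.shape
        h = self.voxel_size_mm
        return nx * h, ny * h, nz * h


@dataclass
class CylVOI:
    """Cylindrical VOI, axis along z, physical coordinates in mm."""

    center_mm: tuple[float, float, float]  # (x, y, z)
    diameter_mm: float = VOI_DIAMETER_MM
    depth_mm: float = VOI_DEPTH_MM["tibia"]
    position: str = "central"  # anterior | central | posterior
    side: str = "lateral"  # lateral | medial

    @classmethod
    def for_site(cls, site: str, center_mm, position="central", side="lateral") -> "CylVOI":
        return cls(center_mm=tuple(center_mm), diameter_mm=VOI_DIAMETER_MM,
                   depth_mm=VOI_DEPTH_MM[site], position=position, side=side)


@dataclass
class MaskedVOI:
    """Cropped subvolume plus the in-cylinder validity mask."""

    bone: np.ndarray  # (nz, ny, nx) bool, bone inside the crop
    inside: np.ndarray  # (nz, ny, nx) bool, voxel centre inside the cylinder
    voxel_size_mm: float
    voi: CylVOI


@dataclass
class Trab3DResult:
    bv_tv_pct: float
    tb_th_mm: float
    tb_sp_mm: float
    tb_n_per_mm: float
    position: str = ""
    side: str = ""

    def as_records(self) -> list[dict]:
        return [
            {"parameter": "BV/TV", "value": self.bv_tv_pct},
            {"parameter": "Tb.Th", "value": self.tb_th_mm},
            {"parameter": "Tb.Sp", "value": self.tb_sp_mm},
            {"parameter": "Tb.N", "value": self.tb_n_per_mm},
        ]


def _voxel_centres(n: int, h: float, origin: float) -> np.ndarray:
    return origin + (np.arange(n) + 0.5) * h


def extract_voi(volume: TrabVolume3D, voi: CylVOI) -> MaskedVOI:
    """Crop the VOI's bounding box and mask voxels by the analytic cylinder.

    Voxel-centre inclusion test; rejects VOIs that are not fully inside the
    volume, reporting the contained fraction.
    """
    h = volume.voxel_size_mm
    ox, oy, oz = volume.origin_mm
    cx, cy, cz = voi.center_mm
    r = voi.diameter_mm / 2.0
    nz, ny, nx = volume.volume.shape

    x0 = int(np.floor((cx - r - ox) / h))
    x1 = int(np.ceil((cx + r - ox) / h))
    y0 = int(np.floor((cy - r - oy) / h))
    y1 = int(np.ceil((cy + r - oy) / h))
    z0 = int(np.floor((cz - voi.depth_mm / 2.0 - oz) / h))
    z1 = int(np.ceil((cz + voi.depth_mm / 2.0 - oz) / h))
    if x0 < 0 or y0 < 0 or z0 < 0 or x1 > nx or y1 > ny or z1 > nz:
        fx0, fy0, fz0 = max(x0, 0), max(y0, 0), max(z0, 0)
        fx1, fy1, fz1 = min(x1, nx), min(y1, ny), min(z1, nz)
        inter = max(0, fx1 - fx0) * max(0, fy1 - fy0) * max(0, fz1 - fz0)
        total = (x1 - x0) * (y1 - y0) * (z1 - z0)
        raise ValueError(
            f"VOI at {voi.center_mm} extends outside the volume "
            f"(contained fraction {inter / total:.2f})"
        )
    xs = _voxel_centres(nx, h, ox)[x0:x1]
    ys = _voxel_centres(ny, h, oy)[y0:y1]
    zs = _voxel_centres(nz, h, oz)[z0:z1]
    in_disc = ((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2) <= r ** 2
    in_depth = np.abs(zs - cz) <= voi.depth_mm / 2.0
    inside = in_depth[:, None, None] & in_disc[None, :, :]
    # pad with one out-of-VOI layer: the distance transform must terminate at
    # the VOI wall even when in-VOI voxels touch the crop's bounding box
    pad = ((1, 1),) * 3
    return MaskedVOI(
        bone=np.pad(volume.volume[z0:z1, y0:y1, x0:x1] & inside, pad),
        inside=np.pad(inside, pad),
        voxel_size_mm=h,
        voi=voi,
    )


def _as_masked(sub, voxel_size_mm=None) -> MaskedVOI:
    if isinstance(sub, MaskedVOI):
        return sub
    if isinstance(sub, TrabVolume3D):
        # whole-volume analysis: every voxel is in-VOI
        return MaskedVOI(
            bone=sub.volume,
            inside=np.ones(sub.volume.shape, dtype=bool),
            voxel_size_mm=sub.voxel_size_mm,
            voi=CylVOI(center_mm=(0, 0, 0)),
        )
    arr = np.asarray(sub).astype(bool)
    return MaskedVOI(
        bone=arr,
        inside=np.ones(arr.shape, dtype=bool),
        voxel_size_mm=float(voxel_size_mm),
        voi=CylVOI(center_mm=(0, 0, 0)),
    )


def bv_tv(sub: MaskedVOI | TrabVolume3D) -> float:
    """Bone volume fraction in percent over the in-VOI voxels."""
    m = _as_masked(sub)
    n_in = int(m.inside.sum())
    if n_in == 0:
        raise ValueError("VOI contains no voxels")
    pct = 100.0 * float(m.bone.sum()) / n_in
    if pct == 0.0:
        warnings.warn("VOI contains no bone voxels", stacklevel=2)
    return pct


def local_thickness(sub: MaskedVOI | TrabVolume3D, phase: str = "bone") -> float:
    """Mean maximal-sphere thickness (mm) of the bone or marrow phase.

    Out-of-VOI voxels belong to neither phase, so they bound the distance
    transform exactly like the opposite phase would.  Returns NaN when the
    phase is empty.
    """
    m = _as_masked(sub)
    if phase == "bone":
        ph = m.bone & m.inside
    elif phase == "marrow":
        ph = (~m.bone) & m.inside
    else:
        raise ValueError("phase must be 'bone' or 'marrow'")
    if not ph.any():
        warnings.warn(f"{phase} phase is empty in the VOI", stacklevel=2)
        return float("nan")
    field = local_thickness_map(ph, m.voxel_size_mm)
    return float(field[ph].mean())


def tb_n(bvtv_pct: float, tbth_mm: float, tbsp_mm: float | None = None,
         model: str = "plate") -> float:
    """Trabecular number in 1/mm.

    ``model="plate"`` uses the parallel-plate identity (BV/TV)/Tb.Th;
    ``model="inverse-sum"`` uses 1/(Tb.Th + Tb.Sp) and requires ``tbsp_mm``.
    """
    if model == "plate":
        if not np.isfinite(tbth_mm) or tbth_mm <= 0:
            return float("nan")
        return (bvtv_pct / 100.0) / tbth_mm
    if model == "inverse-sum":
        if tbsp_mm is None:
            raise ValueError("inverse-sum model needs tbsp_mm")
        denom = tbth_mm + tbsp_mm
        return 1.0 / denom if denom > 0 else float("nan")
    raise ValueError("model must be 'plate' or 'inverse-sum'")


def central_plane_section(volume: TrabVolume3D, voi: CylVOI, site: str | None = None) -> TrabMask2D:
    """Extract the mid-axis (x–z) plane of a central VOI as a 2D histology ROI.

    The plane contains the cylinder axis at the VOI's y-centre; the returned
    mask follows the 2D ROI convention for the site (width along x, height
    along the cylinder depth z), enabling coupled 2D/3D measurements on the
    same synthetic specimen.
    """
    site = site or volume.site
    h = volume.voxel_size_mm
    ox, oy, oz = volume.origin_mm
    cx, cy, cz = voi.center_mm
    w_mm, h_mm = ROI_SIZES_MM[site]
    nz, ny, nx = volume.volume.shape

    iy = int((cy - oy) / h)
    if not 0 <= iy < ny:
        raise ValueError("central plane lies outside the volume")
    x0 = int(round((cx - w_mm / 2.0 - ox) / h))
    z0 = int(round((cz - h_mm / 2.0 - oz) / h))
    npx = int(round(w_mm / h))
    npz = int(round(h_mm / h))
    if x0 < 0 or z0 < 0 or x0 + npx > nx or z0 + npz > nz:
        raise ValueError("central-plane ROI extends outside the volume")
    plane = volume.volume[z0:z0 + npz, iy, x0:x0 + npx]
    return TrabMask2D(plane, h, site)


def measure_voi(volume: TrabVolume3D, voi: CylVOI, tbn_model: str = "plate") -> Trab3DResult:
    """BV/TV, Tb.Th, Tb.Sp and Tb.N for one cylindrical VOI."""
    sub = extract_voi(volume, voi)
    bvtv = bv_tv(sub)
    tbth = local_thickness(sub, "bone")
    tbsp = local_thickness(sub, "marrow")
    return Trab3DResult(
        bv_tv_pct=bvtv,
        tb_th_mm=tbth,
        tb_sp_mm=tbsp,
        tb_n_per_mm=tb_n(bvtv, tbth, tbsp, tbn_model),
        position=voi.position,
        side=voi.side,
    )
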