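"""Zoned cartilage and subchondral-plate morphometry on traced section profiles.

A histological section of one femorotibial compartment is represented by four
traced boundary polylines, ordered from the joint space downwards:

* ``surface`` — the articular cartilage surface,
* ``tidemark`` — the junction between uncalcified and calcified cartilage,
* ``cement_line`` — the calcified-cartilage / subchondral-plate junction,
* ``trab_junction`` — the plate / epiphyseal-trabecular-bone junction.

A straight chord joining the surface endpoints defines the region of interest,
which is split into four equal-width zones (Z1–Z4).  Layer thicknesses are
mean lengths of rays cast perpendicular to that chord:

* ``nCg.Th`` — surface to tidemark (uncalcified cartilage),
* ``cCg.Th`` — tidemark to cement line (calcified cartilage),
* ``Cg.Th``  — their sum (total cartilage),
* ``SB.Th``  — cement line to trabecular junction (subchondral plate).

The fibrillation index (FI) of a zone is the arclength of the surface trace
clipped to the zone divided by the zone's chord width; 1 for a perfectly
smooth surface, increasing with fissuring and undulation.  The µm excess
``L - W`` is kept as a secondary output.

All computations happen in the chord coordinate frame (u along the chord,
v perpendicular to it), which makes every quantity exactly invariant under
rigid motions of the traced section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROLES",
    "COMPARTMENTS",
    "BoundaryTrace",
    "SectionProfile",
    "ZonedROI",
    "ThicknessResult",
    "FibrillationResult",
    "define_roi",
    "mean_thickness",
    "total_cartilage_thickness",
    "fibrillation_index",
    "measure_section",
]

#: anatomical boundary roles, ordered from the joint space downwards
ROLES = ("surface", "tidemark", "cement_line", "trab_junction")

#: femorotibial compartments: lateral/medial femoral condyle, lateral/medial
#: tibial plateau
COMPARTMENTS = ("LFC", "MFC", "LTP", "MTP")

ZONES = ("Z1", "Z2", "Z3", "Z4")


@dataclass
class BoundaryTrace:
    """An ordered planar polyline in µm tagged with its anatomical role."""

    role: str
    vertices: np.ndarray  # (n, 2) float, µm

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown boundary role {self.role!r}; expected one of {ROLES}")
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 2:
            raise ValueError(f"trace {self.role!r} needs at least 2 vertices")


@dataclass
class SectionProfile:
    """Four boundary traces of one compartment section plus specimen metadata."""

    traces: dict[str, BoundaryTrace]
    compartment: str = "LFC"
    specimen: str = ""
    group: str = ""
    joint: str = ""

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )

    def trace(self, role: str) -> BoundaryTrace:
        try:
            return self.traces[role]
        except KeyError:
            raise KeyError(f"section profile is missing the {role!r} trace") from None


@dataclass
class ZonedROI:
    """A straight chord with four equal-width zones along it.

    ``origin`` and ``direction`` define the chord frame: a point p maps to
    u = (p - origin)·direction, v = (p - origin)·normal.  Zone k covers
    u in [u0 + k·W/4, u0 + (k+1)·W/4].
    """

    origin: np.ndarray  # (2,) µm
    direction: np.ndarray  # (2,) unit vector along the chord
    u0: float  # chord-frame start of the common support, µm
    width: float  # total ROI width W, µm

    @property
    def normal(self) -> np.ndarray:
        dx, dy = self.direction
        return np.array([-dy, dx])

    @property
    def zone_width(self) -> float:
        return self.width / 4.0

    def zone_bounds(self, zone: int) -> tuple[float, float]:
        """u-interval of zone index 0..3."""
        w = self.zone_width
        return self.u0 + zone * w, self.u0 + (zone + 1) * w

    def project(self, vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (u, v) chord-frame coordinates of the given points."""
        rel = np.asarray(vertices, dtype=float) - self.origin
        return rel @ self.direction, rel @ self.normal


@dataclass
class ThicknessResult:
    """Per-zone mean layer thicknesses in µm (NaN marks unmeasurable zones)."""

    ncg_th: np.ndarray  # (4,)
    ccg_th: np.ndarray
    cg_th: np.ndarray
    sb_th: np.ndarray
    n_rays_used: np.ndarray  # (4,) int
    n_rays_excluded: np.ndarray  # (4,) int

    def as_records(self) -> list[dict]:
        out = []
        for name, arr in (
            ("nCg.Th", self.ncg_th),
            ("cCg.Th", self.ccg_th),
            ("Cg.Th", self.cg_th),
            ("SB.Th", self.sb_th),
        ):
            for z, v in zip(ZONES, arr):
                out.append({"zone": z, "parameter": name, "value": float(v)})
        return out


@dataclass
class FibrillationResult:
    """Per-zone fibrillation index with the underlying lengths."""

    fi: np.ndarray  # (4,) dimensionless, >= 1
    arclength_um: np.ndarray  # (4,) L
    zone_width_um: np.ndarray  # (4,) W

    @property
    def excess_um(self) -> np.ndarray:
        """Secondary output: the literal surface excess length L - W per zone."""
        return self.arclength_um - self.zone_width_um

    def as_records(self) -> list[dict]:
        return [
            {"zone": z, "parameter": "FI", "value": float(v)}
            for z, v in zip(ZONES, self.fi)
        ]


def _projected_uv(roi: ZonedROI, trace: BoundaryTrace) -> tuple[np.ndarray, np.ndarray]:
    u, v = roi.project(trace.vertices)
    if np.any(np.diff(u) <= 0):
        raise ValueError(
            f"trace {trace.role!r} is not strictly increasing along the ROI chord"
        )
    return u, v


def define_roi(profile: SectionProfile, n_sampling_steps: int = 4) -> ZonedROI:
    """Build the zoned ROI chord from the surface endpoints.

    The chord joins the first and last surface vertex; its extent is then
    restricted to the common u-support of all four traces and split into four
    equal zones.  Rejects supports narrower than ``n_sampling_steps`` median
    vertex spacings.
    """
    for role in ROLES:
        profile.trace(role)  # raises naming the missing role
    surf = profile.trace("surface").vertices
    origin = surf[0].astype(float)
    chord = surf[-1] - surf[0]
    length = float(np.hypot(*chord))
    if length <= 0:
        raise ValueError("surface endpoints coincide; cannot define the ROI chord")
    direction = chord / length
    roi = ZonedROI(origin=origin, direction=direction, u0=0.0, width=length)

    lo, hi = -np.inf, np.inf
    for role in ROLES:
        u, _ = _projected_uv(roi, profile.trace(role))
        lo, hi = max(lo, u[0]), min(hi, u[-1])
    step = float(np.median(np.diff(roi.project(surf)[0])))
    if hi - lo < n_sampling_steps * step:
        raise ValueError(
            f"common trace support [{lo:.1f}, {hi:.1f}] µm is narrower than "
            f"{n_sampling_steps} sampling steps"
        )
    roi.u0, roi.width = lo, hi - lo
    return roi


_PAIR = {"nCg.Th": ("surface", "tidemark"),
         "cCg.Th": ("tidemark", "cement_line"),
         "SB.Th": ("cement_line", "trab_junction")}

_ORDER = {r: i for i, r in enumerate(ROLES)}


def mean_thickness(
    profile: SectionProfile,
    upper_role: str,
    lower_role: str,
    roi: ZonedROI | None = None,
    n_rays: int = 100,
    max_excluded_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-zone mean distance between two boundaries along chord-normal rays.

    ``n_rays`` rays per zone are placed at midpoint-rule u positions; each ray
    length is the difference of the linearly interpolated v-coordinates of the
    two polylines.  Rays falling outside either trace's u-support intersect
    only one boundary and are excluded (counted).  A zone with more than
    ``max_excluded_frac`` of its rays excluded is flagged unmeasurable (NaN).

    Returns ``(means, n_used, n_excluded)``, each of shape (4,).
    """
    if _ORDER[upper_role] >= _ORDER[lower_role]:
        raise ValueError(f"{upper_role!r} is not above {lower_role!r}")
    if roi is None:
        roi = define_roi(profile)
    uu, vu = _projected_uv(roi, profile.trace(upper_role))
    ul, vl = _projected_uv(roi, profile.trace(lower_role))

    means = np.full(4, np.nan)
    used = np.zeros(4, dtype=int)
    excl = np.zeros(4, dtype=int)
    for z in range(4):
        a, b = roi.zone_bounds(z)
        u = a + (np.arange(n_rays) + 0.5) * (b - a) / n_rays
        ok = (u >= uu[0]) & (u <= uu[-1]) & (u >= ul[0]) & (u <= ul[-1])
        used[z] = int(ok.sum())
        excl[z] = n_rays - used[z]
        if used[z] == 0 or excl[z] > max_excluded_frac * n_rays:
            warnings.warn(
                f"zone Z{z + 1}: {excl[z]}/{n_rays} rays excluded; "
                f"{upper_role}-{lower_role} thickness flagged unmeasurable",
                stacklevel=2,
            )
            continue
        d = np.interp(u[ok], uu, vu) - np.interp(u[ok], ul, vl)
        means[z] = float(d.mean())
    return means, used, excl


def total_cartilage_thickness(ncg: np.ndarray | float, ccg: np.ndarray | float):
    """Total cartilage thickness: exact sum of the two layers (NaN propagates)."""
    return np.asarray(ncg, dtype=float) + np.asarray(ccg, dtype=float)


def fibrillation_index(profile: SectionProfile, roi: ZonedROI | None = None) -> FibrillationResult:
    """Fibrillation index per zone: surface arclength over zone chord width.

    The surface polyline is clipped to each zone in the chord frame (with
    interpolated endpoints), its arclength L summed, and FI = L / W returned.
    FI >= 1 always, with equality only for a straight surface.
    """
    if roi is None:
        roi = define_roi(profile)
    u, v = _projected_uv(roi, profile.trace("surface"))
    fi = np.full(4, np.nan)
    arclen = np.full(4, np.nan)
    widths = np.full(4, np.nan)
    for z in range(4):
        a, b = roi.zone_bounds(z)
        w = b - a
        if w <= 0:
            raise ValueError(f"zone Z{z + 1} has zero chord width")
        lo, hi = max(a, u[0]), min(b, u[-1])
        if hi <= lo:
            warnings.warn(f"surface trace does not cover zone Z{z + 1}", stacklevel=2)
            continue
        inside = (u > lo) & (u < hi)
        uc = np.concatenate(([lo], u[inside], [hi]))
        vc = np.concatenate(([np.interp(lo, u, v)], v[inside], [np.interp(hi, u, v)]))
        arclen[z] = float(np.hypot(np.diff(uc), np.diff(vc)).sum())
        widths[z] = w
        fi[z] = arclen[z] / w
    return FibrillationResult(fi=fi, arclength_um=arclen, zone_width_um=widths)


def measure_section(
    profile: SectionProfile,
    roi: ZonedROI | None = None,
    n_rays: int = 100,
) -> tuple[ThicknessResult, FibrillationResult]:
    """All four thickness parameters plus FI for one section.

    nCg.Th, cCg.Th and SB.Th share the same ray positions, and Cg.Th is the
    exact sum nCg.Th + cCg.Th, so layer additivity holds to machine precision.
    """
    if roi is None:
        roi = define_roi(profile)
    ncg, used_n, excl_n = mean_thickness(profile, "surface", "tidemark", roi, n_rays)
    ccg, used_c, excl_c = mean_thickness(profile, "tidemark", "cement_line", roi, n_rays)
    sb, used_s, excl_s = mean_thickness(profile, "cement_line", "trab_junction", roi, n_rays)
    thick = ThicknessResult(
        ncg_th=ncg,
        ccg_th=ccg,
        cg_th=total_cartilage_thickness(ncg, ccg),
        sb_th=sb,
        n_rays_used=np.minimum(np.minimum(used_n, used_c), used_s),
        n_rays_excluded=np.maximum(np.maximum(excl_n, excl_c), excl_s),
    )
    return thick, fibrillation_index(profile, roi)
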