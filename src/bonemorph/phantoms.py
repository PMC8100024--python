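"""Synthetic inputs with known ground truth for every measurement stage.

Three generators:

* section phantoms — four boundary polylines (surface with sinusoidal
  undulation plus optional Gaussian roughness over flat deeper layers) whose
  per-zone layer thicknesses and fibrillation index are computed analytically
  by fine-step quadrature of the generating functions, never from the emitted
  polylines;
* trabecular phantoms — 2D rasters and 3D voxel volumes of parallel plates,
  axis-aligned rod lattices, or thresholded Gaussian random fields, with
  closed-form bone fraction / thickness / spacing ground truth;
* synthetic cohorts — long-format measurement tables drawn per cell from the
  reference means ± SDs of the rabbit knee-OA study design (three groups of
  eight animals, operated OA joint vs contralateral healthy HT joint, four
  femorotibial compartments, four zones), truncated at zero because every
  measured quantity is positive.

All randomness flows through the explicit per-spec seed; identical specs
yield bit-identical outputs.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cartilage import BoundaryTrace, SectionProfile, ZonedROI
from .trab2d import TrabMask2D
from .trab3d import TrabVolume3D

__all__ = [
    "SectionPhantomSpec",
    "SectionGroundTruth",
    "TrabPhantomSpec",
    "TrabGroundTruth",
    "CohortSpec",
    "gen_section_phantom",
    "gen_trab_phantom_2d",
    "gen_trab_phantom_3d",
    "gen_cohort",
    "default_parameter_table",
    "parameter_table_to_map",
]

GROUPS = ("SHAM", "CONT", "RIS")
JOINTS = ("OA", "HT")
COMPARTMENTS = ("LFC", "MFC", "LTP", "MTP")
ZONES = ("Z1", "Z2", "Z3", "Z4")
ZONE_PARAMS = ("nCg.Th", "cCg.Th", "Cg.Th", "SB.Th", "FI")
SITE_PARAMS = ("Tb.A", "Tb.Th", "Tb.Sp", "Tb.N")


# --------------------------------------------------------------------------
# section phantoms
# --------------------------------------------------------------------------

@dataclass
class SectionPhantomSpec:
    """Geometry of a synthetic traced section, all lengths in µm.

    ``layer_means`` holds the nominal thickness of the uncalcified cartilage
    ("nCg"), calcified cartilage ("cCg") and subchondral plate ("SB");
    defaults are in the range measured on rabbit femorotibial compartments.
    The articular surface undulates as a sinusoid of the given amplitude and
    wavelength; every boundary additionally receives seeded band-limited
    Gaussian roughness of SD ``boundary_noise_sd`` with wavelengths drawn
    from ``noise_wavelength_range``.
    """

    roi_width: float = 4000.0
    layer_means: dict = field(default_factory=lambda: {"nCg": 400.0, "cCg": 150.0, "SB": 350.0})
    undulation_amplitude: float = 10.0
    undulation_wavelength: float = 250.0
    boundary_noise_sd: float = 2.0
    noise_wavelength_range: tuple = (50.0, 200.0)
    noise_n_modes: int = 32
    sampling_step: float = 1.0
    seed: int = 0
    compartment: str = "LFC"

    def __post_init__(self) -> None:
        for key in ("nCg", "cCg", "SB"):
            if key not in self.layer_means:
                raise ValueError(f"layer_means is missing {key!r}")
            if self.layer_means[key] <= 0:
                raise ValueError(f"layer mean {key!r} must be positive")
        if self.roi_width <= 0 or self.sampling_step <= 0:
            raise ValueError("roi_width and sampling_step must be positive")
        if self.undulation_amplitude < 0 or self.boundary_noise_sd < 0:
            raise ValueError("amplitude and noise sd must be non-negative")
        if self.undulation_amplitude > 0 and self.undulation_wavelength <= 2 * self.sampling_step:
            raise ValueError("undulation_wavelength must exceed 2x the sampling step")
        if self.undulation_amplitude >= self.layer_means["nCg"]:
            raise ValueError("undulation amplitude must be smaller than the nCg layer")
        if self.boundary_noise_sd > 0 and min(self.noise_wavelength_range) <= 2 * self.sampling_step:
            raise ValueError("roughness wavelengths must exceed 2x the sampling step")


@dataclass
class SectionGroundTruth:
    """Exact per-zone values from quadrature of the generating functions."""

    ncg_th: np.ndarray  # (4,) µm
    ccg_th: np.ndarray
    cg_th: np.ndarray
    sb_th: np.ndarray
    fi: np.ndarray  # (4,) dimensionless


def _roughness_fn(rng: np.random.Generator, sd: float, wl_range: tuple, n_modes: int):
    """Band-limited random roughness with analytic derivative, SD ``sd``.

    Superposition of cosine modes with random wavelengths and phases; being a
    closed-form generating function, it enters the ground-truth quadrature
    exactly (traced boundaries are smooth at the µm scale, so white vertex
    noise would be unphysical and would blow up the surface arclength).
    """
    if sd == 0:
        return (lambda x: np.zeros_like(np.asarray(x, float)),) * 2
    lams = rng.uniform(*wl_range, size=n_modes)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    amp = sd * np.sqrt(2.0 / n_modes)
    ks = 2.0 * np.pi / lams

    def r(x):
        x = np.asarray(x, dtype=float)
        return amp * np.cos(np.multiply.outer(x, ks) + phis).sum(axis=-1)

    def dr(x):
        x = np.asarray(x, dtype=float)
        return -amp * (ks * np.sin(np.multiply.outer(x, ks) + phis)).sum(axis=-1)

    return r, dr


def _boundary_fns(spec: SectionPhantomSpec, rng: np.random.Generator, noise_sd: float):
    """Generating functions (y, dy) for all four boundaries."""
    base = spec.layer_means["SB"] + spec.layer_means["cCg"] + spec.layer_means["nCg"]
    a, lam = spec.undulation_amplitude, spec.undulation_wavelength
    k = 2.0 * np.pi / lam if a > 0 else 0.0
    levels = {
        "tidemark": spec.layer_means["SB"] + spec.layer_means["cCg"],
        "cement_line": spec.layer_means["SB"],
        "trab_junction": 0.0,
    }
    fns = {}
    rs, drs = _roughness_fn(rng, noise_sd, spec.noise_wavelength_range, spec.noise_n_modes)
    fns["surface"] = (
        lambda x: base + a * np.sin(k * np.asarray(x, float)) + rs(x),
        lambda x: a * k * np.cos(k * np.asarray(x, float)) + drs(x),
    )
    for role, level in levels.items():
        rr, drr = _roughness_fn(rng, noise_sd, spec.noise_wavelength_range, spec.noise_n_modes)
        fns[role] = (
            (lambda x, lv=level, rr=rr: lv + rr(x)),
            (lambda x, drr=drr: drr(x)),
        )
    return fns


def _section_truth(spec: SectionPhantomSpec, fns: dict, refine: int = 16) -> SectionGroundTruth:
    """Fine-step quadrature of the generating functions in the chord frame."""
    w = spec.roi_width
    y_s, dy_s = fns["surface"]
    p0 = np.array([0.0, float(y_s(0.0))])
    p1 = np.array([w, float(y_s(w))])
    direction = (p1 - p0) / np.hypot(*(p1 - p0))
    c, s = direction

    def to_uv(x, y):
        return (x - p0[0]) * c + (y - p0[1]) * s, -(x - p0[0]) * s + (y - p0[1]) * c

    x = np.linspace(0.0, w, int(w / spec.sampling_step) * refine + 1)
    uv = {role: to_uv(x, fn(x)) for role, (fn, _) in fns.items()}
    lo = max(u[0] for u, _ in uv.values())
    hi = min(u[-1] for u, _ in uv.values())
    width = hi - lo

    # cumulative surface arclength via the analytic derivative (midpoint rule)
    arc = np.concatenate(([0.0], np.cumsum(
        np.sqrt(1.0 + dy_s(0.5 * (x[1:] + x[:-1])) ** 2) * np.diff(x))))
    u_s = uv["surface"][0]

    ncg = np.empty(4)
    ccg = np.empty(4)
    sb = np.empty(4)
    fi = np.empty(4)
    for z in range(4):
        a_u = lo + z * width / 4.0
        b_u = lo + (z + 1) * width / 4.0
        uq = np.linspace(a_u, b_u, 4096)
        vs = np.interp(uq, *uv["surface"])
        vt = np.interp(uq, *uv["tidemark"])
        vc = np.interp(uq, *uv["cement_line"])
        vb = np.interp(uq, *uv["trab_junction"])
        ncg[z] = np.trapezoid(vs - vt, uq) / (b_u - a_u)
        ccg[z] = np.trapezoid(vt - vc, uq) / (b_u - a_u)
        sb[z] = np.trapezoid(vc - vb, uq) / (b_u - a_u)
        length = np.interp(b_u, u_s, arc) - np.interp(a_u, u_s, arc)
        fi[z] = length / (b_u - a_u)
    return SectionGroundTruth(ncg_th=ncg, ccg_th=ccg, cg_th=ncg + ccg, sb_th=sb, fi=fi)


def gen_section_phantom(spec: SectionPhantomSpec) -> tuple[SectionProfile, SectionGroundTruth]:
    """Generate one traced section plus its quadrature ground truth.

    The ground truth is computed from the generating functions (sinusoid plus
    band-limited roughness) by fine-step quadrature, never from the emitted
    polylines.  If the drawn roughness makes adjacent boundaries cross, the
    phantom is regenerated with the roughness SD halved, with a warning.
    """
    x = np.arange(0.0, spec.roi_width + spec.sampling_step / 2.0, spec.sampling_step)
    x_dense = np.arange(0.0, spec.roi_width + spec.sampling_step / 8.0, spec.sampling_step / 4.0)
    rng = np.random.default_rng(spec.seed)
    noise_sd = spec.boundary_noise_sd
    order = ["surface", "tidemark", "cement_line", "trab_junction"]
    for _ in range(20):
        fns = _boundary_fns(spec, rng, noise_sd)
        dense = {r: fns[r][0](x_dense) for r in order}
        gaps_ok = all(
            np.all(dense[a] - dense[b] > 0) for a, b in zip(order, order[1:])
        )
        if gaps_ok:
            traces = {r: BoundaryTrace(r, np.column_stack([x, fns[r][0](x)])) for r in order}
            profile = SectionProfile(
                traces=traces,
                compartment=spec.compartment,
                specimen=f"phantom-{spec.seed}",
            )
            return profile, _section_truth(spec, fns)
        noise_sd /= 2.0
        warnings.warn(
            f"boundaries crossed after roughness injection; retrying with sd={noise_sd:g} µm",
            stacklevel=2,
        )
    raise ValueError("could not generate non-crossing boundaries for this spec")


# --------------------------------------------------------------------------
# trabecular phantoms
# --------------------------------------------------------------------------

@dataclass
class TrabPhantomSpec:
    """Trabecular phantom geometry, all lengths in mm.

    kinds:
      * ``plates`` — parallel plates of thickness ``thickness`` separated by
        ``spacing``, normal tilted ``orientation_deg`` from the stacking axis;
      * ``rods`` — axis-aligned cylinders of radius ``rod_radius`` on a square
        lattice of pitch ``rod_pitch`` (3D only);
      * ``random_field`` — Gaussian random field of correlation length
        ``correlation_length`` thresholded at the quantile that yields
        ``target_fraction`` bone.
    """

    kind: str = "plates"
    domain_size: tuple = (2.0, 2.0, 2.0)
    pixel_size: float = 0.01
    seed: int = 0
    thickness: float = 0.15
    spacing: float = 0.30
    orientation_deg: float = 0.0
    rod_radius: float = 0.1
    rod_pitch: float = 0.5
    target_fraction: float = 0.5
    correlation_length: float = 0.15
    site: str = "tibia"

    def __post_init__(self) -> None:
        if self.kind not in ("plates", "rods", "random_field", "solid"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.pixel_size <= 0 or any(d <= 0 for d in self.domain_size):
            raise ValueError("pixel size and domain size must be positive")
        if self.kind == "plates":
            if self.thickness <= 0 or self.spacing < 0:
                raise ValueError("plate thickness must be > 0 and spacing >= 0")
            if self.pixel_size >= self.thickness:
                raise ValueError("pixel size >= plate thickness: structure unresolvable")
            if self.pixel_size > self.thickness / 5.0:
                warnings.warn(
                    "pixel size coarser than thickness/5; analytic recovery will be degraded",
                    stacklevel=2,
                )
        if self.kind == "rods":
            if self.rod_radius <= 0 or self.rod_pitch < 2 * self.rod_radius:
                raise ValueError("rods need radius > 0 and pitch >= diameter")
            if self.pixel_size >= 2 * self.rod_radius:
                raise ValueError("pixel size >= rod diameter: structure unresolvable")
        if self.kind == "random_field" and not 0.0 < self.target_fraction < 1.0:
            raise ValueError("target_fraction must lie in (0, 1)")


@dataclass
class TrabGroundTruth:
    """Closed-form truth from the generating parameters (NaN when undefined)."""

    bv_tv_pct: float
    tb_th_mm: float = float("nan")
    tb_sp_mm: float = float("nan")
    tb_n_per_mm: float = float("nan")


def _phantom_truth(spec: TrabPhantomSpec) -> TrabGroundTruth:
    if spec.kind == "solid":
        return TrabGroundTruth(bv_tv_pct=100.0)
    if spec.kind == "plates":
        t, s = spec.thickness, spec.spacing
        return TrabGroundTruth(
            bv_tv_pct=100.0 * t / (t + s),
            tb_th_mm=t,
            tb_sp_mm=s,
            tb_n_per_mm=1.0 / (t + s),
        )
    if spec.kind == "rods":
        r, p = spec.rod_radius, spec.rod_pitch
        return TrabGroundTruth(
            bv_tv_pct=100.0 * np.pi * r ** 2 / p ** 2,
            tb_th_mm=2.0 * r,
            tb_n_per_mm=1.0 / p,
        )
    return TrabGroundTruth(bv_tv_pct=100.0 * spec.target_fraction)


def _random_field(shape: tuple, sigma_px: float, frac: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fieldv = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    return fieldv >= np.quantile(fieldv, 1.0 - frac)


def gen_trab_phantom_2d(spec: TrabPhantomSpec) -> tuple[TrabMask2D, TrabGroundTruth]:
    """Render a 2D trabecular raster by pixel-centre sampling."""
    if len(spec.domain_size) != 2:
        raise ValueError("2D phantom needs a 2-element domain_size")
    w, hgt = spec.domain_size
    h = spec.pixel_size
    nx, ny = int(round(w / h)), int(round(hgt / h))
    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xs, ys)
    if spec.kind == "solid":
        mask = np.ones((ny, nx), dtype=bool)
    elif spec.kind == "plates":
        th = np.deg2rad(spec.orientation_deg)
        d = X * np.cos(th) + Y * np.sin(th)
        # pattern starts with half a gap so no plate is cut by the domain face
        mask = np.mod(d - spec.spacing / 2.0, spec.thickness + spec.spacing) < spec.thickness
    elif spec.kind == "random_field":
        mask = _random_field((ny, nx), spec.correlation_length / h,
                             spec.target_fraction, spec.seed)
    else:
        raise ValueError(f"kind {spec.kind!r} has no 2D renderer")
    return TrabMask2D(mask, h, spec.site), _phantom_truth(spec)


def gen_trab_phantom_3d(spec: TrabPhantomSpec) -> tuple[TrabVolume3D, TrabGroundTruth]:
    """Render a 3D trabecular voxel volume by voxel-centre sampling."""
    if len(spec.domain_size) != 3:
        raise ValueError("3D phantom needs a 3-element domain_size")
    wx, wy, wz = spec.domain_size
    h = spec.pixel_size
    nx, ny, nz = (int(round(d / h)) for d in (wx, wy, wz))
    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    zs = (np.arange(nz) + 0.5) * h
    if spec.kind == "solid":
        vol = np.ones((nz, ny, nx), dtype=bool)
    elif spec.kind == "plates":
        th = np.deg2rad(spec.orientation_deg)
        # plate normal tilted from z towards x
        d = (np.sin(th) * xs[None, None, :]
             + np.cos(th) * zs[:, None, None]
             + 0.0 * ys[None, :, None])
        # half-gap phase: plates never touch the z=0 face of the domain
        vol = np.mod(d - spec.spacing / 2.0, spec.thickness + spec.spacing) < spec.thickness
    elif spec.kind == "rods":
        p, r = spec.rod_pitch, spec.rod_radius
        dx = np.mod(xs, p) - p / 2.0
        dy = np.mod(ys, p) - p / 2.0
        disc = (dx[None, :] ** 2 + dy[:, None] ** 2) <= r ** 2
        vol = np.broadcast_to(disc[None, :, :], (nz, ny, nx)).copy()
    elif spec.kind == "random_field":
        vol = _random_field((nz, ny, nx), spec.correlation_length / h,
                            spec.target_fraction, spec.seed)
    else:
        raise ValueError(f"kind {spec.kind!r} has no 3D renderer")
    return TrabVolume3D(vol, h, site=spec.site), _phantom_truth(spec)


# --------------------------------------------------------------------------
# synthetic cohorts
# --------------------------------------------------------------------------

def default_parameter_table() -> pd.DataFrame:
    """Reference per-cell (mean, sd) table of the rabbit knee-OA study.

    One row per (group, joint, compartment, zone, parameter); zone "ALL"
    marks site-level 2D trabecular parameters.  Thickness values in µm,
    Tb.Th/Tb.Sp in mm, Tb.A in %, FI dimensionless.
    """
    with importlib.resources.files("bonemorph.data").joinpath(
        "reference_cohort_params.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def parameter_table_to_map(table: pd.DataFrame) -> dict:
    """Index a parameter table by (group, joint, compartment, zone, parameter)."""
    return {
        (r.group, r.joint, r.compartment, r.zone, r.parameter): (r.mean, r.sd)
        for r in table.itertuples()
    }


@dataclass
class CohortSpec:
    """Design of a synthetic cohort mirroring the reference study.

    Three treatment groups of eight animals by default (the SHAM group can be
    reduced to seven to reflect one animal lost during the study), each
    animal contributing an operated OA joint and a contralateral healthy HT
    joint, measured in four compartments.  ``parameter_means_sds`` maps
    (group, joint, compartment, zone, parameter) to (mean, sd); when None the
    reference table is used.  ``between_zone_corr`` is kept configurable (the
    reference tables carry no covariance information) and defaults to 0.
    """

    groups: tuple = GROUPS
    n_per_group: dict | int = 8
    compartments: tuple = COMPARTMENTS
    zones: tuple = ZONES
    parameter_means_sds: dict | None = None
    zone_parameters: tuple = ZONE_PARAMS
    site_parameters: tuple = SITE_PARAMS
    between_zone_corr: float = 0.0
    seed: int = 0

    def group_sizes(self) -> dict:
        if isinstance(self.n_per_group, int):
            return {g: self.n_per_group for g in self.groups}
        return dict(self.n_per_group)


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerate sd=0 returns the mean."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a long-format synthetic cohort table from per-cell (mean, sd).

    One record per specimen x joint x compartment x zone x parameter (zone
    "ALL" for the site-level 2D trabecular parameters), each drawn
    independently from a zero-truncated normal.  Raises ``KeyError`` naming
    the first missing cell of the parameterization.
    """
    params = spec.parameter_means_sds
    if params is None:
        params = parameter_table_to_map(default_parameter_table())
    rng = np.random.default_rng(spec.seed)
    sizes = spec.group_sizes()
    records = []
    for group in spec.groups:
        for i in range(sizes[group]):
            specimen = f"{group}-{i + 1:02d}"
            for joint in JOINTS:
                for comp in spec.compartments:
                    cells = [(z, p) for p in spec.zone_parameters for z in spec.zones]
                    cells += [("ALL", p) for p in spec.site_parameters]
                    for zone, param in cells:
                        key = (group, joint, comp, zone, param)
                        if key not in params:
                            raise KeyError(
                                f"no (mean, sd) configured for cell {key}"
                            )
                        mean, sd = params[key]
                        value = float(_draw_truncnorm(rng, mean, sd, 1)[0])
                        records.append(
                            {
                                "specimen": specimen,
                                "group": group,
                                "joint": joint,
                                "compartment": comp,
                                "zone": zone,
                                "parameter": param,
                                "value": value,
                            }
                        )
    return pd.DataFrame.from_records(records)
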