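"""End-to-end orchestration: phantoms → measurement → statistics.

A single :class:`RunConfig` (serializable to YAML) drives four stages:

1. ``sections`` — synthetic traced sections with an undulation-amplitude
   sweep, measured for zoned thickness and fibrillation; measured values are
   written next to their quadrature ground truth.
2. ``trabecular`` — 2D and 3D plate phantoms measured with the stereology
   and micro-CT operators, again against closed-form truth.
3. ``cohort`` — a table-driven synthetic cohort with the reference study
   design, followed by the full statistics pass: per-cell OA vs HT
   comparisons within each group, and three-group comparisons within each
   joint with post-hoc contrasts.
4. ``coupled`` — random-field volumes measured both in 3D (central VOI) and
   in 2D (central-plane section), feeding the 2D↔3D Pearson correlation
   table.

Every stage seeds its randomness from the single config seed; a saved
config re-executes to byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from importlib.metadata import version as _dist_version

from . import io as bio
from .cartilage import measure_section
from .phantoms import (
    COMPARTMENTS,
    GROUPS,
    JOINTS,
    CohortSpec,
    SectionPhantomSpec,
    TrabPhantomSpec,
    gen_cohort,
    gen_section_phantom,
    gen_trab_phantom_2d,
    gen_trab_phantom_3d,
)
from .stats import compare_k, compare_two, correlate_2d3d
from .trab2d import measure_mask
from .trab3d import CylVOI, central_plane_section, measure_voi

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "bonemorph-run"
    # sections stage
    n_sections: int = 8
    section_amplitude_range_um: tuple = (0.0, 30.0)
    section_wavelength_um: float = 250.0
    n_rays: int = 100
    sampling_step_um: float = 1.0
    # trabecular phantom stage
    plate_thickness_mm: float = 0.15
    plate_spacing_mm: float = 0.30
    voxel_size_mm: float = 0.0075
    pixel_size_mm: float = 0.005
    # cohort stage
    n_per_group: dict = field(default_factory=lambda: {"SHAM": 8, "CONT": 8, "RIS": 8})
    alpha: float = 0.05
    paired: bool = False
    # coupled 2D/3D stage
    n_coupled: int = 8
    coupled_voxel_mm: float = 0.02
    coupled_fraction_range: tuple = (0.3, 0.7)
    coupled_correlation_length_mm: float = 0.05

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["section_amplitude_range_um"] = list(d["section_amplitude_range_um"])
        d["coupled_fraction_range"] = list(d["coupled_fraction_range"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("section_amplitude_range_um", "coupled_fraction_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _stage_sections(cfg: RunConfig) -> pd.DataFrame:
    amps = np.linspace(*cfg.section_amplitude_range_um, cfg.n_sections)
    rows = []
    for i, amp in enumerate(amps):
        spec = SectionPhantomSpec(
            undulation_amplitude=float(amp),
            undulation_wavelength=cfg.section_wavelength_um,
            sampling_step=cfg.sampling_step_um,
            seed=cfg.seed * 1000 + i,
        )
        profile, truth = gen_section_phantom(spec)
        thick, fib = measure_section(profile, n_rays=cfg.n_rays)
        truths = {"nCg.Th": truth.ncg_th, "cCg.Th": truth.ccg_th,
                  "Cg.Th": truth.cg_th, "SB.Th": truth.sb_th, "FI": truth.fi}
        for rec_obj in (thick, fib):
            for rec in rec_obj.as_records():
                zi = int(rec["zone"][1]) - 1
                rows.append({
                    "specimen": profile.specimen, "amplitude_um": float(amp),
                    **rec, "truth": float(truths[rec["parameter"]][zi]),
                })
    return pd.DataFrame(rows)


def _stage_trabecular(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    # 1.8 mm = four full plate periods, so the closed-form Tb.A holds exactly
    spec2d = TrabPhantomSpec(
        kind="plates", domain_size=(1.8, 1.8), pixel_size=cfg.pixel_size_mm,
        thickness=cfg.plate_thickness_mm, spacing=cfg.plate_spacing_mm,
        orientation_deg=0.0, seed=cfg.seed,
    )
    mask, truth2d = gen_trab_phantom_2d(spec2d)
    res2d = measure_mask(mask)
    rows += [{"stage": "2d-plates", **r,
              "truth": {"Tb.A": truth2d.bv_tv_pct}.get(r["parameter"], np.nan)}
             for r in res2d.as_records()]

    # Depth of four full plate periods keeps the closed-form BV/TV exact;
    # the default 7.5 um voxel makes plate and gap an even voxel count, which
    # avoids the +-1 voxel parity bias of voxel-centre distance transforms.
    dom = 1.8
    spec3d = TrabPhantomSpec(
        kind="plates", domain_size=(dom / 2, dom / 2, dom), pixel_size=cfg.voxel_size_mm,
        thickness=cfg.plate_thickness_mm, spacing=cfg.plate_spacing_mm,
        orientation_deg=0.0, seed=cfg.seed, site="tibia",
    )
    vol, truth3d = gen_trab_phantom_3d(spec3d)
    from .trab3d import bv_tv, local_thickness, tb_n as _tbn
    bvtv = bv_tv(vol)
    tbth = local_thickness(vol, "bone")
    tbsp = local_thickness(vol, "marrow")
    truths = {"BV/TV": truth3d.bv_tv_pct, "Tb.Th": truth3d.tb_th_mm,
              "Tb.Sp": truth3d.tb_sp_mm, "Tb.N": truth3d.tb_n_per_mm}
    for name, val in (("BV/TV", bvtv), ("Tb.Th", tbth), ("Tb.Sp", tbsp),
                      ("Tb.N", _tbn(bvtv, tbth))):
        rows.append({"stage": "3d-plates", "parameter": name, "value": val,
                     "truth": truths[name]})
    return pd.DataFrame(rows)


def _stage_cohort(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    cohort = gen_cohort(CohortSpec(n_per_group=cfg.n_per_group, seed=cfg.seed))
    rows = []
    cells = cohort[["compartment", "zone", "parameter"]].drop_duplicates()
    for comp, zone, param in cells.itertuples(index=False):
        sub = cohort[(cohort.compartment == comp) & (cohort.zone == zone)
                     & (cohort.parameter == param)]
        # OA vs HT within each treatment group
        for group in GROUPS:
            a = sub[(sub.group == group) & (sub.joint == "OA")].value
            b = sub[(sub.group == group) & (sub.joint == "HT")].value
            res = compare_two(a, b, paired=cfg.paired, alpha=cfg.alpha)
            rows.append({"comparison": "OA-vs-HT", "group": group, "joint": "",
                         "compartment": comp, "zone": zone, "parameter": param,
                         "test": res.test, "statistic": res.statistic,
                         "p": res.p_value,
                         "significant": res.p_value < cfg.alpha})
        # SHAM / CONT / RIS within each joint
        for joint in JOINTS:
            groups = [sub[(sub.group == g) & (sub.joint == joint)].value
                      for g in GROUPS]
            res = compare_k(groups, labels=list(GROUPS), alpha=cfg.alpha)
            rows.append({"comparison": "3-group", "group": "", "joint": joint,
                         "compartment": comp, "zone": zone, "parameter": param,
                         "test": res.test, "statistic": res.statistic,
                         "p": res.p_value,
                         "significant": res.p_value < cfg.alpha})
    return cohort, pd.DataFrame(rows)


def _stage_coupled(cfg: RunConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed + 777)
    fracs = rng.uniform(*cfg.coupled_fraction_range, size=cfg.n_coupled)
    h = cfg.coupled_voxel_mm
    dom_xy = 2.7
    dom_z = 1.7
    rows = []
    for i, frac in enumerate(fracs):
        spec = TrabPhantomSpec(
            kind="random_field", domain_size=(dom_xy, dom_xy, dom_z),
            pixel_size=h, target_fraction=float(frac),
            correlation_length=cfg.coupled_correlation_length_mm,
            seed=cfg.seed * 1000 + i, site="tibia",
        )
        vol, _ = gen_trab_phantom_3d(spec)
        voi = CylVOI.for_site("tibia", (dom_xy / 2, dom_xy / 2, dom_z / 2))
        res3d = measure_voi(vol, voi)
        res2d = measure_mask(central_plane_section(vol, voi, "tibia"))
        vals3d = {"Tb.A": res3d.bv_tv_pct, "Tb.Th": res3d.tb_th_mm,
                  "Tb.Sp": res3d.tb_sp_mm, "Tb.N": res3d.tb_n_per_mm}
        vals2d = {"Tb.A": res2d.tb_a_pct, "Tb.Th": res2d.tb_th_mm,
                  "Tb.Sp": res2d.tb_sp_mm, "Tb.N": res2d.tb_n}
        for param in ("Tb.A", "Tb.Th", "Tb.Sp", "Tb.N"):
            rows.append({"specimen": f"coupled-{i:02d}", "parameter": param,
                         "value_2d": vals2d[param], "value_3d": vals3d[param]})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, returning the run directory.

    Writes ``sections.csv``, ``trabecular.csv``, ``cohort.csv``,
    ``stats.csv``, ``paired_2d3d.csv``, ``correlation.csv``, the echoed
    ``config.yaml`` and a ``run.json`` log (package version, seed, applied
    defaults, aggregated warnings per stage).  A stage failure aborts with
    the stage name; earlier outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: dict = {
        "package_version": _dist_version("bonemorph"),
        "seed": config.seed,
        "config": yaml.safe_load((out / "config.yaml").read_text()),
        "stages": {},
    }

    def run_stage(name, fn):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                log["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "run.json").write_text(json.dumps(log, indent=1))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log["stages"][name] = {
            "status": "ok",
            "warnings": sorted({str(w.message) for w in caught}),
        }
        return result

    sections = run_stage("sections", lambda: _stage_sections(config))
    bio.write_table(sections, out / "sections.csv")

    trab = run_stage("trabecular", lambda: _stage_trabecular(config))
    bio.write_table(trab, out / "trabecular.csv")

    cohort, stats_df = run_stage("cohort", lambda: _stage_cohort(config))
    bio.write_table(cohort, out / "cohort.csv")
    bio.write_table(stats_df, out / "stats.csv")

    paired = run_stage("coupled", lambda: _stage_coupled(config))
    bio.write_table(paired, out / "paired_2d3d.csv")
    bio.write_table(correlate_2d3d(paired), out / "correlation.csv")

    (out / "run.json").write_text(json.dumps(log, indent=1))
    return out
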