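"""Shared builders for synthetic sections and masks."""

from __future__ import annotations

import numpy as np
import pytest

from bonemorph.cartilage import BoundaryTrace, SectionProfile

# nominal layer stack used by the hand-built flat sections (µm)
LAYERS = {"nCg": 400.0, "cCg": 150.0, "SB": 350.0}


def flat_profile(width: float = 4000.0, step: float = 1.0, surface_y=None) -> SectionProfile:
    """Four parallel horizontal boundaries; optional custom surface heights."""
    x = np.arange(0.0, width + step / 2.0, step)
    base = LAYERS["SB"] + LAYERS["cCg"] + LAYERS["nCg"]
    ys = np.full_like(x, base) if surface_y is None else np.asarray(surface_y, float)
    levels = {
        "tidemark": LAYERS["SB"] + LAYERS["cCg"],
        "cement_line": LAYERS["SB"],
        "trab_junction": 0.0,
    }
    traces = {"surface": BoundaryTrace("surface", np.column_stack([x, ys]))}
    for role, level in levels.items():
        traces[role] = BoundaryTrace(role, np.column_stack([x, np.full_like(x, level)]))
    return SectionProfile(traces=traces, compartment="LFC", specimen="flat")


def transform_profile(profile: SectionProfile, angle_deg: float, shift) -> SectionProfile:
    """Rigidly rotate and translate every trace of a profile."""
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    traces = {
        role: BoundaryTrace(role, trace.vertices @ rot.T + np.asarray(shift, float))
        for role, trace in profile.traces.items()
    }
    return SectionProfile(
        traces=traces,
        compartment=profile.compartment,
        specimen=profile.specimen,
    )


@pytest.fixture()
def flat_section() -> SectionProfile:
    return flat_profile()
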