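import numpy as np
import pandas as pd
import pytest

from bonemorph.cartilage import measure_section
from bonemorph.phantoms import (
    COMPARTMENTS,
    GROUPS,
    ZONES,
    CohortSpec,
    SectionPhantomSpec,
    TrabPhantomSpec,
    default_parameter_table,
    gen_cohort,
    gen_section_phantom,
    gen_trab_phantom_2d,
    gen_trab_phantom_3d,
    parameter_table_to_map,
)


# ------------------------------------------------------------------ sections

def test_section_phantom_is_deterministic():
    spec = SectionPhantomSpec(seed=11)
    p1, t1 = gen_section_phantom(spec)
    p2, t2 = gen_section_phantom(spec)
    for role in p1.traces:
        assert np.array_equal(p1.traces[role].vertices, p2.traces[role].vertices)
    assert np.array_equal(t1.fi, t2.fi)
    assert np.array_equal(t1.ncg_th, t2.ncg_th)


def test_section_truth_independent_of_emitted_polylines():
    # truth for a pure sinusoid has a closed form; quadrature must match it
    a, lam, w = 25.0, 250.0, 4000.0
    spec = SectionPhantomSpec(
        roi_width=w, undulation_amplitude=a, undulation_wavelength=lam,
        boundary_noise_sd=0.0,
    )
    _, truth = gen_section_phantom(spec)
    k = 2 * np.pi / lam
    x = np.linspace(0, w / 4, 200001)
    fi_zone1 = np.trapezoid(np.sqrt(1 + (a * k * np.cos(k * x)) ** 2), x) / (w / 4)
    assert truth.fi[0] == pytest.approx(fi_zone1, rel=1e-6)
    # sinusoid averages to the nominal layer mean over whole zones (w = 16 lam)
    assert truth.ncg_th == pytest.approx(400.0, abs=1e-6)


def test_measured_section_matches_truth():
    profile, truth = gen_section_phantom(SectionPhantomSpec(seed=2))
    thick, fib = measure_section(profile)
    assert thick.ncg_th == pytest.approx(truth.ncg_th, rel=1e-3)
    assert thick.sb_th == pytest.approx(truth.sb_th, rel=1e-3)
    assert fib.fi == pytest.approx(truth.fi, abs=1e-4)


def test_crossing_boundaries_retry_with_halved_noise():
    spec = SectionPhantomSpec(boundary_noise_sd=120.0)  # will cross cCg (150 µm)
    with pytest.warns(UserWarning, match="retrying"):
        profile, truth = gen_section_phantom(spec)
    order = ["surface", "tidemark", "cement_line", "trab_junction"]
    ys = [profile.traces[r].vertices[:, 1] for r in order]
    for upper, lower in zip(ys, ys[1:]):
        assert np.all(upper > lower)


@pytest.mark.parametrize("kwargs", [
    {"roi_width": -1.0},
    {"undulation_amplitude": -2.0},
    {"undulation_amplitude": 500.0},  # exceeds the nCg layer
    {"undulation_wavelength": 1.5, "sampling_step": 1.0},
    {"layer_means": {"nCg": 400.0, "cCg": 150.0}},
    {"noise_wavelength_range": (1.0, 2.0)},
])
def test_section_spec_validation(kwargs):
    with pytest.raises(ValueError):
        SectionPhantomSpec(**kwargs)


# ---------------------------------------------------------------- trabecular

def test_plate_phantom_2d_exact_fraction_on_integer_periods():
    mask, truth = gen_trab_phantom_2d(
        TrabPhantomSpec(kind="plates", domain_size=(1.8, 1.8), pixel_size=0.005,
                        thickness=0.15, spacing=0.30)
    )
    assert 100.0 * mask.mask.mean() == pytest.approx(truth.bv_tv_pct, abs=1e-9)
    assert truth.tb_n_per_mm == pytest.approx(1.0 / 0.45)


def test_plate_phantom_3d_exact_fraction_on_integer_periods():
    vol, truth = gen_trab_phantom_3d(
        TrabPhantomSpec(kind="plates", domain_size=(0.45, 0.45, 0.9), pixel_size=0.0075,
                        thickness=0.15, spacing=0.30)
    )
    assert 100.0 * vol.volume.mean() == pytest.approx(truth.bv_tv_pct, abs=1e-9)
    # half-gap phase: no plate touches the z faces of the domain
    assert not vol.volume[0].any() and not vol.volume[-1].any()


def test_rod_phantom_fraction_and_truth():
    vol, truth = gen_trab_phantom_3d(
        TrabPhantomSpec(kind="rods", domain_size=(1.0, 1.0, 0.5), pixel_size=0.005,
                        rod_radius=0.1, rod_pitch=0.5)
    )
    assert truth.bv_tv_pct == pytest.approx(100 * np.pi * 0.01 / 0.25)
    assert 100.0 * vol.volume.mean() == pytest.approx(truth.bv_tv_pct, rel=0.02)
    assert truth.tb_th_mm == 0.2 and truth.tb_n_per_mm == 2.0


def test_random_field_hits_target_fraction():
    for frac in (0.2, 0.5, 0.65):
        vol, truth = gen_trab_phantom_3d(
            TrabPhantomSpec(kind="random_field", domain_size=(1.0, 1.0, 1.0),
                            pixel_size=0.02, target_fraction=frac, seed=9)
        )
        assert vol.volume.mean() == pytest.approx(frac, abs=0.002)
        assert truth.bv_tv_pct == pytest.approx(100 * frac)


def test_trab_phantom_determinism_and_dimension_checks():
    spec = TrabPhantomSpec(kind="random_field", domain_size=(0.5, 0.5), pixel_size=0.01)
    m1, _ = gen_trab_phantom_2d(spec)
    m2, _ = gen_trab_phantom_2d(spec)
    assert np.array_equal(m1.mask, m2.mask)
    with pytest.raises(ValueError, match="3-element"):
        gen_trab_phantom_3d(spec)
    with pytest.raises(ValueError, match="2-element"):
        gen_trab_phantom_2d(TrabPhantomSpec(domain_size=(1, 1, 1)))
    with pytest.raises(ValueError, match="no 2D renderer"):
        gen_trab_phantom_2d(TrabPhantomSpec(kind="rods", domain_size=(1, 1)))


@pytest.mark.parametrize("kwargs", [
    {"kind": "spheres"},
    {"kind": "plates", "pixel_size": 0.2},  # coarser than the plate
    {"kind": "rods", "rod_pitch": 0.1, "rod_radius": 0.1},
    {"kind": "random_field", "target_fraction": 0.0},
    {"pixel_size": -0.01},
])
def test_trab_spec_validation(kwargs):
    with pytest.raises(ValueError):
        TrabPhantomSpec(**kwargs)


def test_coarse_pixel_warns():
    with pytest.warns(UserWarning, match="coarser"):
        TrabPhantomSpec(kind="plates", thickness=0.15, pixel_size=0.05)


# -------------------------------------------------------------------- cohort

def test_reference_table_shape_and_spot_values():
    table = default_parameter_table()
    assert len(table) == 576
    cell = table[(table.group == "CONT") & (table.joint == "OA")
                 & (table.compartment == "MTP") & (table.zone == "Z2")
                 & (table.parameter == "Cg.Th")]
    assert cell.iloc[0]["mean"] == pytest.approx(1024.82)
    assert cell.iloc[0]["sd"] == pytest.approx(97.94)
    cell = table[(table.group == "CONT") & (table.joint == "OA")
                 & (table.compartment == "LTP") & (table.zone == "ALL")
                 & (table.parameter == "Tb.A")]
    assert cell.iloc[0]["mean"] == pytest.approx(48.99)


def test_cohort_shape_and_determinism():
    cohort = gen_cohort(CohortSpec(seed=1))
    # 24 animals x 2 joints x 4 compartments x (5 params x 4 zones + 4 site)
    assert len(cohort) == 24 * 2 * 4 * 24
    assert set(cohort.group) == set(GROUPS)
    assert set(cohort.compartment) == set(COMPARTMENTS)
    assert set(cohort.zone) == set(ZONES) | {"ALL"}
    assert (cohort.value > 0).all()
    again = gen_cohort(CohortSpec(seed=1))
    pd.testing.assert_frame_equal(cohort, again)
    assert not cohort.value.equals(gen_cohort(CohortSpec(seed=2)).value)


def test_cohort_reduced_sham_group():
    cohort = gen_cohort(CohortSpec(n_per_group={"SHAM": 7, "CONT": 8, "RIS": 8}))
    assert cohort[cohort.group == "SHAM"].specimen.nunique() == 7
    assert cohort[cohort.group == "RIS"].specimen.nunique() == 8


def test_cohort_missing_cell_raises_keyerror():
    params = parameter_table_to_map(default_parameter_table())
    params.pop(("RIS", "HT", "MTP", "Z4", "FI"))
    spec = CohortSpec(parameter_means_sds=params)
    with pytest.raises(KeyError, match="RIS.*MTP.*Z4.*FI"):
        gen_cohort(spec)


def test_cohort_zero_sd_cell_is_degenerate():
    params = {("G", "OA", "LFC", "Z1", "X"): (5.0, 0.0),
              ("G", "HT", "LFC", "Z1", "X"): (5.0, 0.0)}
    spec = CohortSpec(groups=("G",), n_per_group=3, compartments=("LFC",),
                      zones=("Z1",), zone_parameters=("X",), site_parameters=(),
                      parameter_means_sds=params)
    cohort = gen_cohort(spec)
    assert (cohort.value == 5.0).all()
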