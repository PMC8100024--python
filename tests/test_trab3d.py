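import numpy as np
import pytest

from bonemorph._localthickness import local_thickness_map, mean_local_thickness
from bonemorph.phantoms import TrabPhantomSpec, gen_trab_phantom_3d
from bonemorph.trab3d import (
    CylVOI,
    TrabVolume3D,
    bv_tv,
    central_plane_section,
    extract_voi,
    local_thickness,
    measure_voi,
    tb_n,
)


def slab_volume(n_layers: int, pad: int = 6, lateral: int = 40) -> np.ndarray:
    vol = np.zeros((n_layers + 2 * pad, lateral, lateral), bool)
    vol[pad:pad + n_layers] = True
    return vol


def test_even_slab_thickness_is_exact():
    assert mean_local_thickness(slab_volume(10)) == pytest.approx(10.0, abs=1e-6)


def test_odd_slab_parity_bias_is_one_voxel():
    # voxel-centre distance transforms overestimate odd-count slabs by one
    # voxel; this is the documented discretization limit of the estimator
    assert mean_local_thickness(slab_volume(9)) == pytest.approx(10.0, abs=1e-6)


def test_sphere_diameter_recovered_within_one_voxel():
    n, r = 41, 14.0
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[:n, :n, :n]
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
    th = local_thickness_map(ball, 1.0)
    assert th[ball].max() == pytest.approx(2 * r, abs=1.0)


def test_thickness_field_constant_inside_slab():
    field = local_thickness_map(slab_volume(12), 1.0)
    vals = field[slab_volume(12)]
    assert vals.min() == vals.max() == pytest.approx(12.0)


def test_voxel_size_scales_thickness():
    vol = slab_volume(10)
    assert mean_local_thickness(vol, 0.02) == pytest.approx(0.2, abs=1e-6)


def test_empty_phase_returns_zeros():
    assert not local_thickness_map(np.zeros((5, 5, 5), bool)).any()


def test_plate_phantom_orientation_robustness():
    # tilting the plates 30 degrees must not change the maximal-sphere
    # thickness by more than the stair-step discretization allowance
    spec = dict(kind="plates", domain_size=(0.9, 0.45, 0.9), pixel_size=0.0075,
                thickness=0.15, spacing=0.30)
    th = {}
    for deg in (0.0, 30.0):
        vol, _ = gen_trab_phantom_3d(TrabPhantomSpec(orientation_deg=deg, **spec))
        th[deg] = local_thickness(vol, "bone")
    assert th[30.0] == pytest.approx(0.15, rel=0.08)
    assert abs(th[30.0] - th[0.0]) / th[0.0] < 0.08


def test_extract_voi_masks_cylinder():
    vol = TrabVolume3D(np.ones((100, 100, 100), bool), 0.02, site="tibia")
    voi = CylVOI(center_mm=(1.0, 1.0, 1.0), diameter_mm=1.0, depth_mm=1.0)
    sub = extract_voi(vol, voi)
    n_expected = np.pi * 0.5 ** 2 * 1.0 / 0.02 ** 3
    assert sub.inside.sum() == pytest.approx(n_expected, rel=0.01)
    assert bv_tv(sub) == 100.0


def test_extract_voi_rejects_protruding_voi():
    vol = TrabVolume3D(np.ones((50, 50, 50), bool), 0.02)
    with pytest.raises(ValueError, match="contained fraction"):
        extract_voi(vol, CylVOI(center_mm=(0.2, 0.5, 0.5), diameter_mm=1.0, depth_mm=0.5))


def test_voi_wall_bounds_inscribed_spheres():
    # a solid cylinder VOI: thickness is capped by the cylinder diameter
    vol = TrabVolume3D(np.ones((80, 80, 80), bool), 0.02)
    voi = CylVOI(center_mm=(0.8, 0.8, 0.8), diameter_mm=1.0, depth_mm=1.2)
    sub = extract_voi(vol, voi)
    assert local_thickness(sub, "bone") <= 1.0 + 2 * 0.02


def test_empty_marrow_phase_warns_nan():
    vol = TrabVolume3D(np.ones((30, 30, 30), bool), 0.02)
    with pytest.warns(UserWarning, match="marrow"):
        assert np.isnan(local_thickness(vol, "marrow"))
    with pytest.raises(ValueError, match="phase"):
        local_thickness(vol, "osteoid")


def test_tb_n_models():
    assert tb_n(33.0, 0.15) == pytest.approx(0.33 / 0.15)
    assert tb_n(33.0, 0.15, 0.30, model="inverse-sum") == pytest.approx(1.0 / 0.45)
    assert np.isnan(tb_n(33.0, 0.0))
    with pytest.raises(ValueError):
        tb_n(33.0, 0.15, model="rod")
    with pytest.raises(ValueError):
        tb_n(33.0, 0.15, model="inverse-sum")


def test_central_plane_section_matches_slice():
    vol, _ = gen_trab_phantom_3d(
        TrabPhantomSpec(kind="plates", domain_size=(2.0, 2.0, 2.0), pixel_size=0.02,
                        thickness=0.16, spacing=0.32, site="tibia")
    )
    voi = CylVOI.for_site("tibia", (1.0, 1.0, 1.0))
    sec = central_plane_section(vol, voi)
    assert sec.mask.shape == (75, 75)  # 1.5 mm x 1.5 mm at 20 um
    iy = int(1.0 / 0.02)
    z0 = x0 = int(round((1.0 - 0.75) / 0.02))
    assert np.array_equal(sec.mask, vol.volume[z0:z0 + 75, iy, x0:x0 + 75])


def test_measure_voi_end_to_end_on_plates():
    vol, truth = gen_trab_phantom_3d(
        TrabPhantomSpec(kind="plates", domain_size=(2.0, 2.0, 1.92), pixel_size=0.015,
                        thickness=0.15, spacing=0.33, site="tibia")
    )
    # depth of three full periods, ends aligned with plate surfaces, so no
    # plate or gap is truncated at the VOI ends
    voi = CylVOI(center_mm=(1.0, 1.0, 1.035), diameter_mm=1.8, depth_mm=1.44)
    res = measure_voi(vol, voi)
    assert res.bv_tv_pct == pytest.approx(truth.bv_tv_pct, rel=0.02)
    assert res.tb_th_mm == pytest.approx(truth.tb_th_mm, abs=0.015)
    assert res.tb_sp_mm == pytest.approx(truth.tb_sp_mm, abs=0.015)
    recs = res.as_records()
    assert [r["parameter"] for r in recs] == ["BV/TV", "Tb.Th", "Tb.Sp", "Tb.N"]


def test_volume_validation():
    with pytest.raises(ValueError, match="3D"):
        TrabVolume3D(np.zeros((4, 4)), 0.01)
    with pytest.raises(ValueError, match="voxel size"):
        TrabVolume3D(np.zeros((4, 4, 4)), 0.0)
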