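import math

import numpy as np
import pytest

from mcmorph.morphometry import (
    aggregate_sample,
    equivalent_diameters,
    measure_object,
    measure_objects,
    object_volume,
    smi,
    surface_area,
    surface_derivative,
)
from mcmorph.segmentation import label_components
from mcmorph.volume_io import VoxelVolume

from conftest import cylinder_mask, plate_mask, sphere_mask

H = 9.0  # um


# --- exact definitions -----------------------------------------------------


@pytest.mark.parametrize(
    "count,spacing,expected",
    [(1000, 10.0, 1e6), (1, 9.0, 729.0)],
)
def test_object_volume_definition(count, spacing, expected):
    assert object_volume(count, spacing) == pytest.approx(expected)


def test_object_volume_scales_cubically_with_spacing():
    v1 = object_volume(123, 9.0)
    assert object_volume(123, 18.0) == pytest.approx(8 * v1)


@pytest.mark.parametrize(
    "V,d_sphere,d_cube",
    [
        (1e6, (6e6 / math.pi) ** (1 / 3), 100.0),
        (math.pi / 6 * 100**3, 100.0, (math.pi / 6) ** (1 / 3) * 100),
        (22e5, None, 130.06),  # cube-equivalent diameter of a 22e5 um^3 mean volume
    ],
)
def test_equivalent_diameters(V, d_sphere, d_cube):
    ds, dc = equivalent_diameters(V)
    if d_sphere is not None:
        assert ds == pytest.approx(d_sphere, rel=1e-12)
    assert dc == pytest.approx(d_cube, rel=1e-3)


@pytest.mark.parametrize(
    "V,S,Sp,expected",
    [
        # ideal solids: sphere, cylinder (lateral only), plate
        (4 / 3 * math.pi * 50**3, 4 * math.pi * 50**2, 8 * math.pi * 50, 4.0),
        (math.pi * 10**2 * 500, 2 * math.pi * 10 * 500, 2 * math.pi * 500, 3.0),
        (1000.0 * 30, 2 * 1000.0, 0.0, 0.0),
    ],
)
def test_smi_formula_on_ideal_solids(V, S, Sp, expected):
    assert smi(V, S, Sp) == pytest.approx(expected, abs=1e-12)


def test_smi_rejects_zero_surface():
    with pytest.raises(ValueError):
        smi(1.0, 0.0, 1.0)


# --- surface estimators ----------------------------------------------------


def test_sphere_surface_area_within_3_percent():
    r = 20.0
    S = surface_area(sphere_mask(r), H)
    assert S == pytest.approx(4 * math.pi * (r * H) ** 2, rel=0.03)


def test_large_cuboid_surface_area_within_5_percent():
    # smoothing rounds the sharp edges, so the relative deficit shrinks as
    # faces grow quadratically while edges grow linearly; large box required
    mask = np.zeros((68, 53, 38), dtype=bool)
    mask[4:64, 4:49, 4:34] = True  # 60 x 45 x 30 voxels
    a, b, c = 60 * H, 45 * H, 30 * H
    S = surface_area(mask, H)
    assert S == pytest.approx(2 * (a * b + b * c + c * a), rel=0.05)


def test_single_voxel_surface_is_near_inscribed_sphere():
    # Smoothing + meshing rounds an isolated voxel toward its inscribed
    # sphere; the measured area sits near pi*h^2, not the 6*h^2 of the cube.
    mask = np.zeros((9, 9, 9), dtype=bool)
    mask[4, 4, 4] = True
    S = surface_area(mask, H)
    assert S == pytest.approx(math.pi * H**2, rel=0.25)


def test_object_touching_border_requires_padding():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[0:3, 3:6, 3:6] = True
    with pytest.raises(ValueError, match="pad"):
        surface_area(mask, H)
    with pytest.raises(ValueError, match="pad"):
        surface_derivative(mask, H)


def test_sphere_surface_derivative_within_10_percent():
    r = 20.0
    Sp = surface_derivative(sphere_mask(r), H)
    assert Sp == pytest.approx(8 * math.pi * r * H, rel=0.10)


def test_long_cylinder_surface_derivative_within_10_percent():
    r, L = 5.0, 300.0  # caps contribute 4r/L ~ 6.7% of the lateral term
    Sp = surface_derivative(cylinder_mask(r, L), H)
    assert Sp == pytest.approx(2 * math.pi * L * H, rel=0.10)


def test_thin_plate_surface_derivative_vanishes_relative_to_S():
    mask = plate_mask(120.0, 4.0)
    S = surface_area(mask, H)
    Sp = surface_derivative(mask, H)
    assert abs(Sp) < 0.15 * S / H  # face area is unchanged by thickening


def test_voxel_dilation_variant_is_available():
    Sp = surface_derivative(sphere_mask(10.0), H, method="voxel")
    assert Sp > 0


# --- SMI on digitized phantoms --------------------------------------------


def test_sphere_smi_converges_monotonically_with_radius():
    errors = [abs(measure_object(sphere_mask(r), H).SMI - 4.0) for r in (10.0, 20.0, 40.0)]
    assert errors[0] > errors[1] > errors[2]
    assert errors[1] < 0.4


def test_cylinder_and_plate_smi_near_class_values():
    assert measure_object(cylinder_mask(6.0, 250.0), H).SMI == pytest.approx(3.0, abs=0.3)
    assert measure_object(plate_mask(220.0, 3.0), H).SMI == pytest.approx(0.0, abs=0.4)


def test_smi_robust_to_resolution_doubling():
    # same 180 um sphere sampled at 9 um and 4.5 um
    smi_coarse = measure_object(sphere_mask(20.0), 9.0).SMI
    smi_fine = measure_object(sphere_mask(40.0), 4.5).SMI
    assert abs(smi_fine - smi_coarse) < 0.2


def test_outward_normal_orientation_grows_sphere_surface():
    # pins the mesh-dilation sign convention: S' of a convex body is positive
    assert surface_derivative(sphere_mask(12.0), H) > 0


# --- measure_objects and aggregation ---------------------------------------


def test_measure_objects_sphere_and_rod():
    grid = np.zeros((100, 120, 120), dtype=bool)
    s = sphere_mask(12.0, pad=0)
    grid[10 : 10 + s.shape[0], 10 : 10 + s.shape[1], 10 : 10 + s.shape[2]] = s
    c = cylinder_mask(5.0, 70.0, pad=0)
    grid[12 : 12 + c.shape[0], 70 : 70 + c.shape[1], 70 : 70 + c.shape[2]] = c
    labeled = label_components(VoxelVolume(grid, H))
    records = measure_objects(labeled)
    assert len(records) == 2
    smis = sorted(o.SMI for o in records)
    assert smis[0] == pytest.approx(3.0, abs=0.45)  # short rod: end caps add ~0.3
    assert smis[1] == pytest.approx(4.0, abs=0.4)
    for o in records:
        assert o.V == o.voxel_count * H**3  # exact, no estimator involved


def test_measure_objects_empty_volume():
    labeled = label_components(VoxelVolume(np.zeros((6, 6, 6), dtype=bool), H))
    assert measure_objects(labeled) == []


def _fake_obj(object_id, V=1e5, SMI=3.0):
    from mcmorph.morphometry import ObjectMorphometry

    d_sphere, d_cube = equivalent_diameters(V)
    return ObjectMorphometry(object_id, 1, V, 1.0, 1.0, SMI, d_sphere, d_cube)


def test_aggregate_sample_statistics():
    objs = [_fake_obj(1, SMI=2.0), _fake_obj(2, SMI=3.0), _fake_obj(3, SMI=4.0)]
    agg = aggregate_sample(objs, "s")
    assert agg.mean_SMI == pytest.approx(3.0)
    assert agg.sd_SMI == pytest.approx(1.0)  # n-1 denominator
    assert not agg.excluded


def test_aggregate_single_object_has_zero_sd_and_is_excluded():
    agg = aggregate_sample([_fake_obj(1, SMI=3.02)], "s")
    assert agg.mean_SMI == pytest.approx(3.02)
    assert agg.sd_SMI == 0.0
    assert agg.excluded


def test_aggregate_mean_volume():
    objs = [_fake_obj(1, V=1e5), _fake_obj(2, V=3e5)]
    assert aggregate_sample(objs, "s").mean_V == pytest.approx(2e5)


def test_aggregate_is_permutation_invariant():
    objs = [_fake_obj(i, V=v, SMI=s) for i, (v, s) in
            enumerate([(1e5, 2.5), (4e5, 3.3), (2e5, 3.9), (8e5, 2.1)])]
    a = aggregate_sample(objs, "s")
    b = aggregate_sample(objs[::-1], "s")
    for fld in ("n_objects", "mean_V", "mean_SMI", "sd_SMI", "mean_d_cube", "max_d_sphere"):
        assert getattr(a, fld) == pytest.approx(getattr(b, fld))


def test_aggregate_empty_sample_flagged():
    agg = aggregate_sample([], "s")
    assert agg.n_objects == 0 and math.isnan(agg.mean_SMI) and not agg.excluded
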