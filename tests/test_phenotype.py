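"""Parameter extraction: cylinder fits, leaf meshing, hulls, segmentation."""

from itertools import combinations

import numpy as np
import pytest

from conftest import random_rigid_motion
from phyto3d import (PlantConfig, cumulated_leaf_area, convex_hull_volume,
                     fit_cylinder, generate_plant, laser_profile, measure_plant,
                     mesh_leaf, sample_sensor, segment_organs, stem_height,
                     true_parameters)
from phyto3d.cloud import PointCloud, UnitState
from phyto3d.phenotype import (DegenerateHullError, FitError, LeafMesh,
                               MeshError, ORGAN_BRANCH, ORGAN_LEAF, ORGAN_STEM,
                               SegmentationError)
from phyto3d.synthetic import _sample_tube


def _cylinder_points(radius=2.0, extent=30.0, axial_step=0.5, n_angles=40):
    z = np.arange(0.0, extent + axial_step / 2, axial_step)
    ang = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    zz, aa = np.meshgrid(z, ang)
    return np.column_stack([radius * np.cos(aa.ravel()),
                            radius * np.sin(aa.ravel()),
                            zz.ravel()])


def _mm_cloud(coords, **kw):
    return PointCloud(np.asarray(coords, float),
                      unit_state=UnitState.MILLIMETERS, **kw)


# ---------------------------------------------------------------------------
# cylinder fitting
# ---------------------------------------------------------------------------

def test_exact_cylinder_recovered_to_machine_precision():
    fit = fit_cylinder(_cylinder_points())
    assert fit.radius == pytest.approx(2.0, abs=1e-9)
    assert fit.height == pytest.approx(30.0, abs=1e-9)
    assert fit.rms_residual < 1e-9
    assert abs(np.linalg.norm(fit.axis_direction) - 1.0) < 1e-9


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cylinder_fit_is_rigid_motion_invariant(seed):
    pts = _cylinder_points()
    rng = np.random.default_rng(seed)
    rot, t = random_rigid_motion(rng)
    fit = fit_cylinder(pts @ rot.T + t)
    assert fit.radius == pytest.approx(2.0, rel=1e-9)
    assert fit.height == pytest.approx(30.0, rel=1e-9)
    rotated_axis = rot @ np.array([0.0, 0.0, 1.0])
    assert abs(fit.axis_direction @ rotated_axis) > 1.0 - 1e-9


def test_noisy_cylinder_statistics_over_20_seeds():
    """5000 samples, radius 2 mm, extent 100 mm, sigma = 0.05 mm: the fit
    stays within tight mean-error bounds (simulation ground truth)."""
    height_err, radius_err = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        z = rng.uniform(-50.0, 50.0, 5000)
        ang = rng.uniform(0.0, 2 * np.pi, 5000)
        pts = np.column_stack([2.0 * np.cos(ang), 2.0 * np.sin(ang), z])
        pts += rng.normal(0.0, 0.05, pts.shape)
        fit = fit_cylinder(pts)
        height_err.append(abs(fit.height - (z.max() - z.min())))
        radius_err.append(abs(fit.radius - 2.0))
    assert np.mean(height_err) < 0.5
    assert np.mean(radius_err) < 0.02


def test_cylinder_fit_rejects_degenerate_input():
    line = np.column_stack([np.zeros((50, 2)), np.linspace(0, 10, 50)])
    with pytest.raises(FitError, match="collinear"):
        fit_cylinder(line)
    with pytest.raises(FitError, match="10"):
        fit_cylinder(np.random.default_rng(0).normal(size=(5, 3)))


# ---------------------------------------------------------------------------
# stem height
# ---------------------------------------------------------------------------

def _stem_branch_cloud(scale=1.0):
    stem = _sample_tube(np.array([[0, 0, 0.0], [0, 0, 168.0]]) * scale,
                        2.5 * scale, 0.5 * scale, 0.0, None)
    branch = _sample_tube(np.array([[0, 0, 120.0], [30, 0, 135.0]]) * scale,
                          1.2 * scale, 0.5 * scale, 0.0, None)
    coords = np.vstack([stem, branch])
    labels = np.concatenate([np.full(len(stem), 1), np.full(len(branch), 2)])
    return _mm_cloud(coords, labels=labels.astype(np.int32))


def test_stem_height_with_ground_truth_markers_is_exact():
    cloud = _stem_branch_cloud()
    seg = segment_organs(cloud, mode="labels")
    height, fit = stem_height(cloud, seg, base_z=0.0, node_z=120.0)
    assert height == pytest.approx(120.0, abs=1e-6)
    assert fit.radius == pytest.approx(2.5, abs=1e-6)


def test_stem_height_scale_equivariance():
    seg1 = segment_organs(_stem_branch_cloud(), mode="labels")
    h1, _ = stem_height(_stem_branch_cloud(), seg1)
    cloud2 = _stem_branch_cloud(scale=2.0)
    h2, _ = stem_height(cloud2, segment_organs(cloud2, mode="labels"))
    assert h2 == pytest.approx(2.0 * h1, rel=1e-9)


def test_detected_junction_close_to_true_node():
    cloud = _stem_branch_cloud()
    seg = segment_organs(cloud, mode="labels")
    height, _ = stem_height(cloud, seg)
    assert height == pytest.approx(120.0, abs=3.0)


def test_bowed_stem_cylinder_height_approximates_chord():
    """Arc with chord 100 mm / sagitta 5 mm: the fitted cylinder height lands
    near the chord and below the true arc length."""
    chord, sagitta = 100.0, 5.0
    radius_arc = (chord ** 2 / 4 + sagitta ** 2) / (2 * sagitta)
    theta = np.arcsin((chord / 2) / radius_arc)
    arc_length = 2 * radius_arc * theta  # independent arc-geometry oracle
    phi = np.linspace(-theta, theta, 201)
    spine = np.column_stack([radius_arc * np.sin(phi),
                             np.zeros_like(phi),
                             radius_arc * np.cos(phi) - radius_arc * np.cos(theta)])
    pts = _sample_tube(spine, 2.0, 0.5, 0.0, None)
    fit = fit_cylinder(pts)
    assert 99.0 <= fit.height <= 101.0
    assert fit.height < arc_length


# ---------------------------------------------------------------------------
# leaf meshing
# ---------------------------------------------------------------------------

def test_mesh_recovers_square_area():
    xs = np.arange(21.0)  # 21 x 21 grid, 1 mm pitch, 20 x 20 mm square
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    mesh = mesh_leaf(pts)
    assert mesh.area == pytest.approx(400.0, rel=0.005)


def test_mesh_recovers_disc_area():
    spacing = 0.25
    xs = np.arange(-10, 10 + spacing, spacing)
    gx, gy = np.meshgrid(xs, xs)
    pts2 = np.column_stack([gx.ravel(), gy.ravel()])
    pts2 = pts2[np.hypot(pts2[:, 0], pts2[:, 1]) <= 10 - 0.3 * spacing]
    ang = np.arange(0.0, 2 * np.pi, spacing / 10.0)
    ring = 10.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    pts = np.column_stack([np.vstack([pts2, ring]),
                           np.zeros(len(pts2) + len(ring))])
    mesh = mesh_leaf(pts)
    assert mesh.area == pytest.approx(np.pi * 100.0, rel=0.01)


def test_mesh_recovers_developable_bent_rectangle():
    """20 x 30 mm rectangle bent isometrically around a 15 mm cylinder keeps
    its 600 mm^2 area."""
    spacing, r = 0.25, 15.0
    x = np.arange(0, 20 + spacing, spacing)
    y = np.arange(0, 30 + spacing, spacing)
    gx, gy = np.meshgrid(x, y)
    pts = np.column_stack([r * np.sin(gx.ravel() / r), gy.ravel(),
                           r * (1 - np.cos(gx.ravel() / r))])
    mesh = mesh_leaf(pts)
    assert mesh.area == pytest.approx(600.0, rel=0.01)


def test_mesh_area_monotone_in_prune_factor():
    rng = np.random.default_rng(7)
    pts = np.column_stack([rng.uniform(0, 20, (2000, 2)), np.zeros(2000)])
    areas = [mesh_leaf(pts, prune_factor=f).area for f in (4.0, 3.0, 2.0, 1.5)]
    assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))


def test_mesh_rejects_degenerate_input():
    with pytest.raises(MeshError):
        mesh_leaf(np.column_stack([np.linspace(0, 1, 30),
                                   np.zeros((30, 2))]))  # collinear
    with pytest.raises(MeshError):
        mesh_leaf(np.zeros((2, 3)))


def test_folded_leaf_triggers_warning():
    ang = np.linspace(0.0, 5.2, 60)  # ~300 degree wrap: projection folds
    y = np.linspace(0.0, 20.0, 40)
    aa, yy = np.meshgrid(ang, y)
    pts = np.column_stack([5 * np.cos(aa.ravel()), yy.ravel(),
                           5 * np.sin(aa.ravel())])
    with pytest.warns(UserWarning, match="fold"):
        mesh_leaf(pts)


def test_cumulated_leaf_area_examples():
    assert cumulated_leaf_area([]) == 0.0
    meshes = [LeafMesh(np.zeros((3, 3)), np.zeros((0, 3), int), a)
              for a in (100.0, 250.5)]
    assert cumulated_leaf_area(meshes) == pytest.approx(350.5)
    rng = np.random.default_rng(0)
    areas = rng.uniform(1, 100, 10)
    ms = [LeafMesh(np.zeros((3, 3)), np.zeros((0, 3), int), a) for a in areas]
    assert cumulated_leaf_area(ms) == pytest.approx(
        cumulated_leaf_area(ms[::-1]), rel=1e-12)


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------

def _brute_force_hull_volume(pts):
    """Exhaustive facet search + tetrahedral decomposition from the centroid."""
    centroid = pts.mean(axis=0)
    volume = 0.0
    for i, j, k in combinations(range(len(pts)), 3):
        a, b, c = pts[i], pts[j], pts[k]
        normal = np.cross(b - a, c - a)
        if np.linalg.norm(normal) < 1e-12:
            continue
        side = (pts - a) @ normal
        if (side <= 1e-9).all() or (side >= -1e-9).all():
            volume += abs(np.dot(a - centroid,
                                 np.cross(b - centroid, c - centroid))) / 6.0
    return volume


def test_hull_volume_of_unit_tetrahedron():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    vol = convex_hull_volume(_mm_cloud(pts))
    assert vol == pytest.approx((1.0 / 6.0) / 1e6, rel=1e-12)


def test_hull_volume_ignores_interior_points():
    corners = np.array([[x, y, z] for x in (0, 100.0)
                        for y in (0, 100.0) for z in (0, 100.0)])
    rng = np.random.default_rng(8)
    interior = rng.uniform(1, 99, (100, 3))
    vol = convex_hull_volume(_mm_cloud(np.vstack([corners, interior])))
    assert vol == pytest.approx(1.0, rel=1e-12)  # 1 dm^3


def test_hull_volume_matches_brute_force_oracle():
    rng = np.random.default_rng(9)
    pts = rng.uniform(0, 50, (50, 3))
    assert convex_hull_volume(_mm_cloud(pts)) * 1e6 == pytest.approx(
        _brute_force_hull_volume(pts), rel=1e-9)


def test_hull_volume_monotone_under_adding_points():
    rng = np.random.default_rng(10)
    base = rng.uniform(0, 50, (40, 3))
    extra = rng.uniform(-10, 70, (20, 3))
    v1 = convex_hull_volume(_mm_cloud(base))
    v2 = convex_hull_volume(_mm_cloud(np.vstack([base, extra])))
    assert v2 >= v1 - 1e-15


def test_hull_degenerate_input_raises():
    with pytest.raises(DegenerateHullError):
        convex_hull_volume(_mm_cloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])))
    flat = np.column_stack([np.random.default_rng(0).uniform(0, 1, (20, 2)),
                            np.zeros(20)])
    with pytest.raises(DegenerateHullError):
        convex_hull_volume(_mm_cloud(flat))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_labels_mode_passes_ground_truth_through(small_plant_cloud):
    seg = segment_organs(small_plant_cloud, mode="labels")
    labels = small_plant_cloud.labels
    assert np.all(seg.organ_class[labels == 1] == ORGAN_STEM)
    assert np.all(seg.organ_class[labels == 2] == ORGAN_BRANCH)
    assert np.all(seg.organ_class[labels >= 10] == ORGAN_LEAF)
    assert np.array_equal(np.unique(seg.leaf_ids[labels >= 10]),
                          np.unique(labels[labels >= 10]) - 10)


def test_labels_mode_requires_labels():
    with pytest.raises(SegmentationError):
        segment_organs(_mm_cloud(np.zeros((60, 3))), mode="labels")


def test_geometric_mode_classifies_cylinder_as_linear():
    pts = _sample_tube(np.array([[0, 0, 0.0], [0, 0, 100.0]]), 2.0, 0.5, 0.0, None)
    seg = segment_organs(_mm_cloud(pts), mode="geometric")
    linear = np.isin(seg.organ_class, (ORGAN_STEM, ORGAN_BRANCH))
    assert linear.mean() >= 0.99


def test_geometric_mode_classifies_plane_as_leaf():
    xs = np.arange(0, 40, 0.5)
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    seg = segment_organs(_mm_cloud(pts), mode="geometric")
    assert (seg.organ_class == ORGAN_LEAF).mean() >= 0.99


# ---------------------------------------------------------------------------
# combined measurement properties
# ---------------------------------------------------------------------------

def test_measurement_invariant_under_rigid_motion(small_plant_cloud):
    base = measure_plant(small_plant_cloud)
    rng = np.random.default_rng(3)
    rot, t = random_rigid_motion(rng)
    moved_cloud = small_plant_cloud.with_coordinates(
        small_plant_cloud.coordinates @ rot.T + t)
    moved = measure_plant(moved_cloud)
    assert moved.main_stem_height == pytest.approx(base.main_stem_height, rel=1e-6)
    assert moved.cumulated_leaf_area == pytest.approx(base.cumulated_leaf_area, rel=1e-6)
    assert moved.convex_hull_volume == pytest.approx(base.convex_hull_volume, rel=1e-6)
    for leaf_id, area in base.single_leaf_areas.items():
        assert moved.single_leaf_areas[leaf_id] == pytest.approx(area, rel=1e-6)


def test_measurement_scales_as_expected(small_plant_cloud):
    s = 2.0
    base = measure_plant(small_plant_cloud)
    scaled = measure_plant(small_plant_cloud.with_coordinates(
        small_plant_cloud.coordinates * s))
    assert scaled.main_stem_height == pytest.approx(s * base.main_stem_height, rel=1e-6)
    assert scaled.cumulated_leaf_area == pytest.approx(
        s ** 2 * base.cumulated_leaf_area, rel=1e-6)
    assert scaled.convex_hull_volume == pytest.approx(
        s ** 3 * base.convex_hull_volume, rel=1e-6)


def test_noiseless_measurement_recovers_ground_truth_within_1pct():
    """On a noiseless, artifact-free, label-segmented cloud every parameter
    lands within 1% of the generator's analytic truth."""
    model = generate_plant(PlantConfig(day_index=2, seed=21))
    truth = true_parameters(model, hull_spacing=0.25)
    cloud = sample_sensor(model, laser_profile(noise_sigma=0.0), seed=2)
    result = measure_plant(cloud)
    assert result.main_stem_height == pytest.approx(truth.main_stem_height, rel=0.01)
    assert result.cumulated_leaf_area == pytest.approx(
        truth.cumulated_leaf_area, rel=0.01)
    assert result.convex_hull_volume == pytest.approx(
        truth.convex_hull_volume, rel=0.01)
    truth_by_id = dict(zip(truth.leaf_ids, truth.single_leaf_areas))
    assert set(result.single_leaf_areas) == set(truth_by_id)
    for leaf_id, area in result.single_leaf_areas.items():
        assert area == pytest.approx(truth_by_id[leaf_id], rel=0.01)
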