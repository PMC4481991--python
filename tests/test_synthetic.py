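"""Synthetic plant generator: ground truth, determinism, sensor emulation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import random_rigid_motion
from phyto3d import (PlantConfig, generate_plant, laser_profile,
                     photogrammetric_profile, sample_sensor, true_parameters)
from phyto3d.cloud import LEAF_LABEL_BASE
from phyto3d.synthetic import ConfigError, dense_surface_points


def _planar_config(**kw):
    return PlantConfig(leaf_bend=0.0, leaf_crookedness=0.0, **kw)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def test_stem_only_plant_has_zero_leaf_area():
    model = generate_plant(PlantConfig(n_leaves=0, n_branches=2))
    assert model.leaves == []
    truth = true_parameters(model, hull_spacing=0.5)
    assert truth.cumulated_leaf_area == 0.0
    assert truth.single_leaf_areas == ()


def test_generation_is_deterministic():
    cfg = PlantConfig(seed=42, day_index=2)
    a, b = generate_plant(cfg), generate_plant(cfg)
    assert np.array_equal(a.stem_spine, b.stem_spine)
    for la, lb in zip(a.leaves, b.leaves):
        assert la.size == lb.size and la.crook_phase == lb.crook_phase
        assert np.array_equal(la.attach, lb.attach)
    ca = sample_sensor(a, photogrammetric_profile(), seed=5)
    cb = sample_sensor(b, photogrammetric_profile(), seed=5)
    assert np.array_equal(ca.coordinates, cb.coordinates)
    assert np.array_equal(ca.colors, cb.colors)


@pytest.mark.parametrize("field,value", [
    ("n_leaves", -1), ("stem_height", 0.0), ("leaf_bend", 1.5),
    ("growth_rate", -0.1), ("leaf_size_range", (5.0, 2.0)),
])
def test_invalid_config_error_names_field(field, value):
    cfg = PlantConfig(**{field: value})
    with pytest.raises(ConfigError, match=field.split("_")[0]):
        generate_plant(cfg)


def test_growth_series_spans_100_to_150_mm_and_adds_leaves():
    heights, counts = [], []
    for day in range(6):
        model = generate_plant(PlantConfig(day_index=day, seed=7))
        heights.append(np.linalg.norm(model.node_point - model.base_point))
        counts.append(len(model.leaves))
    assert 100.0 <= heights[5] - heights[0] <= 150.0
    deltas = np.diff(counts)
    assert np.all((deltas >= 1) & (deltas <= 2))


def test_leaves_attach_on_their_parent_curves():
    model = generate_plant(PlantConfig(day_index=3, seed=3))
    curves = [model.stem_spine] + [c for c, _ in model.branches]
    all_pts = np.vstack(curves)
    tree = cKDTree(all_pts)
    for leaf in model.leaves:
        dist, _ = tree.query(leaf.attach)
        assert dist < 2.0 * model.stem_radius


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def test_planar_leaf_area_matches_polygon_shoelace_oracle():
    """With bend = crookedness = 0 every patch is planar and its area must
    equal the 2D outline polygon area (shoelace on a dense outline)."""
    model = generate_plant(_planar_config(n_leaves=5, seed=1))
    for leaf in model.leaves:
        theta = np.linspace(-np.pi, np.pi, 20001)
        r = leaf.outline_radius(theta)
        x, y = r * np.cos(theta), r * np.sin(theta)
        shoelace = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        assert leaf.area(n=1024) == pytest.approx(shoelace, rel=1e-4)


def test_bent_leaf_area_equals_flat_area():
    """Arc bending is an isometry: the bent patch keeps the flat area."""
    flat = generate_plant(_planar_config(n_leaves=3, seed=2))
    bent = generate_plant(PlantConfig(leaf_bend=0.8, leaf_crookedness=0.0,
                                      n_leaves=3, seed=2))
    for i, (lf, lb) in enumerate(zip(flat.leaves, bent.leaves)):
        if i >= 2:  # cotyledons deliberately stay nearly flat
            assert lb.bend > 0.3
        assert lb.area(n=512) == pytest.approx(lf.area(n=512), rel=1e-3)


def test_leaf_area_quadrature_converges():
    model = generate_plant(PlantConfig(n_leaves=3, seed=5))
    for leaf in model.leaves:
        assert leaf.area(n=512) == pytest.approx(leaf.area(n=256), rel=5e-4)


def test_straight_stem_height_equals_node_height():
    model = generate_plant(PlantConfig(stem_curvature=0.0, stem_height=120.0))
    truth = true_parameters(model, hull_spacing=0.5)
    assert truth.main_stem_height == pytest.approx(120.0, abs=1e-9)


def test_cumulated_area_is_sum_of_singles():
    truth = true_parameters(generate_plant(PlantConfig(seed=4)), hull_spacing=0.5)
    assert truth.cumulated_leaf_area == pytest.approx(
        sum(truth.single_leaf_areas), rel=1e-9)


def test_ground_truth_invariant_under_rigid_motion():
    model = generate_plant(PlantConfig(seed=9))
    truth = true_parameters(model, hull_spacing=0.4)
    rng = np.random.default_rng(0)
    for _ in range(2):
        rot, t = random_rigid_motion(rng)
        moved = true_parameters(model.transformed(rot, t), hull_spacing=0.4)
        assert moved.main_stem_height == pytest.approx(
            truth.main_stem_height, rel=1e-9)
        assert moved.cumulated_leaf_area == pytest.approx(
            truth.cumulated_leaf_area, rel=1e-9)
        # hull truth resamples the rotated tubes with a world-fixed ring
        # phase, so only the sampling (not the hull math) limits agreement
        assert moved.convex_hull_volume == pytest.approx(
            truth.convex_hull_volume, rel=1e-4)


@pytest.mark.parametrize("s", [0.31, 1.7, 2.9])
def test_ground_truth_scales_as_expected(s):
    """Uniform scaling: areas x s^2, height x s, hull volume x s^3."""
    model = generate_plant(PlantConfig(seed=6))
    truth = true_parameters(model, hull_spacing=0.5)
    scaled = true_parameters(model.scaled(s), hull_spacing=0.5 * s)
    assert scaled.main_stem_height == pytest.approx(
        s * truth.main_stem_height, rel=1e-9)
    assert scaled.cumulated_leaf_area == pytest.approx(
        s ** 2 * truth.cumulated_leaf_area, rel=1e-9)
    assert scaled.convex_hull_volume == pytest.approx(
        s ** 3 * truth.convex_hull_volume, rel=1e-9)


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

def test_noiseless_samples_lie_on_the_surface():
    """sigma = 0, artifacts off: every leaf point sits exactly on its
    (planar) patch, i.e. in the z = attach-height plane."""
    model = generate_plant(_planar_config(n_leaves=4, seed=8))
    cloud = sample_sensor(model, laser_profile(noise_sigma=0.0), seed=1)
    for leaf in model.leaves:
        pts = cloud.coordinates[cloud.labels == LEAF_LABEL_BASE + leaf.leaf_id]
        normal = leaf.rotation[:, 2]
        dist = np.abs((pts - leaf.attach) @ normal)
        assert dist.max() < 1e-9


def test_photogrammetric_scale_factor_applies_to_reference_edge():
    model = generate_plant(PlantConfig(seed=2))
    profile = photogrammetric_profile(noise_sigma=0.0, noise_iid_sigma=0.0,
                                      scale_factor=0.002)
    cloud = sample_sensor(model, profile, seed=1)
    ref = cloud.metadata["reference"]
    measured = np.linalg.norm(np.array(ref["corner_a"]) - np.array(ref["corner_b"]))
    assert measured == pytest.approx(0.002 * ref["true_length_mm"], rel=1e-12)


def test_artifact_fraction_follows_binomial_sampling():
    """Bernoulli(rate) per border candidate: the realized source fraction
    stays within 3 binomial standard deviations of the rate."""
    model = generate_plant(PlantConfig(day_index=5, seed=3))
    profile = photogrammetric_profile(point_budget=None, target_spacing=0.4,
                                      noise_sigma=0.0, noise_iid_sigma=0.0,
                                      artifact_rate=0.05, occlusion_rate=0.0)
    cloud = sample_sensor(model, profile, seed=12)
    n = cloud.metadata["n_border_candidates"]
    assert n >= 10_000
    frac = cloud.metadata["n_artifact_sources"] / n
    assert abs(frac - 0.05) <= 3.0 * np.sqrt(0.05 * 0.95 / n)
    assert cloud.artifact_flags.sum() >= cloud.metadata["n_artifact_sources"]


def test_sampling_density_matches_target_spacing_on_planar_regions():
    model = generate_plant(_planar_config(n_leaves=3, seed=10,
                                          leaf_size_range=(30.0, 40.0)))
    spacing = 0.5
    cloud = sample_sensor(model, laser_profile(noise_sigma=0.0), seed=4)
    leaf = model.leaves[2]
    pts = cloud.coordinates[cloud.labels == LEAF_LABEL_BASE + leaf.leaf_id]
    # interior subset: flat-domain radius well inside the outline (border
    # rings are intentionally denser)
    local = (pts - leaf.attach) @ leaf.rotation
    ang = np.arctan2(local[:, 1], local[:, 0])
    rad = np.hypot(local[:, 0], local[:, 1])
    interior = pts[rad < leaf.outline_radius(ang) - 3.0]
    assert len(interior) > 500
    dist, _ = cKDTree(interior).query(interior, k=2)
    assert abs(dist[:, 1].mean() - spacing) <= 0.25 * spacing


def test_point_budget_controls_cloud_size():
    model = generate_plant(PlantConfig(day_index=4, seed=1))
    cloud = sample_sensor(model, photogrammetric_profile(point_budget=20000), seed=1)
    plant_n = int((cloud.labels != 0).sum())
    assert 0.6 * 20000 <= plant_n <= 1.6 * 20000


def test_dense_surface_sampling_refines_with_spacing():
    model = generate_plant(PlantConfig(seed=13))
    coarse = dense_surface_points(model, 1.0)
    fine = dense_surface_points(model, 0.5)
    assert np.isfinite(fine).all()
    assert 2.0 < len(fine) / len(coarse) < 8.0  # ~(1/spacing)^2 growth
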