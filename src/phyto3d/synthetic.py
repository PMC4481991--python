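"""Parametric tomato-like plants with analytic ground truth, plus sensor simulators.

The generator produces a ``PlantModel`` — a curved main stem, lateral branches
and cordate leaf patches — whose phenotype (single leaf areas, cumulated leaf
area, main-stem height, convex-hull volume) is known by construction
(``true_parameters``).  ``sample_sensor`` renders a model into a point cloud
emulating either of two measurement systems:

* ``laser`` — a close-up triangulation line scanner: dense, metrically scaled,
  very low noise (default 45 µm), no reconstruction artifacts.
* ``photogrammetric`` — an SfM/MVS reconstruction: sparse (roughly 15k–55k
  points over a growth series), arbitrarily scaled, smooth low-frequency
  surface error, plus white/grey false points offset from leaf borders — the
  signature failure mode of multi-view matching against a bright background.

Leaf geometry: the outline is the cordate polar curve
``r(theta) = a (1 + cos theta)(1 + eps sin k theta)`` (small serration
``eps``), the midrib is bent along a circular arc (an isometry, so bending
does not change area), and "crookedness" is a low-frequency sinusoidal
displacement along the local surface normal.  Leaf areas are obtained by
numerical quadrature of the final embedded surface, so bending/crookedness
are fully accounted for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.spatial import ConvexHull

from .cloud import (LABEL_BRANCH, LABEL_NONPLANT, LABEL_STEM, LEAF_LABEL_BASE,
                    PointCloud, UnitState)

__all__ = [
    "PlantConfig", "PlantModel", "LeafPatch", "GroundTruth", "SensorProfile",
    "generate_plant", "true_parameters", "sample_sensor",
    "laser_profile", "photogrammetric_profile",
]

# Reference object embedded in photogrammetric scenes: a rectangular table
# frame of known edge length, used for metric rescaling downstream.
TABLE_LENGTH_MM = 600.0
TABLE_WIDTH_MM = 400.0
TABLE_Z_MM = -5.0


class ConfigError(ValueError):
    """A plant/sensor configuration field violates its invariant."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantConfig:
    """Parameters of one synthetic plant at a given growth stage.

    ``n_leaves`` counts leaves at day 0 (the first two are the cotyledon
    pair attached directly to the stem); 1–2 leaves are added per day of
    ``day_index``.  ``growth_rate`` multiplies stem height and leaf sizes
    per day and is calibrated so a 6-day series spans a 100–150 mm height
    increase (default 1.15 on a 120 mm plant: +121 mm over 5 days).
    """

    n_leaves: int = 6
    leaf_size_range: Tuple[float, float] = (8.0, 22.0)   # characteristic half-width a, mm
    leaf_bend: float = 0.45          # dimensionless 0-1, arc-bend magnitude
    leaf_crookedness: float = 2.0    # mm, normal-displacement amplitude
    stem_height: float = 120.0       # mm, base to cotyledon node at day 0
    stem_radius: float = 2.5         # mm
    stem_curvature: float = 3.0      # mm, lateral bow amplitude
    n_branches: int = 4
    day_index: int = 0               # 0..5 growth stage
    growth_rate: float = 1.15        # per-day multiplicative scale
    seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 0:
            raise ConfigError("n_leaves must be >= 0")
        lo, hi = self.leaf_size_range
        if not (0 < lo <= hi):
            raise ConfigError("leaf_size_range must satisfy 0 < min <= max")
        if not 0.0 <= self.leaf_bend <= 1.0:
            raise ConfigError("leaf_bend must be in [0, 1]")
        if self.leaf_crookedness < 0:
            raise ConfigError("leaf_crookedness must be >= 0")
        if self.stem_height <= 0:
            raise ConfigError("stem_height must be > 0")
        if self.stem_radius <= 0:
            raise ConfigError("stem_radius must be > 0")
        if self.stem_curvature < 0:
            raise ConfigError("stem_curvature must be >= 0")
        if self.n_branches < 0:
            raise ConfigError("n_branches must be >= 0")
        if self.day_index < 0:
            raise ConfigError("day_index must be >= 0")
        if self.growth_rate <= 0:
            raise ConfigError("growth_rate must be > 0")


@dataclass(frozen=True)
class SensorProfile:
    """Rendering characteristics of one measurement system.

    ``target_spacing`` is the in-surface point-to-point distance (mm); if
    ``point_budget`` is set the spacing is derived from the model's total
    surface area instead.  ``noise_correlation_mm`` = 0 gives i.i.d.
    Gaussian noise per point (laser); > 0 gives a smooth Gaussian random
    field with that correlation length and pointwise std ``noise_sigma``
    (photogrammetric reconstructions err smoothly, not pointwise).
    ``artifact_rate`` is the Bernoulli probability that a leaf-border point
    spawns an offset white/grey false point.
    """

    name: str = "laser"
    target_spacing: float = 0.5          # mm
    noise_sigma: float = 0.045           # mm, per-axis std
    point_budget: Optional[int] = None
    scale_factor: float = 1.0            # global scale applied to the output
    artifact_rate: float = 0.0
    artifact_offset: float = 1.0         # mm, along the local surface normal
    occlusion_rate: float = 0.0          # fraction of small-leaf area dropped
    noise_correlation_mm: float = 0.0
    noise_iid_sigma: float = 0.0         # mm, residual per-point jitter on top
                                         # of a correlated field (if any)
    include_reference_frame: bool = False

    def validate(self) -> None:
        if self.target_spacing <= 0:
            raise ConfigError("target_spacing must be > 0")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ConfigError("artifact_rate must be in [0, 1)")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be > 0")
        if self.point_budget is not None and self.point_budget <= 0:
            raise ConfigError("point_budget must be positive when set")
        if not 0.0 <= self.occlusion_rate < 1.0:
            raise ConfigError("occlusion_rate must be in [0, 1)")
        if self.noise_iid_sigma < 0:
            raise ConfigError("noise_iid_sigma must be >= 0")


def laser_profile(**overrides) -> SensorProfile:
    """Close-up triangulation laser scanner (metric, dense, 45 µm noise)."""
    base = SensorProfile(
        name="laser", target_spacing=0.5, noise_sigma=0.045, point_budget=None,
        scale_factor=1.0, artifact_rate=0.0, occlusion_rate=0.0,
        noise_correlation_mm=0.0, include_reference_frame=False,
    )
    return replace(base, **overrides)


def photogrammetric_profile(**overrides) -> SensorProfile:
    """SfM/MVS reconstruction (sparse, arbitrary scale, border artifacts)."""
    base = SensorProfile(
        name="photogrammetric", target_spacing=0.8, noise_sigma=0.5,
        point_budget=30000, scale_factor=0.004, artifact_rate=0.05,
        artifact_offset=1.0, occlusion_rate=0.02, noise_correlation_mm=12.0,
        noise_iid_sigma=0.05, include_reference_frame=True,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# plant model
# ---------------------------------------------------------------------------

@dataclass
class LeafPatch:
    """One leaf: a cordate flat region embedded by bend + crookedness.

    The flat domain is ``{(x, y): hypot(x, y) <= r(theta)}`` with the cordate
    outline ``r``.  ``surface_local`` maps flat coordinates to the deformed
    local surface; world coordinates are ``attach + rotation @ local``.
    """

    leaf_id: int
    attach: np.ndarray          # (3,) world attachment point (leaf base, r=0)
    rotation: np.ndarray        # (3,3), columns = leaf local axes in world
    size: float                 # a, mm
    serration_eps: float
    serration_k: int
    bend: float                 # 0-1
    crook_amp: float            # mm
    crook_freq: Tuple[float, float]
    crook_phase: Tuple[float, float]

    # -- flat-domain geometry ------------------------------------------------
    def outline_radius(self, theta: np.ndarray) -> np.ndarray:
        return (self.size * (1.0 + np.cos(theta))
                * (1.0 + self.serration_eps * np.sin(self.serration_k * theta)))

    def _span(self) -> float:
        return 2.0 * self.size * (1.0 + self.serration_eps)

    def surface_local(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Deformed surface in the leaf frame; shape ``x.shape + (3,)``."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        span = self._span()
        fx, fy = self.crook_freq
        px, py = self.crook_phase
        # cap the wave slope at ~0.4 so leaves stay sheet-like: stronger
        # waviness would fold the surface beyond what a real (measurable)
        # tomato leaf shows and outside the plane-projection meshing domain
        amp = min(self.crook_amp, 0.4 * span / (2.0 * np.pi * max(fx, fy)))
        c = (amp
             * np.sin(2.0 * np.pi * fx * x / span + px)
             * np.cos(2.0 * np.pi * fy * y / span + py))
        if self.bend < 1e-9:
            return np.stack([x, y, c], axis=-1)
        psi = 1.5 * self.bend               # total arc angle over the span
        radius = span / psi
        u = x / radius
        sin_u, cos_u = np.sin(u), np.cos(u)
        # arc map B=(R sin u, y, R(1-cos u)); unit normal (-sin u, 0, cos u)
        return np.stack([radius * sin_u - c * sin_u,
                         y,
                         radius * (1.0 - cos_u) + c * cos_u], axis=-1)

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        local = self.surface_local(x, y)
        return self.attach + local @ self.rotation.T

    def surface_normal(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Unit world normals via central differences in the flat domain."""
        h = 1e-4 * self.size
        du = self.surface_local(np.asarray(x) + h, y) - self.surface_local(np.asarray(x) - h, y)
        dv = self.surface_local(x, np.asarray(y) + h) - self.surface_local(x, np.asarray(y) - h)
        n = np.cross(du, dv)
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        return (n / norm) @ self.rotation.T

    # -- area ---------------------------------------------------------------
    def area(self, n: int = 256) -> float:
        """Surface area by triangulated quadrature of the polar parameterization.

        Relative discretization error is O(n^-2); doubling ``n`` changes the
        result well below 0.05 % at the default.
        """
        theta = np.linspace(-np.pi, np.pi, n + 1)
        v = np.linspace(0.0, 1.0, n + 1)
        r = self.outline_radius(theta)
        x = v[:, None] * r[None, :] * np.cos(theta)[None, :]
        y = v[:, None] * r[None, :] * np.sin(theta)[None, :]
        pts = self.surface_local(x, y)
        a, b = pts[:-1, :-1], pts[1:, :-1]
        c, d = pts[:-1, 1:], pts[1:, 1:]
        t1 = np.linalg.norm(np.cross(b - a, c - a), axis=-1)
        t2 = np.linalg.norm(np.cross(d - b, d - c), axis=-1)
        return float(0.5 * (t1.sum() + t2.sum()))

    # -- transforms ----------------------------------------------------------
    def transformed(self, rot: np.ndarray, t: np.ndarray) -> "LeafPatch":
        return replace(self, attach=rot @ self.attach + t, rotation=rot @ self.rotation)

    def scaled(self, s: float) -> "LeafPatch":
        return replace(self, attach=self.attach * s, size=self.size * s,
                       crook_amp=self.crook_amp * s)


@dataclass
class PlantModel:
    """Ground-truth plant geometry: stem spine, branch curves, leaf patches."""

    stem_spine: np.ndarray                  # (m, 3), strictly increasing z-ish axial order
    stem_radius: float
    base_point: np.ndarray                  # (3,) stem emergence from the cube
    node_point: np.ndarray                  # (3,) cotyledon node (main-stem end)
    branches: List[Tuple[np.ndarray, float]] = field(default_factory=list)
    leaves: List[LeafPatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stem_spine = np.asarray(self.stem_spine, dtype=np.float64)
        if len(self.stem_spine) < 2:
            raise ConfigError("stem_spine needs at least 2 points")

    def transformed(self, rot: np.ndarray, t: np.ndarray) -> "PlantModel":
        rot = np.asarray(rot, dtype=np.float64)
        t = np.asarray(t, dtype=np.float64)
        return PlantModel(
            stem_spine=self.stem_spine @ rot.T + t,
            stem_radius=self.stem_radius,
            base_point=rot @ self.base_point + t,
            node_point=rot @ self.node_point + t,
            branches=[(curve @ rot.T + t, r) for curve, r in self.branches],
            leaves=[leaf.transformed(rot, t) for leaf in self.leaves],
        )

    def scaled(self, s: float) -> "PlantModel":
        return PlantModel(
            stem_spine=self.stem_spine * s,
            stem_radius=self.stem_radius * s,
            base_point=self.base_point * s,
            node_point=self.node_point * s,
            branches=[(curve * s, r * s) for curve, r in self.branches],
            leaves=[leaf.scaled(s) for leaf in self.leaves],
        )

    def total_surface_area(self) -> float:
        """Approximate one-sided surface area (leaves + stem/branch mantles), mm^2."""
        area = sum(leaf.area(n=64) for leaf in self.leaves)
        area += _polyline_length(self.stem_spine) * 2.0 * np.pi * self.stem_radius
        for curve, r in self.branches:
            area += _polyline_length(curve) * 2.0 * np.pi * r
        return float(area)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic phenotype of one model (areas mm^2, height mm, hull dm^3)."""

    single_leaf_areas: Tuple[float, ...]
    cumulated_leaf_area: float
    main_stem_height: float
    convex_hull_volume: float
    leaf_ids: Tuple[int, ...] = ()


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


def _rotation_from_angles(azimuth: float, pitch: float, roll: float) -> np.ndarray:
    """World rotation for a leaf: midrib azimuth, downward pitch, roll about midrib."""
    ca, sa = math.cos(azimuth), math.sin(azimuth)
    cp, sp = math.cos(pitch), math.sin(pitch)
    cr, sr = math.cos(roll), math.sin(roll)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cr, -sr], [0.0, sr, cr]])
    return rz @ ry @ rx


def generate_plant(config: PlantConfig) -> PlantModel:
    """Deterministically build a plant model for the given configuration.

    The same ``seed`` yields the same plant individual across ``day_index``
    values: per-leaf attributes are drawn from streams keyed by leaf index,
    so a day series shows the *same* plant growing (existing leaves scale by
    ``growth_rate`` per day, 1–2 new leaves appear per day).
    """
    config.validate()
    day = config.day_index
    g = config.growth_rate ** day

    # leaf appearance schedule: 1-2 new leaves per elapsed day
    growth_rng = _rng_for(config.seed, 1)
    increments = growth_rng.integers(1, 3, size=max(day, 1))[:day]
    n_leaves_eff = config.n_leaves + int(increments.sum())
    appearance_day = [0] * config.n_leaves
    for d, inc in enumerate(increments, start=1):
        appearance_day += [d] * int(inc)

    node_z = config.stem_height * g
    stem_top_z = 1.4 * node_z
    bow_azimuth = float(_rng_for(config.seed, 2).uniform(0.0, 2.0 * np.pi))
    bow = config.stem_curvature

    def spine_point(z: np.ndarray) -> np.ndarray:
        lateral = bow * np.sin(np.pi * np.asarray(z) / stem_top_z)
        return np.stack([lateral * math.cos(bow_azimuth),
                         lateral * math.sin(bow_azimuth),
                         np.asarray(z, dtype=np.float64)], axis=-1)

    zs = np.linspace(0.0, stem_top_z, max(int(stem_top_z / 2.0), 8) + 1)
    spine = spine_point(zs)
    base_point = spine_point(np.array(0.0))
    node_point = spine_point(np.array(node_z))

    n_cotyledons = min(2, n_leaves_eff)
    n_upper_leaves = n_leaves_eff - n_cotyledons
    n_branches_eff = max(config.n_branches, n_upper_leaves)

    branches: List[Tuple[np.ndarray, float]] = []
    branch_tips: List[np.ndarray] = []
    branch_dirs: List[np.ndarray] = []
    for j in range(n_branches_eff):
        brng = _rng_for(config.seed, 3, j)
        if n_branches_eff > 1:
            z_j = node_z + (j / (n_branches_eff - 1)) * (stem_top_z - node_z) * 0.95
        else:
            z_j = node_z
        azim = j * _GOLDEN_ANGLE + brng.uniform(-0.3, 0.3)
        elev = brng.uniform(np.deg2rad(10.0), np.deg2rad(35.0))
        length = (12.0 + 8.0 * brng.uniform()) * g
        direction = np.array([math.cos(azim) * math.cos(elev),
                              math.sin(azim) * math.cos(elev),
                              math.sin(elev)])
        start = spine_point(np.array(z_j))
        t = np.linspace(0.0, 1.0, 6)
        droop = 0.08 * length * t ** 2  # slight downward sag toward the tip
        curve = start + np.outer(t * length, direction)
        curve[:, 2] -= droop
        radius = 0.5 * config.stem_radius * g ** 0.5
        branches.append((curve, radius))
        branch_tips.append(curve[-1])
        branch_dirs.append(direction)

    leaves: List[LeafPatch] = []
    lo, hi = config.leaf_size_range
    for i in range(n_leaves_eff):
        lrng = _rng_for(config.seed, 4, i)
        a0 = float(lrng.uniform(lo, hi))
        eps = float(lrng.uniform(0.03, 0.08))
        k = int(lrng.integers(5, 10))
        bend = float(np.clip(config.leaf_bend * lrng.uniform(0.7, 1.3), 0.0, 1.0))
        crook = config.leaf_crookedness * float(lrng.uniform(0.5, 1.5))
        freq = (float(lrng.uniform(0.6, 1.4)), float(lrng.uniform(0.6, 1.4)))
        phase = (float(lrng.uniform(0.0, 2.0 * np.pi)), float(lrng.uniform(0.0, 2.0 * np.pi)))
        growth = config.growth_rate ** (day - appearance_day[i])
        roll = float(lrng.uniform(-0.35, 0.35))
        if i < n_cotyledons:
            # cotyledon pair: small, nearly flat, directly on the stem below the node
            size = 0.55 * a0 * growth
            attach = spine_point(np.array(0.85 * node_z))
            azim = i * np.pi + float(lrng.uniform(-0.2, 0.2))
            pitch = float(lrng.uniform(np.deg2rad(5.0), np.deg2rad(20.0)))
            rot = _rotation_from_angles(azim, pitch, roll)
            leaves.append(LeafPatch(
                leaf_id=i, attach=attach, rotation=rot, size=size,
                serration_eps=eps, serration_k=k, bend=min(bend, 0.2),
                crook_amp=0.3 * crook * growth, crook_freq=freq, crook_phase=phase))
        else:
            j = (i - n_cotyledons) % n_branches_eff
            size = a0 * growth
            attach = branch_tips[j]
            d = branch_dirs[j]
            azim = math.atan2(d[1], d[0]) + float(lrng.uniform(-0.25, 0.25))
            pitch = float(lrng.uniform(np.deg2rad(10.0), np.deg2rad(40.0)))
            rot = _rotation_from_angles(azim, pitch, roll)
            leaves.append(LeafPatch(
                leaf_id=i, attach=attach, rotation=rot, size=size,
                serration_eps=eps, serration_k=k, bend=bend,
                crook_amp=crook * growth, crook_freq=freq, crook_phase=phase))

    return PlantModel(
        stem_spine=spine, stem_radius=config.stem_radius * g ** 0.5,
        base_point=base_point, node_point=node_point,
        branches=branches, leaves=leaves,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def true_parameters(model: PlantModel, *, quad_n: int = 256,
                    hull_spacing: float = 0.1) -> GroundTruth:
    """Analytic phenotype of a model.

    Leaf areas come from quadrature of the patch parameterization
    (relative convergence well below 0.05 % at the default ``quad_n``);
    main-stem height is the base-to-cotyledon-node distance; the hull
    volume is computed from a dense (``hull_spacing``) noise-free surface
    sampling, which is what any finitely-sampling sensor can see at best.
    All values are invariant under rigid motion of the model; under uniform
    scaling by ``s`` they scale as s^2 (areas), s (height), s^3 (volume).
    """
    areas = tuple(leaf.area(n=quad_n) for leaf in model.leaves)
    height = float(np.linalg.norm(model.node_point - model.base_point))
    pts = dense_surface_points(model, hull_spacing)
    volume = _chunked_hull_volume(pts) / 1e6  # mm^3 -> dm^3
    return GroundTruth(
        single_leaf_areas=areas,
        cumulated_leaf_area=float(sum(areas)),
        main_stem_height=height,
        convex_hull_volume=volume,
        leaf_ids=tuple(leaf.leaf_id for leaf in model.leaves),
    )


def _chunked_hull_volume(points: np.ndarray, chunk: int = 120_000) -> float:
    """Convex-hull volume of a large point set via hull-of-chunk-hulls.

    hull(S) = hull(union of hull vertices of any partition of S), so the
    reduction is exact.
    """
    if len(points) <= chunk:
        return float(ConvexHull(points).volume)
    keep = []
    for start in range(0, len(points), chunk):
        part = points[start:start + chunk]
        if len(part) >= 4:
            keep.append(part[ConvexHull(part).vertices])
        else:
            keep.append(part)
    return float(ConvexHull(np.vstack(keep)).volume)


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

def _leaf_outline_flat(patch: LeafPatch, spacing: float) -> np.ndarray:
    """Flat-domain points along the outline at ~arc-length ``spacing``."""
    theta = np.linspace(-np.pi, np.pi, 4096)
    r = patch.outline_radius(theta)
    xy = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < spacing:
        return xy[:1]
    s = np.arange(0.0, total, spacing)
    return np.stack([np.interp(s, cum, xy[:, 0]), np.interp(s, cum, xy[:, 1])], axis=1)


def _leaf_interior_flat(patch: LeafPatch, spacing: float,
                        jitter: float, rng: Optional[np.random.Generator]) -> np.ndarray:
    theta = np.linspace(-np.pi, np.pi, 2048)
    r = patch.outline_radius(theta)
    xs = r * np.cos(theta)
    ys = r * np.sin(theta)
    gx = np.arange(xs.min(), xs.max() + spacing, spacing)
    gy = np.arange(ys.min(), ys.max() + spacing, spacing)
    if len(gx) == 0 or len(gy) == 0:
        return np.empty((0, 2))
    grid_x, grid_y = np.meshgrid(gx, gy)
    pts = np.stack([grid_x.ravel(), grid_y.ravel()], axis=1)
    if jitter > 0 and rng is not None:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    rad = np.hypot(pts[:, 0], pts[:, 1])
    keep = rad <= patch.outline_radius(ang) - 0.35 * spacing
    return pts[keep]


def _sample_leaf(patch: LeafPatch, spacing: float, jitter: float,
                 rng: Optional[np.random.Generator]
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World samples of one leaf: (points, normals, is_border flag).

    The outline ring is sampled at half the interior spacing: leaf borders
    are high-gradient image regions that reconstruct densely (and a laser
    line scan does not thin out at a physical edge), and the denser ring
    keeps the meshed area faithful to the outline.
    """
    interior = _leaf_interior_flat(patch, spacing, jitter, rng)
    ring = _leaf_outline_flat(patch, 0.5 * spacing)
    flat = np.vstack([interior, ring]) if len(interior) else ring
    border = np.zeros(len(flat), dtype=bool)
    border[len(interior):] = True
    pts = patch.surface(flat[:, 0], flat[:, 1])
    normals = patch.surface_normal(flat[:, 0], flat[:, 1])
    return pts, normals, border


def _sample_tube(curve: np.ndarray, radius: float, spacing: float,
                 jitter: float, rng: Optional[np.random.Generator]) -> np.ndarray:
    """World samples on the mantle of a tube swept along a polyline."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return np.empty((0, 3))
    t = np.arange(0.0, total + 0.5 * spacing, spacing)
    centers = np.stack([np.interp(t, cum, curve[:, i]) for i in range(3)], axis=1)
    # tangents by finite differences along the resampled spine
    tangents = np.gradient(centers, axis=0)
    tangents /= np.maximum(np.linalg.norm(tangents, axis=1, keepdims=True), 1e-12)
    ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(tangents, ref)
    bad = np.linalg.norm(n1, axis=1) < 1e-6
    n1[bad] = np.cross(tangents[bad], np.array([0.0, 1.0, 0.0]))
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    m = max(int(round(2.0 * np.pi * radius / spacing)), 3)
    phases = (rng.uniform(0.0, 2.0 * np.pi, size=len(centers))
              if (rng is not None and jitter > 0) else np.zeros(len(centers)))
    angles = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    cos_a = np.cos(angles[None, :] + phases[:, None])
    sin_a = np.sin(angles[None, :] + phases[:, None])
    pts = (centers[:, None, :]
           + radius * (cos_a[..., None] * n1[:, None, :] + sin_a[..., None] * n2[:, None, :]))
    pts = pts.reshape(-1, 3)
    if jitter > 0 and rng is not None:
        # axial jitter along the tube direction
        tan = np.repeat(tangents, m, axis=0)
        pts = pts + tan * rng.uniform(-jitter, jitter, size=(len(pts), 1))
    return pts


def dense_surface_points(model: PlantModel, spacing: float) -> np.ndarray:
    """Noise-free surface sampling of every organ at the given spacing (mm)."""
    parts = [_sample_tube(model.stem_spine, model.stem_radius, spacing, 0.0, None)]
    for curve, radius in model.branches:
        parts.append(_sample_tube(curve, radius, spacing, 0.0, None))
    for leaf in model.leaves:
        pts, _, _ = _sample_leaf(leaf, spacing, 0.0, None)
        parts.append(pts)
    return np.vstack([p for p in parts if len(p)])


def _reference_frame_points(spacing: float, rng: np.random.Generator
                            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rectangular table frame below the plant; returns (points, corner A, corner B).

    Corners A and B span one long edge: their true separation is
    ``TABLE_LENGTH_MM`` — the feature later used for metric rescaling.
    """
    hx, hy = TABLE_LENGTH_MM / 2.0, TABLE_WIDTH_MM / 2.0
    band = 3.0
    step = max(spacing, 2.0)
    xs = np.arange(-hx, hx + step, step)
    ys = np.arange(-hy, hy + step, step)
    rows = []
    for offset in (-band / 2.0, band / 2.0):
        rows.append(np.stack([xs, np.full_like(xs, -hy + offset)], axis=1))
        rows.append(np.stack([xs, np.full_like(xs, hy + offset)], axis=1))
        rows.append(np.stack([np.full_like(ys, -hx + offset), ys], axis=1))
        rows.append(np.stack([np.full_like(ys, hx + offset), ys], axis=1))
    xy = np.vstack(rows)
    corner_a = np.array([-hx, -hy, TABLE_Z_MM])
    corner_b = np.array([hx, -hy, TABLE_Z_MM])
    pts = np.column_stack([xy, np.full(len(xy), TABLE_Z_MM)])
    pts = np.vstack([pts, corner_a, corner_b])
    return pts, corner_a, corner_b


def _smooth_noise_field(points: np.ndarray, sigma: float, length: float,
                        rng: np.random.Generator, n_features: int = 96) -> np.ndarray:
    """Gaussian random field (RBF covariance, pointwise per-axis std sigma)."""
    disp = np.empty_like(points)
    for axis in range(3):
        omega = rng.normal(0.0, 1.0 / length, size=(n_features, 3))
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
        proj = points @ omega.T + phase
        disp[:, axis] = sigma * math.sqrt(2.0 / n_features) * np.cos(proj).sum(axis=1)
    return disp


def _organ_colors(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Textured plant-green (or white/grey for artifacts) RGB uint8 colors."""
    if kind == "leaf":
        h = rng.uniform(0.26, 0.34, n)
        s = rng.uniform(0.45, 0.75, n)
        v = rng.uniform(0.35, 0.65, n)
    elif kind == "stem":
        h = rng.uniform(0.20, 0.30, n)
        s = rng.uniform(0.40, 0.60, n)
        v = rng.uniform(0.30, 0.50, n)
    elif kind == "artifact":
        h = rng.uniform(0.0, 1.0, n)
        s = rng.uniform(0.0, 0.08, n)
        v = rng.uniform(0.65, 1.0, n)
    elif kind == "frame":
        h = rng.uniform(0.0, 1.0, n)
        s = rng.uniform(0.0, 0.10, n)
        v = rng.uniform(0.6, 0.9, n)
    else:  # pragma: no cover - defensive
        raise ValueError(kind)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=1))
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def sample_sensor(model: PlantModel, profile: SensorProfile, seed: int) -> PointCloud:
    """Render a plant model into a sensor-specific point cloud.

    The output carries true organ labels and an artifact flag for evaluation
    only; measurement stages must not read them unless explicitly run in
    label (oracle) mode.  Photogrammetric output is globally multiplied by
    ``profile.scale_factor`` and includes the reference table frame whose
    long-edge corners (and true length) are recorded in
    ``cloud.metadata["reference"]`` for later rescaling.
    """
    profile.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(17,)))

    if profile.point_budget is not None:
        total_area = model.total_surface_area()
        spacing = math.sqrt(max(total_area, 1e-9) / profile.point_budget)
    else:
        spacing = profile.target_spacing
    jitter = 0.25 * spacing

    coords: List[np.ndarray] = []
    labels: List[np.ndarray] = []
    kinds: List[Tuple[str, int]] = []   # (color kind, count) in order

    stem_pts = _sample_tube(model.stem_spine, model.stem_radius, spacing, jitter, rng)
    coords.append(stem_pts)
    labels.append(np.full(len(stem_pts), LABEL_STEM, dtype=np.int32))
    kinds.append(("stem", len(stem_pts)))
    for curve, radius in model.branches:
        pts = _sample_tube(curve, radius, spacing, jitter, rng)
        coords.append(pts)
        labels.append(np.full(len(pts), LABEL_BRANCH, dtype=np.int32))
        kinds.append(("stem", len(pts)))

    leaf_areas = [leaf.area(n=64) for leaf in model.leaves]
    small_cut = (np.quantile(leaf_areas, 1.0 / 3.0) if leaf_areas else 0.0)
    border_pts_all: List[np.ndarray] = []
    border_normals_all: List[np.ndarray] = []
    border_labels_all: List[np.ndarray] = []
    for leaf, area in zip(model.leaves, leaf_areas):
        pts, normals, border = _sample_leaf(leaf, spacing, jitter, rng)
        if profile.occlusion_rate > 0 and area <= small_cut and len(pts) > 8:
            # small leaves lose a border-first fraction of their points
            # (filigree structures are hardest for multi-view matching)
            n_drop = int(round(profile.occlusion_rate * len(pts)))
            n_drop = min(n_drop, len(pts) - 4)
            order = np.concatenate([np.flatnonzero(border), np.flatnonzero(~border)])
            drop = order[:n_drop]
            keep_mask = np.ones(len(pts), dtype=bool)
            keep_mask[drop] = False
            pts, normals, border = pts[keep_mask], normals[keep_mask], border[keep_mask]
        label = LEAF_LABEL_BASE + leaf.leaf_id
        coords.append(pts)
        labels.append(np.full(len(pts), label, dtype=np.int32))
        kinds.append(("leaf", len(pts)))
        border_pts_all.append(pts[border])
        border_normals_all.append(normals[border])
        border_labels_all.append(np.full(int(border.sum()), label, dtype=np.int32))

    n_border = int(sum(len(b) for b in border_pts_all))
    artifact_coords = np.empty((0, 3))
    artifact_labels = np.empty(0, dtype=np.int32)
    n_artifact_sources = 0
    if profile.artifact_rate > 0 and n_border > 0:
        # each Bernoulli-selected border point spawns a small white/grey
        # cluster offset along the surface normal: false matches against a
        # bright background form dense mats at borders, not isolated points
        bp = np.vstack(border_pts_all)
        bn = np.vstack(border_normals_all)
        bl = np.concatenate(border_labels_all)
        pick = rng.random(n_border) < profile.artifact_rate
        n_artifact_sources = int(pick.sum())
        if n_artifact_sources:
            counts = rng.integers(3, 8, size=n_artifact_sources)
            src = np.repeat(np.flatnonzero(pick), counts)
            side = np.where(rng.random(n_artifact_sources) < 0.5, 1.0, -1.0)
            offset = profile.artifact_offset * (
                1.0 + 0.3 * rng.standard_normal(n_artifact_sources))
            centers = bp[pick] + bn[pick] * (side * offset)[:, None]
            centers = np.repeat(centers, counts, axis=0)
            artifact_coords = centers + rng.normal(0.0, 0.6, size=(len(src), 3))
            artifact_labels = bl[src]

    n_plant = int(sum(len(c) for c in coords))
    all_coords = np.vstack(coords + [artifact_coords]) if n_plant else artifact_coords
    all_labels = np.concatenate(labels + [artifact_labels])
    flags = np.zeros(len(all_coords), dtype=bool)
    flags[n_plant:] = True

    # colors (before noise; texture jitter is independent of geometry)
    color_parts = []
    for kind, count in kinds:
        color_parts.append(_organ_colors(kind, count, rng))
    color_parts.append(_organ_colors("artifact", len(artifact_coords), rng))
    all_colors = np.vstack(color_parts) if len(all_coords) else np.empty((0, 3), np.uint8)

    # measurement noise: a correlated field (reconstruction error varies
    # smoothly over the surface) plus optional residual per-point jitter;
    # with no correlation length the noise is purely i.i.d. per point
    if len(all_coords):
        if profile.noise_sigma > 0 and profile.noise_correlation_mm > 0:
            all_coords = all_coords + _smooth_noise_field(
                all_coords, profile.noise_sigma, profile.noise_correlation_mm, rng)
        elif profile.noise_sigma > 0:
            all_coords = all_coords + rng.normal(0.0, profile.noise_sigma,
                                                 size=all_coords.shape)
        if profile.noise_iid_sigma > 0:
            all_coords = all_coords + rng.normal(0.0, profile.noise_iid_sigma,
                                                 size=all_coords.shape)

    metadata = {"n_border_candidates": n_border,
                "n_artifact_sources": n_artifact_sources,
                "sensor": profile.name,
                "spacing_mm": spacing}

    if profile.include_reference_frame:
        frame_pts, corner_a, corner_b = _reference_frame_points(spacing, rng)
        if profile.noise_sigma > 0:
            frame_noise = rng.normal(0.0, profile.noise_sigma, size=frame_pts.shape)
            frame_pts = frame_pts + frame_noise
            corner_a = frame_pts[-2]
            corner_b = frame_pts[-1]
        all_coords = np.vstack([all_coords, frame_pts])
        all_labels = np.concatenate([all_labels,
                                     np.full(len(frame_pts), LABEL_NONPLANT, np.int32)])
        flags = np.concatenate([flags, np.zeros(len(frame_pts), dtype=bool)])
        all_colors = np.vstack([all_colors, _organ_colors("frame", len(frame_pts), rng)])
        metadata["reference"] = {
            "corner_a": (corner_a * profile.scale_factor).tolist(),
            "corner_b": (corner_b * profile.scale_factor).tolist(),
            "true_length_mm": TABLE_LENGTH_MM,
        }

    s = profile.scale_factor
    unit = UnitState.MILLIMETERS if abs(s - 1.0) < 1e-12 else UnitState.ARBITRARY
    return PointCloud(all_coords * s, colors=all_colors, labels=all_labels,
                      artifact_flags=flags, unit_state=unit, metadata=metadata)
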