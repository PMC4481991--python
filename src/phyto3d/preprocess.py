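"""Point-cloud preparation: metric scaling, cropping, outlier and false-point
removal, rasterization to homogeneous spacing.

The chain mirrors the preparation a phenotyping lab applies before organ
measurement: photogrammetric clouds are first brought to millimeters using a
known reference length (the scale factor is the ratio of the feature's true
millimeter length to its length in the unscaled cloud), irrelevant scene
objects (table, nourishment cube) are cropped away, statistical outliers and
white/grey false border points are removed, and laser clouds are rasterized
to a homogeneous 0.5 mm point-to-point distance.  All manual editing steps
are replaced by parameterized, reproducible filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from matplotlib.colors import rgb_to_hsv
from scipy.spatial import cKDTree

from .cloud import LABEL_NONPLANT, PointCloud, UnitState

__all__ = [
    "ScaleReference", "ColorFilterSpec", "PrepParams",
    "scale_to_mm", "rasterize", "remove_outliers", "filter_colors",
    "crop_to_plant", "prepare",
    "PreprocessError", "OverCroppingError",
]


class PreprocessError(ValueError):
    pass


class OverCroppingError(PreprocessError):
    """Cropping removed every point — the crop parameters do not fit the scene."""


@dataclass(frozen=True)
class ScaleReference:
    """A known feature length: measured in cloud units vs true millimeters."""

    measured_length: float
    true_length_mm: float

    def scale_factor(self) -> float:
        if self.measured_length <= 0:
            raise PreprocessError("measured_length must be > 0")
        if self.true_length_mm <= 0:
            raise PreprocessError("true_length_mm must be > 0")
        return self.true_length_mm / self.measured_length


@dataclass(frozen=True)
class ColorFilterSpec:
    """White/grey removal region in HSV: saturation <= max_saturation AND
    value >= min_value.  Defaults catch pure white and mid-grey while leaving
    saturated plant greens untouched."""

    max_saturation: float = 0.15
    min_value: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.max_saturation <= 1.0:
            raise PreprocessError("max_saturation must be in [0, 1]")
        if not 0.0 <= self.min_value <= 1.0:
            raise PreprocessError("min_value must be in [0, 1]")


def scale_to_mm(cloud: PointCloud, ref: ScaleReference) -> PointCloud:
    """Multiply all coordinates (about the origin) by true/measured.

    Precondition: the cloud is still arbitrarily scaled.  The applied factor
    is recorded in ``metadata["scale_factor_applied"]``.
    """
    if cloud.unit_state is not UnitState.ARBITRARY:
        raise PreprocessError("scale_to_mm expects an arbitrarily scaled cloud")
    s = ref.scale_factor()
    out = cloud.with_coordinates(cloud.coordinates * s, unit_state=UnitState.MILLIMETERS)
    out.metadata["scale_factor_applied"] = s
    ref_meta = out.metadata.get("reference")
    if isinstance(ref_meta, dict):
        scaled_ref = dict(ref_meta)
        for key in ("corner_a", "corner_b"):
            if key in scaled_ref:
                scaled_ref[key] = (np.asarray(scaled_ref[key]) * s).tolist()
        out.metadata["reference"] = scaled_ref
    return out


def rasterize(cloud: PointCloud, spacing_mm: float = 0.5) -> PointCloud:
    """Resample to homogeneous spacing by a voxel-grid partition.

    One representative per occupied cubic cell (edge ``spacing_mm``, grid
    anchored at the cloud's minimum corner): member centroid, majority label
    and artifact flag, per-channel mean color.
    """
    if spacing_mm <= 0:
        raise PreprocessError("spacing_mm must be > 0")
    if cloud.unit_state is not UnitState.MILLIMETERS:
        raise PreprocessError("rasterize expects a metrically scaled cloud")
    if cloud.n == 0:
        return cloud.select(np.zeros(0, dtype=bool))
    origin = cloud.coordinates.min(axis=0)
    idx = np.floor((cloud.coordinates - origin) / spacing_mm).astype(np.int64)
    # one flat key per cell, stable under permutation of input points
    dims = idx.max(axis=0) + 1
    keys = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]
    cells, inverse = np.unique(keys, return_inverse=True)
    n_cells = len(cells)
    counts = np.bincount(inverse, minlength=n_cells).astype(np.float64)
    centroid = np.empty((n_cells, 3))
    for axis in range(3):
        centroid[:, axis] = np.bincount(inverse, weights=cloud.coordinates[:, axis],
                                        minlength=n_cells) / counts

    colors = None
    if cloud.colors is not None:
        colors = np.empty((n_cells, 3), dtype=np.uint8)
        for c in range(3):
            mean = np.bincount(inverse, weights=cloud.colors[:, c].astype(np.float64),
                               minlength=n_cells) / counts
            colors[:, c] = np.clip(np.round(mean), 0, 255).astype(np.uint8)

    labels = None
    if cloud.labels is not None:
        labels = _majority_per_group(inverse, cloud.labels, n_cells)

    flags = None
    if cloud.artifact_flags is not None:
        frac = np.bincount(inverse, weights=cloud.artifact_flags.astype(np.float64),
                           minlength=n_cells) / counts
        flags = frac > 0.5

    out = PointCloud(centroid, colors=colors, labels=labels, artifact_flags=flags,
                     unit_state=cloud.unit_state, metadata=dict(cloud.metadata))
    return out


def _majority_per_group(groups: np.ndarray, values: np.ndarray, n_groups: int) -> np.ndarray:
    """Majority vote of ``values`` within each group (ties -> smaller value)."""
    order = np.lexsort((values, groups))
    g, v = groups[order], values[order]
    # count identical (group, value) runs
    boundary = np.concatenate([[True], (g[1:] != g[:-1]) | (v[1:] != v[:-1])])
    run_start = np.flatnonzero(boundary)
    run_group = g[run_start]
    run_value = v[run_start]
    run_len = np.diff(np.concatenate([run_start, [len(g)]]))
    out = np.zeros(n_groups, dtype=values.dtype)
    best = np.full(n_groups, -1)
    for grp, val, ln in zip(run_group, run_value, run_len):
        if ln > best[grp]:
            best[grp] = ln
            out[grp] = val
    return out


def remove_outliers(cloud: PointCloud, k: int = 16, n_sigma: float = 2.5) -> PointCloud:
    """Drop points whose mean k-nearest-neighbor distance is anomalous.

    The threshold is ``global mean + n_sigma * global std`` of the per-point
    statistic — the standard statistical-outlier-removal rule.  The removed
    count is recorded in ``metadata["outliers_removed"]``.
    """
    if cloud.n <= k:
        raise PreprocessError(f"need more than k={k} points, got {cloud.n}")
    tree = cKDTree(cloud.coordinates)
    dist, _ = tree.query(cloud.coordinates, k=k + 1)
    mean_dist = dist[:, 1:].mean(axis=1)
    mu, sd = mean_dist.mean(), mean_dist.std()
    # relative epsilon keeps degenerate zero-variance statistics (perfectly
    # regular point sets) from being split by floating-point jitter
    keep = mean_dist <= mu + n_sigma * sd + 1e-12 * mu
    out = cloud.select(keep)
    out.metadata["outliers_removed"] = int(cloud.n - out.n)
    return out


def filter_colors(cloud: PointCloud, spec: ColorFilterSpec = ColorFilterSpec()) -> PointCloud:
    """Remove white/grey points (hexcone HSV: low saturation, high value).

    Surviving points keep their order, coordinates and colors.
    """
    spec.validate()
    if cloud.colors is None:
        raise PreprocessError("filter_colors requires a cloud with colors")
    if cloud.n == 0:
        return cloud.select(np.zeros(0, dtype=bool))
    hsv = rgb_to_hsv(cloud.colors.astype(np.float64) / 255.0)
    white_grey = (hsv[:, 1] <= spec.max_saturation) & (hsv[:, 2] >= spec.min_value)
    out = cloud.select(~white_grey)
    out.metadata["color_filtered"] = int(white_grey.sum())
    return out


def crop_to_plant(cloud: PointCloud, base_plane_z: float = 0.0,
                  max_radius: Optional[float] = None,
                  mode: str = "geometric") -> PointCloud:
    """Remove scene objects (table, nourishment cube) around the plant.

    ``geometric`` keeps points with ``z >= base_plane_z`` and, if
    ``max_radius`` is set, within that distance of the vertical axis through
    the kept points' centroid.  ``labels`` is an oracle mode that keeps
    exactly the plant-labeled points of a synthetic cloud.
    """
    if cloud.unit_state is not UnitState.MILLIMETERS:
        raise PreprocessError("crop_to_plant expects a metrically scaled cloud")
    if mode == "labels":
        if cloud.labels is None:
            raise PreprocessError("labels crop mode requires labels")
        keep = cloud.labels != LABEL_NONPLANT
    elif mode == "geometric":
        keep = cloud.coordinates[:, 2] >= base_plane_z
        if max_radius is not None and keep.any():
            center = cloud.coordinates[keep, :2].mean(axis=0)
            radial = np.linalg.norm(cloud.coordinates[:, :2] - center, axis=1)
            keep = keep & (radial <= max_radius)
    else:
        raise PreprocessError(f"unknown crop mode {mode!r}")
    if not keep.any():
        raise OverCroppingError("cropping removed every point")
    out = cloud.select(keep)
    out.metadata["cropped_away"] = int(cloud.n - out.n)
    return out


@dataclass(frozen=True)
class PrepParams:
    """Parameters of the full preparation chain (see ``prepare``)."""

    raster_spacing_mm: Optional[float] = 0.5    # applied only when rasterize=True
    outlier_k: int = 16
    outlier_n_sigma: float = 2.5
    color_filter: bool = True
    color_spec: ColorFilterSpec = field(default_factory=ColorFilterSpec)
    base_plane_z: float = 0.0
    crop_radius: Optional[float] = None
    crop_mode: str = "geometric"


def prepare(cloud: PointCloud, params: PrepParams = PrepParams(),
            ref: Optional[ScaleReference] = None,
            rasterize_cloud: bool = False) -> Tuple[PointCloud, dict]:
    """Full preparation chain: scale -> crop -> outliers -> colors -> [raster].

    Scaling runs only for arbitrarily scaled clouds; if no ``ref`` is given
    the embedded reference-object corners in ``cloud.metadata["reference"]``
    are measured (Euclidean corner distance vs true edge length).
    Rasterization is the laser-path finishing step.  Returns the prepared
    cloud and a log dict of the scale factor and per-stage removal counts.
    """
    log: dict = {"n_input": cloud.n}
    if cloud.unit_state is UnitState.ARBITRARY:
        if ref is None:
            meta = cloud.metadata.get("reference")
            if not meta:
                raise PreprocessError(
                    "cloud is arbitrarily scaled but no reference length is available")
            measured = float(np.linalg.norm(
                np.asarray(meta["corner_a"]) - np.asarray(meta["corner_b"])))
            ref = ScaleReference(measured_length=measured,
                                 true_length_mm=float(meta["true_length_mm"]))
        cloud = scale_to_mm(cloud, ref)
        log["scale_factor"] = cloud.metadata["scale_factor_applied"]

    cloud = crop_to_plant(cloud, base_plane_z=params.base_plane_z,
                          max_radius=params.crop_radius, mode=params.crop_mode)
    log["cropped_away"] = cloud.metadata.get("cropped_away", 0)

    if cloud.n > params.outlier_k:
        cloud = remove_outliers(cloud, k=params.outlier_k, n_sigma=params.outlier_n_sigma)
        log["outliers_removed"] = cloud.metadata.get("outliers_removed", 0)

    if params.color_filter and cloud.colors is not None:
        cloud = filter_colors(cloud, params.color_spec)
        log["color_filtered"] = cloud.metadata.get("color_filtered", 0)

    if rasterize_cloud and params.raster_spacing_mm:
        n_before = cloud.n
        cloud = rasterize(cloud, params.raster_spacing_mm)
        log["rasterized_from"] = n_before
    log["n_output"] = cloud.n
    return cloud, log
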