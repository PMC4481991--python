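"""In-memory point-cloud container with optional color / label / artifact channels.

Coordinates are kept as an ``(n, 3)`` float64 array.  The semantic unit of the
coordinates is tracked explicitly (``UnitState``): laser clouds come out of the
sensor metrically scaled, photogrammetric reconstructions are arbitrarily
scaled until a known reference length has been applied.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "UnitState",
    "PointCloud",
    "LABEL_NONPLANT",
    "LABEL_STEM",
    "LABEL_BRANCH",
    "LEAF_LABEL_BASE",
]

# Organ label conventions used by the synthetic generator and the
# label-based segmentation mode.
LABEL_NONPLANT = 0   # table / reference frame / other scene objects
LABEL_STEM = 1
LABEL_BRANCH = 2
LEAF_LABEL_BASE = 10  # leaf i carries label LEAF_LABEL_BASE + i


class UnitState(str, enum.Enum):
    ARBITRARY = "arbitrary"
    MILLIMETERS = "millimeters"


class CloudValidationError(ValueError):
    """A point cloud violates a structural invariant."""


@dataclass
class PointCloud:
    """Points with optional per-point RGB color, organ label and artifact flag.

    Parameters
    ----------
    coordinates:
        ``(n, 3)`` array of finite reals.
    colors:
        optional ``(n, 3)`` uint8 RGB.
    labels:
        optional ``(n,)`` integer organ ids (see module-level label constants).
    artifact_flags:
        optional ``(n,)`` booleans marking simulated false points
        (evaluation-only channel; measurement stages must not read it).
    unit_state:
        whether coordinates are metric millimeters or still arbitrary.
    metadata:
        free-form sidecar (e.g. embedded reference-object corners).  Not
        persisted by the PLY/XYZ writers.
    """

    coordinates: np.ndarray
    colors: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    artifact_flags: Optional[np.ndarray] = None
    unit_state: UnitState = UnitState.ARBITRARY
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.size == 0:
            self.coordinates = self.coordinates.reshape(0, 3)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise CloudValidationError(
                f"coordinates must be (n, 3), got {self.coordinates.shape}"
            )
        if not np.isfinite(self.coordinates).all():
            raise CloudValidationError("coordinates contain non-finite values")
        n = len(self.coordinates)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(n, 3)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int32).reshape(n)
        if self.artifact_flags is not None:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool).reshape(n)
        if isinstance(self.unit_state, str):
            self.unit_state = UnitState(self.unit_state)

    @property
    def n(self) -> int:
        return len(self.coordinates)

    def __len__(self) -> int:
        return self.n

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask (or index array); all channels follow."""
        return PointCloud(
            coordinates=self.coordinates[mask],
            colors=None if self.colors is None else self.colors[mask],
            labels=None if self.labels is None else self.labels[mask],
            artifact_flags=None
            if self.artifact_flags is None
            else self.artifact_flags[mask],
            unit_state=self.unit_state,
            metadata=dict(self.metadata),
        )

    def with_coordinates(self, coordinates: np.ndarray,
                         unit_state: Optional[UnitState] = None) -> "PointCloud":
        """Same channels, new coordinates (e.g. after a similarity transform)."""
        return PointCloud(
            coordinates=coordinates,
            colors=self.colors,
            labels=self.labels,
            artifact_flags=self.artifact_flags,
            unit_state=self.unit_state if unit_state is None else unit_state,
            metadata=dict(self.metadata),
        )
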