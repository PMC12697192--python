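"""Labelled 3D point sets (millimetres, lab frame)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointSet"]


@dataclass
class PointSet:
    """A set of labelled 3D points in millimetres.

    Labels identify material points (tantalum bead ids, implant-surface
    sample ids) so that the same physical point can be matched across
    examinations. Coordinates are lab-frame, right-handed, in mm.
    """

    coords: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.labels is None:
            self.labels = np.array([f"p{i}" for i in range(len(self.coords))])
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.coords):
                raise ValueError("labels and coords length mismatch")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("duplicate labels in PointSet")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def subset(self, labels) -> "PointSet":
        index = {lab: i for i, lab in enumerate(self.labels)}
        idx = [index[lab] for lab in labels]
        return PointSet(self.coords[idx].copy(), np.asarray(labels, dtype=object))

    def match(self, other: "PointSet") -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of the points whose labels occur in both sets.

        Returns (self_coords, other_coords) in a common label order.
        """
        common = [lab for lab in self.labels if lab in set(other.labels)]
        if not common:
            raise ValueError("no common labels between point sets")
        return self.subset(common).coords, other.subset(common).coords

    def mirrored(self, axis: int = 0) -> "PointSet":
        """Reflection through the plane normal to `axis` (sagittal for x)."""
        c = self.coords.copy()
        c[:, axis] *= -1.0
        return PointSet(c, self.labels.copy())
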