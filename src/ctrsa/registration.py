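"""Rigid registration of marker sets and implant models.

Implements the measurement core of a radiostereometric migration
pipeline: least-squares orthogonal superposition of matched bead sets
(Kabsch), the two standard RSA quality metrics — the condition number of
the marker configuration and the mean error (ME) of rigid-body fitting —
and iterative-closest-point (ICP) fitting of an implant surface model to
an observed point cloud.

Quality thresholds follow standard RSA practice: marker configurations
with condition number >= 120 are flagged as too collinear, and exam
pairs with ME >= 0.35 mm are flagged as having unstable markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pointset import PointSet

__all__ = [
    "RigidTransform",
    "FitResult",
    "DegenerateFitError",
    "fit_rigid",
    "mean_error",
    "condition_number",
    "fit_model_pose",
    "CN_THRESHOLD",
    "ME_THRESHOLD",
    "CN_CAP",
]

#: marker-spread acceptance threshold (dimensionless)
CN_THRESHOLD = 120.0
#: marker-stability acceptance threshold (mm, RMS rigid-body residual)
ME_THRESHOLD = 0.35
#: cap reported for numerically singular configurations
CN_CAP = 1e12

_ORTHO_TOL = 1e-9


class DegenerateFitError(ValueError):
    """Raised when a rigid fit is not uniquely determined (collinear or
    too few points)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform p -> R @ p + t (rotation then translation).

    rotation is a 3x3 orthonormal matrix with det +1; translation is in
    mm. Composition and inversion stay within the type.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection is not a rigid transform")
        # re-project onto SO(3) so long composition chains stay orthonormal
        U, _, Vt = np.linalg.svd(R)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        object.__setattr__(self, "rotation", U @ D @ Vt)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_pointset(self, ps: PointSet) -> PointSet:
        return PointSet(self.apply(ps.coords), ps.labels.copy())

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() < tol
            and np.abs(self.translation - other.translation).max() < tol
        )

    # --- serialization (JSON-friendly, row-major rotation) ---
    def to_dict(self) -> dict:
        return {
            "rotation": [list(map(float, row)) for row in self.rotation],
            "translation_mm": list(map(float, self.translation)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation_mm"]))

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        max_rotation_deg: float = 15.0,
        max_translation_mm: float = 50.0,
    ) -> "RigidTransform":
        """Random proper rigid transform, e.g. patient repositioning.

        Rotation axis uniform on the sphere, angle uniform in
        [0, max_rotation_deg]; translation components uniform.
        """
        from scipy.spatial.transform import Rotation

        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
        R = Rotation.from_rotvec(axis * angle).as_matrix()
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        return cls(R, t)


@dataclass
class FitResult:
    """Outcome of a rigid fit with RSA quality metrics attached."""

    transform: RigidTransform
    residuals: np.ndarray
    mean_error: float
    condition_number: float
    converged: bool = True
    n_iterations: int = 0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flags.setdefault("cn_ok", bool(self.condition_number < CN_THRESHOLD))
        self.flags.setdefault("me_ok", bool(self.mean_error < ME_THRESHOLD))


def mean_error(residuals: np.ndarray) -> float:
    """Mean error (ME) of rigid-body fitting: RMS of per-point residual
    distances after optimal superposition, in mm.

    Values above 0.35 mm conventionally indicate that the bead
    configuration was not stable between the two examinations.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residuals")
    return float(np.sqrt(np.mean(r**2)))


def condition_number(points: PointSet | np.ndarray) -> float:
    """Condition number of a marker configuration.

    Ratio of the largest to the smallest singular value of the
    centroid-centred coordinate matrix. Large values mean the beads are
    nearly collinear and rotations about the bead axis are poorly
    determined; configurations >= 120 are conventionally rejected.
    Numerically singular configurations return the cap value (1e12).
    """
    coords = points.coords if isinstance(points, PointSet) else np.asarray(points, float)
    if coords.shape[0] < 3:
        raise DegenerateFitError("condition number needs at least 3 points")
    centred = coords - coords.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[-1] <= s[0] * 1e-12 or s[0] == 0.0:
        return CN_CAP
    return float(min(s[0] / s[-1], CN_CAP))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation + translation mapping src onto dst.

    Standard SVD superposition; if the best orthogonal map is a
    reflection, the sign of the smallest singular direction is flipped so
    a proper rotation is returned.
    """
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    H = (src - src_c).T @ (dst - dst_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst_c - R @ src_c
    return RigidTransform(R, t)


def fit_rigid(src: PointSet, dst: PointSet) -> FitResult:
    """Fit the rigid transform taking `src` onto `dst`, matched by label.

    This is the "rigid alignment" step of RSA: the bead set of the
    reference bone in one examination is superimposed onto the same beads
    in another. The fit minimises the sum of squared distances over
    proper rigid transforms (reflections rejected).

    Raises
    ------
    DegenerateFitError
        Fewer than 3 matched points, or a (near-)collinear configuration
        for which the rotation is not unique.
    """
    s, d = src.match(dst)
    if len(s) < 3:
        raise DegenerateFitError(f"rigid fit needs >= 3 matched points, got {len(s)}")
    # collinear (rank < 2) configurations leave the rotation about the
    # point axis free; planar sets are fine (flagged by the CN gate)
    sv = np.linalg.svd(s - s.mean(axis=0), compute_uv=False)
    if sv[1] <= sv[0] * 1e-12 or sv[0] == 0.0:
        raise DegenerateFitError("collinear marker configuration: rigid fit singular")
    cn = condition_number(s)
    transform = _kabsch(s, d)
    residuals = np.linalg.norm(transform.apply(s) - d, axis=1)
    return FitResult(
        transform=transform,
        residuals=residuals,
        mean_error=mean_error(residuals),
        condition_number=cn,
    )


def fit_model_pose(
    model: "PointSet | np.ndarray",
    cloud: PointSet,
    init: RigidTransform,
    max_iterations: int = 200,
    tolerance_mm: float = 1e-6,
) -> FitResult:
    """Fit an implant surface model to an observed cloud by point-to-point
    ICP (nearest-neighbour correspondence + rigid fit until convergence).

    `model` holds surface samples in the implant model frame; `init` is a
    coarse model->lab pose, in practice obtained from landmark
    correspondence. Convergence is declared when the pose update moves no
    model point by more than `tolerance_mm`.

    ICP is local: a good initial pose is assumed, as when implant
    landmarks have already been located in the scan.
    """
    mpts = model.coords if isinstance(model, PointSet) else np.asarray(model, float)
    if len(cloud) == 0:
        raise ValueError("empty observed cloud")
    if not np.all(np.isfinite(cloud.coords)):
        raise ValueError("non-finite coordinates in cloud")
    pose = init
    tree = cKDTree(cloud.coords)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        placed = pose.apply(mpts)
        _, nearest = tree.query(placed)
        update = _kabsch(placed, cloud.coords[nearest])
        pose = update.compose(pose)
        # largest displacement of any model point under the update
        step = np.linalg.norm(update.apply(placed) - placed, axis=1).max()
        if step < tolerance_mm:
            converged = True
            break
    placed = pose.apply(mpts)
    dists, _ = tree.query(placed)
    return FitResult(
        transform=pose,
        residuals=dists,
        mean_error=mean_error(dists),
        condition_number=condition_number(mpts),
        converged=converged,
        n_iterations=n_iter,
    )
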