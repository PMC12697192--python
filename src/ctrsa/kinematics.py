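"""Coordinate frames and 6-DOF migration between two examinations.

Migration of a hip implant is reported in six degrees of freedom in a
segment-specific anatomic frame: translations Tx/Ty/Tz in mm along the
medial (+x), superior (+y) and anterior (+z) axes, and Cardan rotations
Rx/Ry/Rz in degrees (anterior tilt, internal rotation/anteversion, and
valgus for the stem / decreased inclination for the cup). Euclidean
totals Ttot and Rtot summarise each triple. Results are always reported
in right-hip convention: for left hips Tx, Ry and Rz change sign under
the sagittal mirror, Ty, Tz and Rx do not.

The stem frame is implant-based: y along the stem long axis (tip ->
shoulder), x in the stem/neck plane perpendicular to y, z completing the
right-handed triad. The cup frame uses the scanner-table (lab) axes of
the baseline examination, since the near-spherical cup offers no stable
implant-based frame.

Sign bookkeeping for sides: the frame builder orients x along the
projected neck axis for right hips and opposite to it for left hips, so
that raw left-hip components come out in the mirror-image frame of the
equivalent right hip; `mirror_to_right` then flips Tx, Ry, Rz. With this
pairing, a left scene that is the exact sagittal mirror of a right scene
yields an identical migration table after mirroring — exactly, not only
to first order in the angles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .pointset import PointSet
from .registration import (
    DegenerateFitError,
    FitResult,
    RigidTransform,
    fit_model_pose,
    fit_rigid,
)

__all__ = [
    "AnatomicFrame",
    "MigrationDOF",
    "TRANSLATION_DOFS",
    "ROTATION_DOFS",
    "ALL_DOFS",
    "build_stem_frame",
    "build_table_frame",
    "euclidean_total",
    "mirror_to_right",
    "cardan_from_matrix",
    "matrix_from_cardan",
    "dof_to_frame_transform",
    "transform_in_frame",
    "landmark_init",
    "analyze_pair",
]

TRANSLATION_DOFS = ("Tx", "Ty", "Tz")
ROTATION_DOFS = ("Rx", "Ry", "Rz")
ALL_DOFS = TRANSLATION_DOFS + ROTATION_DOFS + ("Ttot", "Rtot")

#: Cardan sequence: rotations applied about the fixed frame axes in the
#: order x, then y, then z (extrinsic). At the sub-2 degree magnitudes of
#: implant migration the ordering effect is below reporting precision.
_CARDAN_SEQ = "xyz"


@dataclass(frozen=True)
class AnatomicFrame:
    """Right-handed orthonormal frame: origin (mm) and axes as columns
    x, y, z of a 3x3 rotation-like matrix."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.abs(A.T @ A - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame is left-handed (x cross y must equal z)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", A)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


@dataclass(frozen=True)
class MigrationDOF:
    """Six migration components plus Euclidean totals and quality info."""

    Tx: float
    Ty: float
    Tz: float
    Rx: float
    Ry: float
    Rz: float
    side: str = "right"
    segment: str = "stem"
    condition_number: float = float("nan")
    mean_error: float = float("nan")
    flags: tuple = ()
    mirrored: bool = False

    @property
    def Ttot(self) -> float:
        return euclidean_total(self.Tx, self.Ty, self.Tz)

    @property
    def Rtot(self) -> float:
        return euclidean_total(self.Rx, self.Ry, self.Rz)

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.Tx, self.Ty, self.Tz])

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.Rx, self.Ry, self.Rz])

    def as_dict(self) -> dict:
        return {
            "Tx": self.Tx, "Ty": self.Ty, "Tz": self.Tz,
            "Rx": self.Rx, "Ry": self.Ry, "Rz": self.Rz,
            "Ttot": self.Ttot, "Rtot": self.Rtot,
        }


def euclidean_total(x: float, y: float, z: float) -> float:
    """Euclidean total sqrt(x^2 + y^2 + z^2) of three components."""
    v = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite input to euclidean_total")
    return float(np.linalg.norm(v))


def mirror_to_right(dof: MigrationDOF) -> MigrationDOF:
    """Re-express a migration in right-hip convention.

    Right hips are returned unchanged. For left hips the sagittal
    reflection negates the medial translation Tx and the rotations about
    the in-plane axes Ry and Rz, while Ty, Tz and Rx are invariant.
    Totals are unchanged. Applying the rule twice (toggling the side) is
    the identity.
    """
    if dof.side not in ("left", "right"):
        raise ValueError(f"unknown side {dof.side!r}")
    if dof.side == "right" or dof.mirrored:
        return replace(dof, mirrored=True)
    return replace(
        dof, Tx=-dof.Tx, Ry=-dof.Ry, Rz=-dof.Rz, mirrored=True
    )


def build_stem_frame(
    tip: np.ndarray,
    shoulder: np.ndarray,
    neck_point: np.ndarray,
    side: str = "right",
) -> AnatomicFrame:
    """Implant-based stem frame.

    y is the unit vector from stem tip to shoulder (the stem long axis,
    pointing superior); x lies in the plane of the stem and neck axes,
    perpendicular to y — along the projected neck direction for right
    hips, opposite for left hips so that left measurements land in the
    mirror-image frame and the standard sign flip brings them to
    right-hip convention; z = x cross y. Origin at the tip.

    Raises ``DegenerateFitError`` if the stem and neck axes are parallel.
    """
    tip = np.asarray(tip, dtype=float)
    shoulder = np.asarray(shoulder, dtype=float)
    neck_point = np.asarray(neck_point, dtype=float)
    long_axis = shoulder - tip
    norm = np.linalg.norm(long_axis)
    if norm < 1e-12:
        raise DegenerateFitError("zero-length stem long axis")
    y = long_axis / norm
    neck_dir = neck_point - shoulder
    x_raw = neck_dir - (neck_dir @ y) * y
    if np.linalg.norm(x_raw) < 1e-9 * max(np.linalg.norm(neck_dir), 1.0):
        raise DegenerateFitError("neck axis parallel to stem long axis")
    x = x_raw / np.linalg.norm(x_raw)
    if side == "left":
        x = -x
    elif side != "right":
        raise ValueError(f"unknown side {side!r}")
    z = np.cross(x, y)
    return AnatomicFrame(origin=tip, axes=np.column_stack([x, y, z]))


def build_table_frame(origin: np.ndarray | None = None) -> AnatomicFrame:
    """Scanner-table frame: identity axes of the baseline examination.

    Used for the cup, whose near-spherical shape offers no reliable
    implant-based frame; only the origin (the cup reference point) is
    implant-derived.
    """
    o = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    return AnatomicFrame(origin=o, axes=np.eye(3))


def matrix_from_cardan(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix from Cardan angles (degrees, x-then-y-then-z)."""
    return Rotation.from_euler(_CARDAN_SEQ, [rx, ry, rz], degrees=True).as_matrix()


def cardan_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Cardan angles (degrees, x-then-y-then-z) of a rotation matrix."""
    rx, ry, rz = Rotation.from_matrix(np.asarray(R, float)).as_euler(
        _CARDAN_SEQ, degrees=True
    )
    return float(rx), float(ry), float(rz)


def dof_to_frame_transform(
    tx: float, ty: float, tz: float, rx: float, ry: float, rz: float
) -> RigidTransform:
    """The rigid motion, expressed in frame coordinates, that realises
    the six migration components: rotate about the frame origin by the
    Cardan angles, then translate by (tx, ty, tz)."""
    return RigidTransform(matrix_from_cardan(rx, ry, rz), np.array([tx, ty, tz]))


def transform_in_frame(frame: AnatomicFrame, local: RigidTransform) -> RigidTransform:
    """Conjugate a frame-coordinate motion into lab coordinates.

    A point p (lab) has frame coordinates q = A^T (p - o); the motion
    maps q -> R q + t in the frame, hence p -> o + A (R A^T (p - o) + t)
    in the lab.
    """
    A = frame.axes
    o = frame.origin
    R_lab = A @ local.rotation @ A.T
    t_lab = o - R_lab @ o + A @ local.translation
    return RigidTransform(R_lab, t_lab)


def frame_components(
    frame: AnatomicFrame, lab: RigidTransform
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Inverse of :func:`transform_in_frame`: express a lab-coordinate
    rigid motion as frame-coordinate translations and Cardan angles."""
    A = frame.axes
    o = frame.origin
    R_local = A.T @ lab.rotation @ A
    t_local = A.T @ (lab.apply(o) - o)
    return t_local, cardan_from_matrix(R_local)


def landmark_init(
    model_landmarks: dict[str, np.ndarray],
    observed_landmarks: dict[str, np.ndarray],
) -> RigidTransform:
    """Coarse model->lab pose from matched named landmarks.

    Emulates the landmark-localisation stage of an automated pipeline;
    the result seeds the ICP surface fit.
    """
    common = sorted(set(model_landmarks) & set(observed_landmarks))
    if len(common) < 3:
        raise DegenerateFitError("landmark init needs >= 3 shared landmarks")
    src = PointSet(np.array([model_landmarks[k] for k in common]), np.array(common, dtype=object))
    dst = PointSet(np.array([observed_landmarks[k] for k in common]), np.array(common, dtype=object))
    return fit_rigid(src, dst).transform


def _implant_pose(model, exam, segment: str) -> FitResult:
    """ICP pose of `segment`'s model in one examination, seeded from the
    exam's observed implant landmarks."""
    cloud = exam.implant_clouds[segment]
    init = landmark_init(model.landmarks, exam.implant_landmarks[segment])
    fit = fit_model_pose(model.surface_points, cloud, init)
    if not fit.converged:
        raise DegenerateFitError(f"ICP did not converge for {segment}")
    return fit


def analyze_pair(
    baseline,
    followup,
    model,
    reference: str = "auto",
    segment: str | None = None,
    translation_reference: str = "centroid",
) -> MigrationDOF:
    """Measure 6-DOF migration of an implant between two examinations.

    Steps: (1) rigid fit of the reference-bone markers aligns the
    follow-up exam into baseline space; (2) the implant model is
    ICP-fitted in both exams; (3) the relative implant motion is
    expressed in the segment frame (implant-based for the stem,
    scanner-table for the cup) built from the baseline fit; (4) Cardan
    decomposition and reference-point translation give the six
    components; (5) left hips are mirrored to right-hip convention.

    Quality gates (condition number < 120, mean error < 0.35 mm) are
    evaluated on the reference-bone fit and attached as flags; gated
    records are flagged, never silently dropped.

    Parameters
    ----------
    baseline, followup : Examination
        Two exams of the same subject; the follow-up may be a replicate
        (double examination) of the same visit.
    model : ImplantModel
        Surface samples and named landmarks of the migrating implant.
    reference : str
        "pelvis", "femur", or "auto" (pelvis for the cup, femur for the
        stem).
    segment : str
        "stem" or "cup"; defaults to ``model.kind``.
    translation_reference : str
        Implant point whose displacement is reported: "centroid" of the
        surface model, or the name of a model landmark (e.g.
        "head_center" for the stem, "center" for the cup).
    """
    segment = segment or model.kind
    if baseline.subject != followup.subject:
        raise ValueError("exams are from different subjects")
    side = baseline.side
    if reference == "auto":
        reference = "pelvis" if segment == "cup" else "femur"
    ref_markers_base = getattr(baseline, f"{reference}_markers")
    ref_markers_follow = getattr(followup, f"{reference}_markers")

    # 1) align follow-up into baseline space via the reference bone
    ref_fit = fit_rigid(ref_markers_follow, ref_markers_base)
    S = ref_fit.transform

    # 2) implant pose in each exam
    pose0 = _implant_pose(model, baseline, segment).transform
    pose1 = _implant_pose(model, followup, segment).transform

    # 3) relative implant motion in baseline space
    D = S.compose(pose1).compose(pose0.inverse())

    # 4) segment frame from the baseline implant fit
    if translation_reference == "centroid":
        ref_point_model = model.surface_points.centroid
    else:
        ref_point_model = np.asarray(model.landmarks[translation_reference], float)
    origin = pose0.apply(ref_point_model)
    if segment == "stem":
        lm = {k: pose0.apply(np.asarray(v, float)) for k, v in model.landmarks.items()}
        frame = build_stem_frame(lm["tip"], lm["shoulder"], lm["neck_point"], side=side)
        frame = AnatomicFrame(origin=origin, axes=frame.axes)
    elif segment == "cup":
        frame = build_table_frame(origin=origin)
    else:
        raise ValueError(f"unknown segment {segment!r}")

    t_local, (rx, ry, rz) = frame_components(frame, D)
    raw = MigrationDOF(
        Tx=float(t_local[0]), Ty=float(t_local[1]), Tz=float(t_local[2]),
        Rx=rx, Ry=ry, Rz=rz,
        side=side, segment=segment,
        condition_number=ref_fit.condition_number,
        mean_error=ref_fit.mean_error,
        flags=tuple(k for k, ok in ref_fit.flags.items() if not ok),
    )
    # 5) report in right-hip convention
    return mirror_to_right(raw)
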