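"""Synthetic radiostereometric follow-up studies.

Generates complete virtual THA migration studies — labelled bone-marker
sets for pelvis and femur, parametric stem and cup implant models,
per-subject piecewise-linear migration trajectories, and per-timepoint
examinations for two measurement methods (CT-based and marker-based RSA)
— with known ground truth, so the whole measurement and statistics
pipeline can be exercised without any imaging data.

The generator emulates the design of a two-year uncemented-THA follow-up
study: a baseline examination within days of surgery (indexed month 0),
follow-ups at 3, 12 and 24 months, 9–10 tantalum-style bone markers per
segment, a duplicated visit with intermediate repositioning for
precision estimation, left and right hips, and a planned-vs-used implant
size table. Migration follows a piecewise-linear trajectory with a
breakpoint at 3 months (fast settling, then plateau), with per-subject
random slope deviations.

Noise model: each examination carries an independent 6-DOF measurement
error (isotropic Gaussian per component, method-specific SD) realised
geometrically as a small rigid perturbation of the observed implant
pose, plus optional isotropic Gaussian noise on every observed point
coordinate and optional marker instability (sporadic fixed displacements
of individual beads). The per-DOF error is the primary driver of the
method's precision; the point-level noise exercises the registration
robustness separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .kinematics import (
    AnatomicFrame,
    build_stem_frame,
    build_table_frame,
    dof_to_frame_transform,
    landmark_init,
    transform_in_frame,
)
from .pointset import PointSet
from .registration import RigidTransform

__all__ = [
    "StudyConfig",
    "ImplantModel",
    "Examination",
    "TrueTrajectory",
    "make_implant_model",
    "make_baseline_examination",
    "apply_true_migration",
    "generate_study",
    "simulate_long_table",
    "DEFAULT_SLOPES_EARLY",
    "DEFAULT_SLOPES_LATE",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# Default mean migration slopes (units/month) chosen to land the 2-year
# trajectories in the range reported for collared uncemented stems and
# press-fit cups: stem subsidence ~0.1 mm and retroversion ~0.5 deg,
# cup proximal migration ~0.3 mm and decreased inclination ~0.5 deg,
# with most of the motion inside the first 3 months.
DEFAULT_SLOPES_EARLY: dict[str, dict[str, float]] = {
    "stem": {"Ty": -0.0133, "Ry": -0.1333},
    "cup": {"Ty": 0.0733, "Rz": 0.1167},
}
DEFAULT_SLOPES_LATE: dict[str, dict[str, float]] = {
    "stem": {"Ty": -0.0033, "Ry": -0.0067},
    "cup": {"Ty": 0.0043, "Rz": 0.0071},
}

_DOF6 = ("Tx", "Ty", "Tz", "Rx", "Ry", "Rz")


class StudyConfig(BaseModel):
    """Parameters of a simulated follow-up study.

    All lengths are millimetres, angles degrees, times months. The same
    config and seed always produce byte-identical studies.
    """

    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(default=26, ge=1)
    prop_left: float = Field(default=14 / 26, ge=0.0, le=1.0)
    timepoints_months: tuple[float, ...] = (0.0, 3.0, 12.0, 24.0)
    breakpoint_months: float = Field(default=3.0, gt=0.0)

    markers_per_segment: tuple[int, int] = (9, 10)
    marker_spread_mm: float = Field(default=30.0, gt=0.0)
    marker_instability_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    instability_magnitude_mm: float = Field(default=1.0, ge=0.0)

    slope_early: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SLOPES_EARLY.items()}
    )
    slope_late: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SLOPES_LATE.items()}
    )
    subject_sd: float = Field(default=0.01, ge=0.0)

    # per-DOF, per-examination measurement error SDs (mm / degrees)
    noise_sd_ctrsa: float = Field(default=0.035, ge=0.0)
    noise_sd_mbrsa: float = Field(default=0.08, ge=0.0)
    point_noise_sd: float = Field(default=0.0, ge=0.0)

    double_exam_timepoint: float | None = 3.0
    reposition_max_rotation_deg: float = Field(default=15.0, ge=0.0)
    reposition_max_translation_mm: float = Field(default=50.0, ge=0.0)

    plan_match_prob_cup: float = Field(default=25 / 26, ge=0.0, le=1.0)
    plan_match_prob_stem: float = Field(default=23 / 26, ge=0.0, le=1.0)
    plan_exact_prob_stem: float = Field(default=16 / 26, ge=0.0, le=1.0)

    methods: tuple[str, ...] = ("ctrsa", "mbrsa")
    mbrsa_subgroup_size: int = Field(default=10, ge=0)
    segments: tuple[str, ...] = ("stem", "cup")

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        tps = self.timepoints_months
        if len(tps) < 2 or tps[0] != 0.0:
            raise ValueError("timepoints must start at 0 and include a follow-up")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        lo, hi = self.markers_per_segment
        if not (3 <= lo <= hi):
            raise ValueError("markers_per_segment must be an increasing range >= 3")
        if self.double_exam_timepoint is not None and (
            self.double_exam_timepoint not in tps or self.double_exam_timepoint == 0.0
        ):
            raise ValueError("double_exam_timepoint must be a follow-up timepoint")
        if self.plan_exact_prob_stem > self.plan_match_prob_stem:
            raise ValueError("exact stem match cannot be more likely than size match")
        for m in self.methods:
            if m not in ("ctrsa", "mbrsa"):
                raise ValueError(f"unknown method {m!r}")
        for s in self.segments:
            if s not in ("stem", "cup"):
                raise ValueError(f"unknown segment {s!r}")
        return self

    def noise_sd(self, method: str) -> float:
        return {"ctrsa": self.noise_sd_ctrsa, "mbrsa": self.noise_sd_mbrsa}[method]


@dataclass
class ImplantModel:
    """Parametric implant surface model with named landmarks.

    Stand-in for a manufacturer CAD model: `surface_points` are labelled
    samples of the implant surface in the implant's own frame;
    `landmarks` are the named points used for frame construction and
    coarse pose initialisation (stem: tip, shoulder, neck_point,
    head_center; cup: center, pole, rim_point).

    Both models are built exactly symmetric under z -> -z (the stem/neck
    plane), mirroring the near-symmetry of real implants; this lets a
    left-hip scene, the sagittal mirror of a right-hip scene, still be
    fit by a proper rotation of the same model.
    """

    kind: str
    surface_points: PointSet
    landmarks: dict[str, np.ndarray]
    size_label: str

    def __post_init__(self) -> None:
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}
        if self.kind == "stem":
            required = {"tip", "shoulder", "neck_point", "head_center"}
            if not required <= set(self.landmarks):
                raise ValueError(f"stem model missing landmarks {required - set(self.landmarks)}")
            # raises if the long and neck axes are parallel or degenerate
            build_stem_frame(
                self.landmarks["tip"], self.landmarks["shoulder"], self.landmarks["neck_point"]
            )
        elif self.kind == "cup":
            required = {"center", "pole", "rim_point"}
            if not required <= set(self.landmarks):
                raise ValueError(f"cup model missing landmarks {required - set(self.landmarks)}")
            radius = np.linalg.norm(self.landmarks["pole"] - self.landmarks["center"])
            r = np.linalg.norm(self.surface_points.coords - self.landmarks["center"], axis=1)
            if np.abs(r - radius).max() > 0.5:
                raise ValueError("cup surface points do not lie on a hemisphere about center")
        else:
            raise ValueError(f"unknown implant kind {self.kind!r}")


@dataclass
class Examination:
    """One (possibly replicated) imaging examination of a subject.

    All coordinates are in this examination's scanner frame;
    `patient_pose` maps the subject's baseline scanner frame into this
    one (identity for the baseline itself). Marker labels are stable
    across a subject's examinations. Replicate examinations (double
    exams) share the subject's true state at their timepoint and differ
    only by repositioning and measurement noise.
    """

    subject: str
    side: str
    method: str
    timepoint_months: float
    replicate: int
    pelvis_markers: PointSet
    femur_markers: PointSet
    implant_clouds: dict[str, PointSet]
    implant_landmarks: dict[str, dict[str, np.ndarray]]
    patient_pose: RigidTransform = field(default_factory=RigidTransform.identity)


@dataclass
class TrueTrajectory:
    """Ground-truth piecewise-linear migration of one implant.

    Each DOF follows value(t) = s_early * min(t, b) + s_late * max(0, t - b)
    with breakpoint b; the value at month 0 is exactly zero and the
    trajectory is continuous at the breakpoint by construction. DOF
    values are in right-hip convention.
    """

    subject: str
    segment: str
    slopes_early: dict[str, float]
    slopes_late: dict[str, float]
    breakpoint_months: float = 3.0

    def dof_at(self, timepoint: float) -> dict[str, float]:
        if timepoint < 0:
            raise ValueError("negative timepoint")
        b = self.breakpoint_months
        out = {}
        for dof in _DOF6:
            se = self.slopes_early.get(dof, 0.0)
            sl = self.slopes_late.get(dof, 0.0)
            out[dof] = se * min(timepoint, b) + sl * max(0.0, timepoint - b)
        return out

    def table(self, timepoints: Iterable[float]) -> pd.DataFrame:
        rows = []
        for t in timepoints:
            d = self.dof_at(t)
            d.update(subject=self.subject, segment=self.segment, timepoint_months=t)
            rows.append(d)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# implant models


def _symmetrize(points: list[np.ndarray], labels: list[str]) -> PointSet:
    """Union of each point with its z-mirror, giving an exactly
    z-symmetric sample set."""
    pts, labs = [], []
    for p, lab in zip(points, labels):
        pts.append(p)
        labs.append(lab)
        q = p.copy()
        q[2] *= -1.0
        pts.append(q)
        labs.append(lab + "m")
    return PointSet(np.array(pts), np.array(labs, dtype=object))


def make_implant_model(
    kind: str,
    size_label: str | None = None,
    n_surface_points: int = 90,
) -> ImplantModel:
    """Build a parametric stem or cup model in its canonical frame.

    Stem (canonical frame: y = long axis tip->shoulder, x = medial
    toward the neck, z = anterior): a tapered shaft from tip (origin) to
    shoulder plus a neck cylinder toward the head center, sampled on an
    irregular golden-angle spiral. `size_label` (e.g. "12") sets the
    shaft length and girth.

    Cup: a hemisphere sampled by a spherical Fibonacci spiral; the
    azimuthally irregular sampling leaves no rotational symmetry about
    the pole, so the pose of the sampled model is uniquely identifiable.
    `size_label` (e.g. "52") is the outer diameter in mm.

    The sampling is deterministic: same arguments, same model.
    """
    if kind == "stem":
        size = float(size_label if size_label is not None else 12)
        length = 80.0 + 2.0 * size  # tip-to-shoulder, mm
        tip = np.array([0.0, 0.0, 0.0])
        shoulder = np.array([0.0, length, 0.0])
        neck_dir = np.array([np.sin(np.deg2rad(47.0)), np.cos(np.deg2rad(47.0)), 0.0])
        neck_point = shoulder + 25.0 * neck_dir
        head_center = shoulder + 40.0 * neck_dir
        n_shaft = max(3 * n_surface_points // 4, 8)
        n_neck = max(n_surface_points - n_shaft, 4)
        pts, labs = [], []
        for i in range(n_shaft):
            s = (i + 0.5) / n_shaft
            radius = 3.0 + s * 0.18 * size  # tapered: wider toward the shoulder
            theta = i * _GOLDEN_ANGLE + 0.2
            pts.append(
                np.array([radius * np.cos(theta), s * length, radius * np.sin(theta)])
            )
            labs.append(f"sh{i}")
        for i in range(n_neck):
            s = (i + 0.5) / n_neck
            theta = i * _GOLDEN_ANGLE + 0.7
            center = shoulder + s * 25.0 * neck_dir
            u = np.array([neck_dir[1], -neck_dir[0], 0.0])  # in-plane normal to neck
            v = np.array([0.0, 0.0, 1.0])
            pts.append(center + 6.0 * (np.cos(theta) * u + np.sin(theta) * v))
            labs.append(f"nk{i}")
        surface = _symmetrize(pts, labs)
        return ImplantModel(
            kind="stem",
            surface_points=surface,
            landmarks={
                "tip": tip,
                "shoulder": shoulder,
                "neck_point": neck_point,
                "head_center": head_center,
            },
            size_label=str(size_label if size_label is not None else 12),
        )
    if kind == "cup":
        size = float(size_label if size_label is not None else 52)
        radius = size / 2.0
        center = np.zeros(3)
        pole = np.array([0.0, radius, 0.0])  # polar axis +y in canonical frame
        rim_point = np.array([radius, 0.0, 0.0])
        pts, labs = [], []
        for i in range(n_surface_points):
            cos_phi = (i + 0.5) / n_surface_points  # y in (0, 1): hemisphere
            sin_phi = np.sqrt(1.0 - cos_phi**2)
            theta = i * _GOLDEN_ANGLE + 0.3
            pts.append(
                radius
                * np.array([sin_phi * np.cos(theta), cos_phi, sin_phi * np.sin(theta)])
            )
            labs.append(f"c{i}")
        surface = _symmetrize(pts, labs)
        return ImplantModel(
            kind="cup",
            surface_points=surface,
            landmarks={"center": center, "pole": pole, "rim_point": rim_point},
            size_label=str(size_label if size_label is not None else 52),
        )
    raise ValueError(f"unknown implant kind {kind!r}")


# ---------------------------------------------------------------------------
# scenes and examinations


def _raw_convention_flip(dof: Mapping[str, float], side: str) -> dict[str, float]:
    """Convert right-hip-convention DOF values to the raw components seen
    in the (side-aware) segment frame: the sagittal mirror negates Tx,
    Ry and Rz for left hips."""
    out = dict(dof)
    if side == "left":
        for k in ("Tx", "Ry", "Rz"):
            out[k] = -out.get(k, 0.0)
    elif side != "right":
        raise ValueError(f"unknown side {side!r}")
    return out


def _sample_shell(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    semi_axes: np.ndarray,
    inner_fraction: float = 0.5,
) -> np.ndarray:
    """Uniform points in an ellipsoidal shell (keeps markers spread out,
    avoiding the near-collinear configurations of center-clustered
    samples unless the spread itself is made small)."""
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    lo = inner_fraction**3
    radii = (lo + rng.uniform(size=(n, 1)) * (1.0 - lo)) ** (1.0 / 3.0)
    return center + directions * radii * semi_axes


def make_baseline_examination(
    subject: str,
    side: str,
    config: StudyConfig,
    rng: np.random.Generator,
    models: Mapping[str, ImplantModel],
) -> Examination:
    """Ground-truth baseline examination of one subject.

    Builds a right-sided hip scene — implants placed with randomised
    anatomic poses, 9-10 bone markers per segment in ellipsoidal shells
    around each implant — mirrors it sagittally for left hips, and poses
    the whole scene randomly on the scanner table. The returned
    examination is noise-free and defines the subject's baseline scanner
    frame (its `patient_pose` is the identity); all migration truths are
    expressed relative to the frames derived from this examination.
    """
    n_lo, n_hi = config.markers_per_segment
    spread = config.marker_spread_mm

    # cup placed near the origin, opening facing lateral-anterior
    from scipy.spatial.transform import Rotation

    cup = models.get("cup")
    stem = models.get("stem")
    incl = Rotation.from_euler("z", -50.0, degrees=True)
    antev = Rotation.from_euler("y", 15.0, degrees=True)
    jitter = Rotation.from_rotvec(rng.normal(scale=np.deg2rad(3.0), size=3))
    cup_rot = (jitter * incl * antev).as_matrix()
    cup_center = rng.normal(scale=2.0, size=3)
    cup_pose = RigidTransform(cup_rot, cup_center)

    stem_rot = Rotation.from_rotvec(rng.normal(scale=np.deg2rad(4.0), size=3)).as_matrix()
    if stem is not None:
        head_model = stem.landmarks["head_center"]
        stem_t = cup_center - stem_rot @ head_model + rng.normal(scale=1.5, size=3)
        stem_pose = RigidTransform(stem_rot, stem_t)
    else:
        stem_pose = None

    clouds: dict[str, PointSet] = {}
    lms: dict[str, dict[str, np.ndarray]] = {}
    poses = {"cup": cup_pose, "stem": stem_pose}
    for seg, model in models.items():
        pose = poses[seg]
        clouds[seg] = pose.apply_pointset(model.surface_points)
        lms[seg] = {k: pose.apply(v) for k, v in model.landmarks.items()}

    # bone markers: pelvis around the cup, femur along the stem shaft
    pelvis_center = cup_center + np.array([5.0, 25.0, 0.0])
    pelvis = _sample_shell(
        rng, int(rng.integers(n_lo, n_hi + 1)), pelvis_center,
        spread * np.array([1.0, 0.8, 0.9]),
    )
    if stem is not None:
        shaft_mid = stem_pose.apply(0.45 * stem.landmarks["shoulder"])
        femur_center = shaft_mid + np.array([-8.0, -10.0, 0.0])
    else:
        femur_center = cup_center + np.array([-10.0, -80.0, 0.0])
    femur = _sample_shell(
        rng, int(rng.integers(n_lo, n_hi + 1)), femur_center,
        spread * np.array([0.7, 1.3, 0.7]),
    )
    pelvis_ps = PointSet(pelvis, np.array([f"p{i}" for i in range(len(pelvis))], dtype=object))
    femur_ps = PointSet(femur, np.array([f"f{i}" for i in range(len(femur))], dtype=object))

    if side == "left":
        pelvis_ps = pelvis_ps.mirrored(axis=0)
        femur_ps = femur_ps.mirrored(axis=0)
        clouds = {k: v.mirrored(axis=0) for k, v in clouds.items()}
        for seg in lms:
            lms[seg] = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in lms[seg].items()}
    elif side != "right":
        raise ValueError(f"unknown side {side!r}")

    # patient position on the scanner table at baseline
    table_pose = RigidTransform.random(
        rng, config.reposition_max_rotation_deg, config.reposition_max_translation_mm
    )
    pelvis_ps = table_pose.apply_pointset(pelvis_ps)
    femur_ps = table_pose.apply_pointset(femur_ps)
    clouds = {k: table_pose.apply_pointset(v) for k, v in clouds.items()}
    lms = {seg: {k: table_pose.apply(v) for k, v in d.items()} for seg, d in lms.items()}

    return Examination(
        subject=subject,
        side=side,
        method="truth",
        timepoint_months=0.0,
        replicate=1,
        pelvis_markers=pelvis_ps,
        femur_markers=femur_ps,
        implant_clouds=clouds,
        implant_landmarks=lms,
    )


def _segment_frame(
    baseline: Examination, model: ImplantModel, segment: str
) -> AnatomicFrame:
    """Segment frame derived from the baseline examination's implant
    geometry (implant-based for the stem, table axes for the cup), with
    its origin at the implant surface centroid — the reported
    translation reference point."""
    pose0 = landmark_init(model.landmarks, baseline.implant_landmarks[segment])
    origin = pose0.apply(model.surface_points.centroid)
    if segment == "stem":
        lm = {k: pose0.apply(v) for k, v in model.landmarks.items()}
        f = build_stem_frame(lm["tip"], lm["shoulder"], lm["neck_point"], side=baseline.side)
        return AnatomicFrame(origin=origin, axes=f.axes)
    return build_table_frame(origin=origin)


def apply_true_migration(
    baseline: Examination,
    trajectories: "TrueTrajectory | Sequence[TrueTrajectory] | Mapping[str, TrueTrajectory]",
    timepoint: float,
    models: Mapping[str, ImplantModel],
    *,
    method: str = "truth",
    replicate: int = 1,
    patient_pose: RigidTransform | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    point_noise_sd: float = 0.0,
    marker_instability_prob: float = 0.0,
    instability_magnitude_mm: float = 1.0,
) -> Examination:
    """Realise an examination at `timepoint` from a baseline examination.

    Each implant cloud is displaced, relative to its reference bone, by
    exactly the trajectory's 6-DOF pose at that timepoint, composed in
    the implant's segment frame (built from the baseline examination);
    the bones stay fixed relative to each other. Optionally adds a
    per-examination 6-DOF measurement error (SD `noise_sd` per
    component), isotropic point noise, sporadic marker instability, and
    a rigid repositioning of the whole scene (`patient_pose`).

    With an all-zero trajectory, no noise and no pose, the output is
    geometrically identical to the baseline.
    """
    if timepoint < 0:
        raise ValueError("unknown timepoint: negative months")
    if isinstance(trajectories, TrueTrajectory):
        trajectories = {trajectories.segment: trajectories}
    elif not isinstance(trajectories, Mapping):
        trajectories = {t.segment: t for t in trajectories}
    if rng is None and (noise_sd > 0 or point_noise_sd > 0 or marker_instability_prob > 0):
        raise ValueError("rng required when noise is requested")

    clouds: dict[str, PointSet] = {}
    lms: dict[str, dict[str, np.ndarray]] = {}
    for seg, cloud in baseline.implant_clouds.items():
        model = models[seg]
        traj = trajectories.get(seg)
        dof = traj.dof_at(timepoint) if traj is not None else {k: 0.0 for k in _DOF6}
        raw = _raw_convention_flip(dof, baseline.side)
        local = dof_to_frame_transform(
            raw["Tx"], raw["Ty"], raw["Tz"], raw["Rx"], raw["Ry"], raw["Rz"]
        )
        if noise_sd > 0:
            e = rng.normal(scale=noise_sd, size=6)
            local = dof_to_frame_transform(*e).compose(local)
        frame = _segment_frame(baseline, model, seg)
        displacement = transform_in_frame(frame, local)
        clouds[seg] = displacement.apply_pointset(cloud)
        lms[seg] = {
            k: displacement.apply(v) for k, v in baseline.implant_landmarks[seg].items()
        }

    pelvis = PointSet(baseline.pelvis_markers.coords.copy(), baseline.pelvis_markers.labels.copy())
    femur = PointSet(baseline.femur_markers.coords.copy(), baseline.femur_markers.labels.copy())
    if marker_instability_prob > 0 and (timepoint > 0 or replicate > 1):
        for ps in (pelvis, femur):
            unstable = rng.uniform(size=len(ps)) < marker_instability_prob
            ps.coords[unstable] += rng.normal(
                scale=instability_magnitude_mm, size=(int(unstable.sum()), 3)
            )

    pose = patient_pose if patient_pose is not None else RigidTransform.identity()
    pelvis = pose.apply_pointset(pelvis)
    femur = pose.apply_pointset(femur)
    clouds = {k: pose.apply_pointset(v) for k, v in clouds.items()}
    lms = {seg: {k: pose.apply(v) for k, v in d.items()} for seg, d in lms.items()}

    if point_noise_sd > 0:
        pelvis.coords += rng.normal(scale=point_noise_sd, size=pelvis.coords.shape)
        femur.coords += rng.normal(scale=point_noise_sd, size=femur.coords.shape)
        for seg in clouds:
            clouds[seg].coords += rng.normal(scale=point_noise_sd, size=clouds[seg].coords.shape)
            lms[seg] = {
                k: v + rng.normal(scale=point_noise_sd, size=3) for k, v in lms[seg].items()
            }

    return Examination(
        subject=baseline.subject,
        side=baseline.side,
        method=method,
        timepoint_months=float(timepoint),
        replicate=replicate,
        pelvis_markers=pelvis,
        femur_markers=femur,
        implant_clouds=clouds,
        implant_landmarks=lms,
        patient_pose=pose,
    )


def _subject_trajectories(
    subject: str, config: StudyConfig, rng: np.random.Generator
) -> dict[str, TrueTrajectory]:
    """Per-subject trajectories: population mean slopes plus independent
    per-subject slope deviations (SD `subject_sd` per DOF early, an
    eighth of that late)."""
    out = {}
    for seg in config.segments:
        early = {d: config.slope_early.get(seg, {}).get(d, 0.0) for d in _DOF6}
        late = {d: config.slope_late.get(seg, {}).get(d, 0.0) for d in _DOF6}
        for d in _DOF6:
            early[d] += rng.normal(scale=config.subject_sd)
            late[d] += rng.normal(scale=config.subject_sd / 8.0)
        out[seg] = TrueTrajectory(
            subject=subject,
            segment=seg,
            slopes_early=early,
            slopes_late=late,
            breakpoint_months=config.breakpoint_months,
        )
    return out


def _plan_rows(
    subject: str, config: StudyConfig, rng: np.random.Generator
) -> list[dict]:
    """Planned-vs-used implant size draws for one subject."""
    cup_sizes = [48, 50, 52, 54, 56]
    stem_sizes = list(range(9, 15))
    variants = ["standard", "varus", "high-offset"]

    planned_cup = int(rng.choice(cup_sizes[1:-1]))
    cup_match = rng.uniform() < config.plan_match_prob_cup
    used_cup = planned_cup if cup_match else planned_cup + int(rng.choice([-2, 2]))

    planned_stem = int(rng.choice(stem_sizes[1:-1]))
    planned_variant = str(rng.choice(variants))
    size_match = rng.uniform() < config.plan_match_prob_stem
    used_stem = planned_stem if size_match else planned_stem + int(rng.choice([-1, 1]))
    if size_match and config.plan_match_prob_stem > 0:
        variant_match = rng.uniform() < (
            config.plan_exact_prob_stem / config.plan_match_prob_stem
        )
    else:
        variant_match = False
    if variant_match:
        used_variant = planned_variant
    else:
        used_variant = str(rng.choice([v for v in variants if v != planned_variant]))

    return [
        {
            "subject": subject, "component": "cup",
            "planned_size": planned_cup, "planned_variant": "",
            "used_size": used_cup, "used_variant": "",
        },
        {
            "subject": subject, "component": "stem",
            "planned_size": planned_stem, "planned_variant": planned_variant,
            "used_size": used_stem, "used_variant": used_variant,
        },
    ]


def generate_study(
    config: StudyConfig,
) -> tuple[list[Examination], list[TrueTrajectory], pd.DataFrame]:
    """Generate a complete virtual follow-up study.

    Returns the examinations of every subject (one baseline plus one
    exam per follow-up timepoint and method, with the configured visit
    duplicated for double-examination precision), the ground-truth
    trajectories, and the planned-vs-used implant size table.

    The CT-based method is simulated for all subjects; the marker-based
    method only for the first `mbrsa_subgroup_size` subjects, mirroring
    the typical study design where bead implantation is restricted to a
    subgroup. All randomness descends from `config.seed` through a fixed
    spawning order, so identical configs yield byte-identical studies.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    models = {seg: make_implant_model(seg) for seg in config.segments}

    exams: list[Examination] = []
    truths: list[TrueTrajectory] = []
    plan_rows: list[dict] = []
    plan_rng = np.random.default_rng(children[-1])

    for i in range(config.n_subjects):
        rng = np.random.default_rng(children[i])
        subject = f"S{i + 1:03d}"
        side = "left" if rng.uniform() < config.prop_left else "right"
        trajs = _subject_trajectories(subject, config, rng)
        truths.extend(trajs.values())
        truth_base = make_baseline_examination(subject, side, config, rng, models)

        for method in config.methods:
            if method == "mbrsa" and i >= config.mbrsa_subgroup_size:
                continue
            noise = config.noise_sd(method)
            exams.append(
                apply_true_migration(
                    truth_base, trajs, 0.0, models,
                    method=method, replicate=1, rng=rng,
                    noise_sd=noise, point_noise_sd=config.point_noise_sd,
                )
            )
            for t in config.timepoints_months[1:]:
                n_reps = 2 if t == config.double_exam_timepoint else 1
                for rep in range(1, n_reps + 1):
                    pose = RigidTransform.random(
                        rng,
                        config.reposition_max_rotation_deg,
                        config.reposition_max_translation_mm,
                    )
                    exams.append(
                        apply_true_migration(
                            truth_base, trajs, t, models,
                            method=method, replicate=rep, patient_pose=pose, rng=rng,
                            noise_sd=noise, point_noise_sd=config.point_noise_sd,
                            marker_instability_prob=config.marker_instability_prob,
                            instability_magnitude_mm=config.instability_magnitude_mm,
                        )
                    )
        plan_rows.extend(_plan_rows(subject, config, plan_rng))

    return exams, truths, pd.DataFrame(plan_rows)


def simulate_long_table(
    n_subjects: int = 25,
    slope_early: float = 0.15,
    slope_late: float = 0.005,
    subject_sd: float = 0.05,
    noise_sd: float = 0.05,
    timepoints: Sequence[float] = (3.0, 12.0, 24.0),
    breakpoint_months: float = 3.0,
    seed: int | np.random.Generator = 0,
    segment: str = "stem",
    dof: str = "Ty",
    method: str = "ctrsa",
) -> pd.DataFrame:
    """Directly simulate a tidy migration table for one DOF.

    Bypasses the geometric pipeline: measured migration at follow-up t is
    the piecewise-linear mean trajectory plus a subject-level random
    intercept (SD `subject_sd` — physically, the baseline examination's
    measurement error, shared by all of a subject's follow-ups) plus
    independent observation noise (SD `noise_sd`). Intended for testing
    and calibrating the longitudinal model at scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        subject = f"S{i + 1:03d}"
        u = rng.normal(scale=subject_sd)
        for t in timepoints:
            mean = slope_early * min(t, breakpoint_months) + slope_late * max(
                0.0, t - breakpoint_months
            )
            rows.append(
                {
                    "subject": subject, "side": "right", "method": method,
                    "segment": segment, "dof": dof, "timepoint_months": float(t),
                    "replicate": 1,
                    "value": mean + u + rng.normal(scale=noise_sd),
                }
            )
    return pd.DataFrame(rows)
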