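"""Serialization of studies, transforms and result tables.

On-disk layout of a study (one directory per study):

    study/
      config.yaml            # the StudyConfig that generated it
      manifest.json          # file list with SHA-256 hashes and the seed
      truth.csv              # ground-truth DOF values per timepoint
      truth_slopes.csv       # ground-truth trajectory slopes
      plan.csv               # planned vs used implant sizes
      exams/<exam id>/
        meta.json            # subject, side, method, timepoint, replicate,
                             # patient pose (row-major rotation + mm)
        markers.csv          # subject, segment, marker_id, x, y, z (mm)
        <segment>.ply        # observed implant cloud (ASCII point cloud)
        landmarks.json       # observed implant landmarks per segment

Tables are tidy CSV throughout; transforms are JSON with a row-major
rotation matrix and a translation in mm.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml
from trimesh.exchange.ply import export_ply

from .pointset import PointSet
from .registration import RigidTransform
from .synthetic import Examination, StudyConfig, TrueTrajectory

__all__ = [
    "save_study",
    "load_study",
    "exam_id",
    "write_long_table",
    "read_long_table",
    "sha256_file",
]

LONG_COLUMNS = [
    "subject", "side", "method", "segment", "dof",
    "timepoint_months", "replicate", "value", "cn", "me", "flags",
]


def exam_id(exam: Examination) -> str:
    t = f"{exam.timepoint_months:g}".replace(".", "p")
    return f"{exam.method}_{exam.subject}_t{t}_r{exam.replicate}"


def sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_ply(path: Path, coords: np.ndarray) -> None:
    cloud = trimesh.PointCloud(np.asarray(coords, dtype=np.float64))
    Path(path).write_bytes(export_ply(cloud, encoding="ascii"))


def _read_ply(path: Path) -> np.ndarray:
    return np.asarray(trimesh.load(str(path), file_type="ply").vertices, dtype=float)


def save_study(
    directory: str | Path,
    exams: list[Examination],
    truths: list[TrueTrajectory] | None = None,
    plan_table: pd.DataFrame | None = None,
    config: StudyConfig | None = None,
) -> Path:
    """Serialize a study to a directory; returns the manifest path."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    if config is not None:
        p = root / "config.yaml"
        p.write_text(yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True))
        files.append(p)
    if truths is not None:
        tps = config.timepoints_months if config is not None else (0.0, 3.0, 12.0, 24.0)
        p = root / "truth.csv"
        pd.concat([t.table(tps) for t in truths], ignore_index=True).to_csv(p, index=False)
        files.append(p)
        p = root / "truth_slopes.csv"
        rows = []
        for t in truths:
            for dof, s in t.slopes_early.items():
                rows.append(
                    {
                        "subject": t.subject, "segment": t.segment, "dof": dof,
                        "slope_early": s, "slope_late": t.slopes_late.get(dof, 0.0),
                        "breakpoint_months": t.breakpoint_months,
                    }
                )
        pd.DataFrame(rows).to_csv(p, index=False)
        files.append(p)
    if plan_table is not None:
        p = root / "plan.csv"
        plan_table.to_csv(p, index=False)
        files.append(p)

    for exam in exams:
        d = root / "exams" / exam_id(exam)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "subject": exam.subject,
            "side": exam.side,
            "method": exam.method,
            "timepoint_months": exam.timepoint_months,
            "replicate": exam.replicate,
            "patient_pose": exam.patient_pose.to_dict(),
        }
        p = d / "meta.json"
        p.write_text(json.dumps(meta, indent=1, sort_keys=True))
        files.append(p)

        rows = []
        for segment, ps in (("pelvis", exam.pelvis_markers), ("femur", exam.femur_markers)):
            for lab, (x, y, z) in zip(ps.labels, ps.coords):
                rows.append(
                    {
                        "subject": exam.subject, "segment": segment, "marker_id": lab,
                        "x": repr(float(x)), "y": repr(float(y)), "z": repr(float(z)),
                    }
                )
        p = d / "markers.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        files.append(p)

        for segment, cloud in exam.implant_clouds.items():
            p = d / f"{segment}.ply"
            _write_ply(p, cloud.coords)
            files.append(p)
        p = d / "landmarks.json"
        p.write_text(
            json.dumps(
                {
                    seg: {k: list(map(float, v)) for k, v in lms.items()}
                    for seg, lms in exam.implant_landmarks.items()
                },
                indent=1,
                sort_keys=True,
            )
        )
        files.append(p)

    manifest = {
        "seed": config.seed if config is not None else None,
        "n_exams": len(exams),
        "files": {str(f.relative_to(root)): sha256_file(f) for f in sorted(files)},
    }
    mpath = root / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def _load_markers(path: Path) -> dict[str, PointSet]:
    df = pd.read_csv(path)
    required = {"segment", "marker_id", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    out = {}
    for i, row in df.iterrows():
        for c in ("x", "y", "z"):
            try:
                v = float(row[c])
            except (TypeError, ValueError):
                raise ValueError(f"{path}: non-numeric {c!r} in row {i} ({row[c]!r})")
            if not np.isfinite(v):
                raise ValueError(f"{path}: non-finite {c!r} in row {i}")
    for segment, grp in df.groupby("segment"):
        out[segment] = PointSet(
            grp[["x", "y", "z"]].to_numpy(dtype=float),
            grp["marker_id"].astype(str).to_numpy(dtype=object),
        )
    return out


def load_study(directory: str | Path) -> tuple[list[Examination], StudyConfig | None]:
    """Load the examinations (and config, if present) of a serialized
    study. Truth and plan tables are plain CSV, readable directly."""
    root = Path(directory)
    config = None
    if (root / "config.yaml").exists():
        config = StudyConfig.model_validate(yaml.safe_load((root / "config.yaml").read_text()))
    exams = []
    for d in sorted((root / "exams").iterdir()):
        if not d.is_dir():
            continue
        meta = json.loads((d / "meta.json").read_text())
        markers = _load_markers(d / "markers.csv")
        lms = {
            seg: {k: np.array(v, dtype=float) for k, v in d2.items()}
            for seg, d2 in json.loads((d / "landmarks.json").read_text()).items()
        }
        clouds = {}
        for ply in sorted(d.glob("*.ply")):
            clouds[ply.stem] = PointSet(_read_ply(ply))
        exams.append(
            Examination(
                subject=meta["subject"],
                side=meta["side"],
                method=meta["method"],
                timepoint_months=float(meta["timepoint_months"]),
                replicate=int(meta["replicate"]),
                pelvis_markers=markers["pelvis"],
                femur_markers=markers["femur"],
                implant_clouds=clouds,
                implant_landmarks=lms,
                patient_pose=RigidTransform.from_dict(meta["patient_pose"]),
            )
        )
    return exams, config


def write_long_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long table missing columns {missing}")
    df.to_csv(path, index=False, columns=LONG_COLUMNS, float_format="%.10g")


def read_long_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: long table missing columns {missing}")
    df["flags"] = df["flags"].fillna("").astype(str)
    return df
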