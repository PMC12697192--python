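"""Study-level orchestration: examinations in, tidy migration table out."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .kinematics import analyze_pair
from .synthetic import Examination, ImplantModel, make_implant_model

__all__ = ["analyze_study", "migration_row"]

log = logging.getLogger(__name__)


def migration_row(exam: Examination, dof_name: str, value: float, result) -> dict:
    return {
        "subject": exam.subject,
        "side": exam.side,
        "method": exam.method,
        "segment": result.segment,
        "dof": dof_name,
        "timepoint_months": exam.timepoint_months,
        "replicate": exam.replicate,
        "value": value,
        "cn": result.condition_number,
        "me": result.mean_error,
        "flags": ";".join(result.flags),
    }


def analyze_study(
    exams: Sequence[Examination],
    models: Mapping[str, ImplantModel] | None = None,
    translation_reference: str = "centroid",
) -> pd.DataFrame:
    """Measure migration for every follow-up examination of a study.

    Each (subject, method) group is analysed against its baseline
    (timepoint 0, replicate 1) examination: the stem against the femur
    markers, the cup against the pelvis markers. Returns the tidy long
    table (one row per DOF, Euclidean totals included), with the
    reference-fit quality metrics and gate flags carried on every row;
    flagged records are logged, never dropped.

    `models` maps segment name to its implant model; by default the
    canonical parametric models are used (matching the generator's
    defaults).
    """
    if models is None:
        segments = set()
        for e in exams:
            segments |= set(e.implant_clouds)
        models = {seg: make_implant_model(seg) for seg in sorted(segments)}

    rows: list[dict] = []
    groups: dict[tuple[str, str], list[Examination]] = {}
    for e in exams:
        groups.setdefault((e.subject, e.method), []).append(e)

    for (subject, method), group in sorted(groups.items()):
        baselines = [e for e in group if e.timepoint_months == 0 and e.replicate == 1]
        if not baselines:
            raise ValueError(f"no baseline examination for {subject}/{method}")
        baseline = baselines[0]
        followups = [e for e in group if e is not baseline]
        for exam in sorted(followups, key=lambda e: (e.timepoint_months, e.replicate)):
            for segment in sorted(exam.implant_clouds):
                result = analyze_pair(
                    baseline,
                    exam,
                    models[segment],
                    segment=segment,
                    translation_reference=translation_reference,
                )
                if result.flags:
                    log.warning(
                        "quality gate %s for %s/%s %s at %g months (CN=%.1f, ME=%.3f)",
                        ",".join(result.flags), subject, method, segment,
                        exam.timepoint_months, result.condition_number, result.mean_error,
                    )
                for dof_name, value in result.as_dict().items():
                    rows.append(migration_row(exam, dof_name, value, result))
    return pd.DataFrame(rows)
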