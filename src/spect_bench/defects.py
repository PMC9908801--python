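"""Artificial perfusion defects: VOI count reduction and projection-domain
insertion.

A defect study is built from a *normal* study: counts inside a drawn VOI of
the reconstructed normal are reduced by the defect severity (presets 40 %
and 70 %), the removed counts form a lesion-difference volume, and that
difference is forward projected and subtracted from the normal acquisition
data — so the same known lesion can be inserted consistently into the full-,
half- and quarter-time projection sets of one study.  Insertion never
increases a projection bin; negative bins are clamped at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import SystemGeometry
from .phantom import DefectVOI
from .projector import ProjectionSet, SystemOperator, forward_project
from .volume import AttenuationMap, Volume

__all__ = ["apply_voi_reduction", "insert_defect_in_projections", "StudyRecord", "defect_manifest"]


def apply_voi_reduction(vol: Volume, voi: DefectVOI) -> tuple[Volume, Volume]:
    """Reduce counts inside the VOI by its severity.

    Returns ``(reduced, lesion_diff)`` where ``lesion_diff = vol - reduced``
    is the non-negative difference used for projection-domain insertion.
    """
    if voi.mask.shape != vol.shape:
        raise ValueError(f"VOI grid {voi.mask.shape} does not match volume {vol.shape}")
    mask = voi.mask.data > 0
    if not mask.any():
        raise ValueError("defect mask is empty")
    if not (mask & (vol.data != 0)).any() and vol.data.any():
        raise ValueError("defect mask does not intersect the activity distribution")
    reduced = vol.data.copy()
    reduced[mask] *= 1.0 - voi.severity
    diff = vol.data - reduced
    return vol.like(reduced), vol.like(diff)


def insert_defect_in_projections(
    normal_proj: ProjectionSet,
    lesion_diff: Volume,
    attn: AttenuationMap | None,
    geom: SystemGeometry,
    op: SystemOperator | None = None,
) -> ProjectionSet:
    """Subtract the forward-projected lesion difference from normal data.

    ``out = max(normal - FP(lesion_diff), 0)`` — deterministic, applied
    identically to every acquisition-time dataset of the study.
    """
    if np.any(lesion_diff.data < 0):
        raise ValueError("lesion difference must be non-negative")
    if normal_proj.geometry != geom:
        raise ValueError("projection geometry mismatch")
    if op is not None:
        lesion_proj = op.forward(lesion_diff.data)
    else:
        lesion_proj = forward_project(lesion_diff, attn, geom).counts
    return ProjectionSet(np.clip(normal_proj.counts - lesion_proj, 0.0, None), geom)


@dataclass
class StudyRecord:
    """Manifest entry for one generated study."""

    study_id: str
    arm: str  # "stress" | "rest"
    acquisition_time: str  # "full" | "half" | "three_eighths" | "quarter"
    defect: bool
    severity: float | None = None
    location: str | None = None
    seed: int | None = None
    files: dict = field(default_factory=dict)


def defect_manifest(
    normal_seeds: list[int], arm: str, severities: tuple[float, ...] = (0.4, 0.7),
    times: tuple[str, ...] = ("full", "half", "quarter"),
) -> list[StudyRecord]:
    """Enumerate the defect-study bookkeeping for one arm.

    N normals x 1 lesion x len(severities) severities gives ``2N`` defect
    studies per arm at each acquisition time (20 normals -> 40 defect
    studies), before any reconstruction happens.
    """
    records = []
    for seed in normal_seeds:
        for sev in severities:
            for t in times:
                records.append(
                    StudyRecord(
                        study_id=f"{arm}-s{seed}-sev{int(sev * 100)}-{t}",
                        arm=arm, acquisition_time=t, defect=True,
                        severity=sev, seed=seed,
                    )
                )
    return records


def save_manifest(records: list[StudyRecord], path: str) -> None:
    with open(path, "w") as f:
        json.dump([r.__dict__ for r in records], f, indent=1)
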