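"""Quantitative surrogate endpoints: diameter and volume change at BOR.

The primary endpoints are subtraction-based: the change in the sum of
longest diameters (per criteria system) and the change in total tumor
volume between the best-overall-response (BOR) date and baseline.  For
volumetry the BOR date is the follow-up scan with the smallest total
lesion volume (all lesions, measurable or not), and the change is

    delta_volume = V(BOR) - V(baseline)   [mm^3]

Subtraction rather than a ratio is the primary form because many brain
metastases are sub-measurable at baseline (a ratio's per-lesion
denominator can be zero); the percent change of the total volume is
reported as auxiliary output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .criteria import Category, PatientAssessment
from .data_model import PatientCourse, Scan

__all__ = [
    "VolumeIncompleteError",
    "VolumetricSummary",
    "total_volume",
    "volumetric_summary",
    "os_analysis_filter",
]


class VolumeIncompleteError(ValueError):
    """A scan needed for volumetry has a lesion without a volume."""


@dataclass(frozen=True)
class VolumetricSummary:
    """Volumetric endpoint for one patient.

    ``percent_change`` is ``100 * delta_volume / baseline_volume`` and
    is ``None`` when the baseline volume is zero.
    """

    patient_id: str
    baseline_volume: float
    bor_volume: float
    bor_day: int
    delta_volume: float
    percent_change: float | None
    n_lesions_baseline: int
    n_lesions_bor: int


def total_volume(scan: Scan) -> float:
    """Sum of all lesion volumes on one scan (mm^3).

    Every lesion must carry a volume; otherwise the patient is
    volume-incomplete and :class:`VolumeIncompleteError` is raised.
    """
    if not scan.has_complete_volumes():
        missing = [m.lesion_id for m in scan.measurements if m.volume is None]
        raise VolumeIncompleteError(
            f"scan at day {scan.scan_day}: lesions {missing} have no volume"
        )
    return float(sum(m.volume for m in scan.measurements))


def volumetric_summary(course: PatientCourse) -> VolumetricSummary:
    """Volumetric BOR and change in volumetry for one patient.

    The BOR scan is the follow-up minimizing total volume (earliest on
    ties); baseline is excluded from the minimization so that growth
    yields a positive change.
    """
    baseline_volume = total_volume(course.baseline)
    volumes = [(s, total_volume(s)) for s in course.followups]
    if not volumes:
        raise ValueError(f"patient {course.patient_id!r}: no follow-up scan")
    bor_scan, bor_volume = min(volumes, key=lambda sv: (sv[1], sv[0].scan_day))
    delta = bor_volume - baseline_volume
    percent = 100.0 * delta / baseline_volume if baseline_volume > 0 else None
    return VolumetricSummary(
        patient_id=course.patient_id,
        baseline_volume=baseline_volume,
        bor_volume=bor_volume,
        bor_day=bor_scan.scan_day,
        delta_volume=delta,
        percent_change=percent,
        n_lesions_baseline=len(course.baseline.measurements),
        n_lesions_bor=len(bor_scan.measurements),
    )


def os_analysis_filter(
    assessments: dict[str, PatientAssessment],
) -> tuple[list[str], list[str]]:
    """Split patients for the overall-survival analysis.

    Patients progressing at the *first* follow-up scan under the
    reference criteria stopped therapy after a single course; they are
    excluded from OS modeling (short follow-up, confounding subsequent
    treatment).  ``assessments`` maps patient id to that patient's
    adjudication under the reference criteria (RANO-BM by default in
    the pipeline).  Returns ``(included_ids, excluded_ids)``.
    """
    included, excluded = [], []
    for pid, a in assessments.items():
        first = a.timepoints[0] if a.timepoints else None
        if first is not None and first.category in (
            Category.PD,
            Category.PRELIMINARY_PD,
        ) and a.progression_day == first.scan_day:
            excluded.append(pid)
        else:
            included.append(pid)
    return included, excluded
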