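"""Domain types for longitudinal brain-metastasis lesion data.

The atomic observation is a single lesion's measurement on a single MRI
scan (:class:`LesionMeasurement`).  A :class:`Scan` bundles all lesions
measured on one day, and a :class:`PatientCourse` is the time-ordered
sequence of scans for one patient together with the survival outcome.

Time convention: scan days are integer days relative to the start of
immune-checkpoint-inhibitor (ICI) therapy, so the baseline scan has
``scan_day <= 0`` (baseline imaging is acquired within two months before
therapy start).  Survival times (``os_day``, ``last_imaging_day``) are
days from the baseline imaging date.  Months are reported as
``days / DAYS_PER_MONTH`` with a fixed divisor so results are
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DAYS_PER_MONTH",
    "ValidationError",
    "LesionMeasurement",
    "Scan",
    "PatientCourse",
    "days_to_months",
]

#: Fixed day/month conversion (365.25 / 12).
DAYS_PER_MONTH = 30.4375


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


def days_to_months(days: float) -> float:
    """Convert days to months using the fixed 30.4375-day month."""
    return days / DAYS_PER_MONTH


@dataclass(frozen=True)
class LesionMeasurement:
    """One lesion's size on one scan.

    Parameters
    ----------
    lesion_id
        Opaque label, stable across scans of the same patient.
    longest_diameter
        Longest axial diameter in mm; ``0`` encodes complete
        disappearance of a previously seen lesion.
    smallest_diameter
        Shortest orthogonal diameter in mm, or ``None`` for 2D-only
        datasets.  Used for the 5 mm measurability cutoff of mRECIST.
    volume
        Segmented lesion volume in mm^3, or ``None`` when volumetry is
        unavailable.
    location
        Optional free-text anatomic location.
    """

    lesion_id: str
    longest_diameter: float
    smallest_diameter: float | None = None
    volume: float | None = None
    location: str | None = None

    def __post_init__(self) -> None:
        if self.longest_diameter < 0:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: negative longest diameter "
                f"{self.longest_diameter}"
            )
        if self.smallest_diameter is not None:
            if self.smallest_diameter < 0:
                raise ValidationError(
                    f"lesion {self.lesion_id!r}: negative smallest diameter "
                    f"{self.smallest_diameter}"
                )
            if self.smallest_diameter > self.longest_diameter:
                raise ValidationError(
                    f"lesion {self.lesion_id!r}: smallest diameter "
                    f"{self.smallest_diameter} exceeds longest diameter "
                    f"{self.longest_diameter}"
                )
        if self.volume is not None and self.volume < 0:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: negative volume {self.volume}"
            )


@dataclass(frozen=True)
class Scan:
    """All lesion measurements from one MRI examination.

    ``non_target_pd`` is an explicit reader-supplied flag marking
    unequivocal progression of non-target (non-measurable) disease at
    this scan; it is an input, not a computed quantity.
    """

    scan_day: int
    measurements: tuple[LesionMeasurement, ...]
    non_target_pd: bool = False

    def __post_init__(self) -> None:
        ids = [m.lesion_id for m in self.measurements]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"scan at day {self.scan_day}: duplicate lesion ids {dupes}"
            )

    @property
    def lesion_ids(self) -> frozenset[str]:
        return frozenset(m.lesion_id for m in self.measurements)

    def lesion(self, lesion_id: str) -> LesionMeasurement | None:
        for m in self.measurements:
            if m.lesion_id == lesion_id:
                return m
        return None

    def has_complete_volumes(self) -> bool:
        return all(m.volume is not None for m in self.measurements)


@dataclass
class PatientCourse:
    """Time-ordered scans for one patient plus the survival outcome.

    ``scans[0]`` is the baseline examination (``scan_day <= 0``, within
    60 days before therapy start); at least one follow-up is required
    for the patient to be assessable.  ``os_day`` counts days from
    baseline imaging to death (``os_event=True``) or to the censoring
    date; ``last_imaging_day`` is the last follow-up MRI date, used as
    the progression-free-survival censoring date.
    """

    patient_id: str
    scans: list[Scan] = field(default_factory=list)
    os_day: int = 0
    os_event: bool = False
    last_imaging_day: int | None = None

    def __post_init__(self) -> None:
        if len(self.scans) < 2:
            raise ValidationError(
                f"patient {self.patient_id!r}: needs a baseline and at least "
                f"one follow-up scan, got {len(self.scans)}"
            )
        days = [s.scan_day for s in self.scans]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"patient {self.patient_id!r}: scan days not strictly "
                f"increasing: {days}"
            )
        if self.scans[0].scan_day > 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: first scan day "
                f"{self.scans[0].scan_day} is after therapy start; baseline "
                f"must be on or before day 0"
            )
        if self.scans[0].scan_day < -60:
            raise ValidationError(
                f"patient {self.patient_id!r}: baseline scan day "
                f"{self.scans[0].scan_day} is more than 60 days before "
                f"therapy start"
            )
        if self.os_day < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: negative os_day {self.os_day}"
            )
        if self.last_imaging_day is None:
            self.last_imaging_day = self.scans[-1].scan_day

    @property
    def baseline(self) -> Scan:
        return self.scans[0]

    @property
    def followups(self) -> list[Scan]:
        return self.scans[1:]
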