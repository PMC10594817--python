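"""Response-criteria adjudication for serial brain-metastasis MRI.

Implements three diameter-based criteria systems for intracranial
response under immune-checkpoint-inhibitor therapy:

mRECIST
    target lesions measurable at >= 5 mm in the *smallest* diameter;
    appearance of any new lesion is immediate progression.
RANO-BM
    target lesions measurable at >= 10 mm in the longest diameter
    (3 mm slice thickness, so the 5 mm thin-slice concession does not
    apply); a new lesion is not automatic progression — its diameter is
    added to the sum of longest diameters (SLD), and progression is
    judged on the combined sum.
iRANO-BM
    RANO-BM rules plus a pseudoprogression guard: progression first
    seen within 6 months (182 days) of therapy start is *preliminary*
    and must be confirmed on follow-up imaging at least 3 months
    (91 days) later; if the confirmatory scan no longer meets
    progression criteria against the same nadir, the preliminary call
    is revoked and the timepoint re-classified.

Common thresholds (RECIST 1.1 / RANO-BM): partial response at a >= 30%
SLD decrease from baseline, progression at a >= 20% SLD increase over
the nadir that is also a >= 5 mm absolute increase; complete response
when all target disease disappears.  The nadir is the smallest SLD
observed on study, baseline included.  Category precedence is
PD > CR > PR > SD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .data_model import DAYS_PER_MONTH, PatientCourse, Scan, days_to_months

__all__ = [
    "Category",
    "CriteriaConfig",
    "IranoConfirmation",
    "TimepointAssessment",
    "PatientAssessment",
    "MRECIST",
    "RANO_BM",
    "IRANO_BM",
    "PRESETS",
    "select_targets",
    "compute_sld",
    "classify_timepoint",
    "apply_irano_confirmation",
    "determine_bor",
    "assess_patient",
    "UnassessableError",
]


class Category(str, enum.Enum):
    """Ordered response categories (best to worst)."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    PRELIMINARY_PD = "preliminary_PD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ranking used for best-overall-response determination (lower = better).
_BOR_RANK = {Category.CR: 0, Category.PR: 1, Category.SD: 2}


class UnassessableError(ValueError):
    """Patient has no measurable disease at baseline under a criteria set."""


@dataclass(frozen=True)
class IranoConfirmation:
    """Pseudoprogression-confirmation window parameters (days).

    ``window_days``: progression first seen at or before this many days
    after therapy start is preliminary.  ``confirm_days``: minimum gap
    to the confirmatory scan.  Boundaries are inclusive ("within 6
    months" means <= 182 days).
    """

    window_days: int = 182
    confirm_days: int = 91


@dataclass(frozen=True)
class CriteriaConfig:
    """Parameterization of one criteria system.

    ``eligibility_dimension`` selects which diameter the measurability
    cutoff applies to ('smallest' for mRECIST, 'longest' for
    RANO-BM/iRANO-BM); the SLD always sums longest diameters.
    ``new_lesion_policy`` is ``'immediate_pd'`` (mRECIST) or
    ``'add_to_sld'`` (RANO-BM/iRANO-BM).
    """

    name: str
    measurable_cutoff: float
    eligibility_dimension: str  # 'smallest' | 'longest'
    new_lesion_policy: str  # 'immediate_pd' | 'add_to_sld'
    max_targets: int = 5
    pr_threshold: float = 0.30
    pd_threshold: float = 0.20
    pd_absolute: float = 5.0
    confirmation: IranoConfirmation | None = None

    def __post_init__(self) -> None:
        if self.measurable_cutoff <= 0 or self.pr_threshold <= 0 or self.pd_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.max_targets < 1:
            raise ValueError("max_targets must be >= 1")
        if self.eligibility_dimension not in ("smallest", "longest"):
            raise ValueError(f"unknown eligibility dimension {self.eligibility_dimension!r}")
        if self.new_lesion_policy not in ("immediate_pd", "add_to_sld"):
            raise ValueError(f"unknown new-lesion policy {self.new_lesion_policy!r}")


MRECIST = CriteriaConfig(
    name="mRECIST",
    measurable_cutoff=5.0,
    eligibility_dimension="smallest",
    new_lesion_policy="immediate_pd",
)
RANO_BM = CriteriaConfig(
    name="RANO-BM",
    measurable_cutoff=10.0,
    eligibility_dimension="longest",
    new_lesion_policy="add_to_sld",
)
IRANO_BM = CriteriaConfig(
    name="iRANO-BM",
    measurable_cutoff=10.0,
    eligibility_dimension="longest",
    new_lesion_policy="add_to_sld",
    confirmation=IranoConfirmation(),
)

PRESETS: dict[str, CriteriaConfig] = {
    c.name: c for c in (MRECIST, RANO_BM, IRANO_BM)
}


def load_criteria_config(path) -> CriteriaConfig:
    """Read a criteria configuration from a plain-text key=value file.

    A ``preset`` key selects one of the shipped presets (mRECIST,
    RANO-BM, iRANO-BM); any further keys override individual fields.
    Confirmation-window fields use ``confirmation_window_days`` and
    ``confirmation_confirm_days`` (set ``confirmation=none`` to disable).
    """
    import dataclasses
    from pathlib import Path

    entries: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()

    base = PRESETS[entries.pop("preset")] if "preset" in entries else None
    fields = {f.name: f.type for f in dataclasses.fields(CriteriaConfig)}
    kwargs: dict = dataclasses.asdict(base) if base else {}
    if base is not None and base.confirmation is not None:
        kwargs["confirmation"] = base.confirmation
    conf_window = entries.pop("confirmation_window_days", None)
    conf_confirm = entries.pop("confirmation_confirm_days", None)
    if entries.pop("confirmation", "").lower() == "none":
        kwargs["confirmation"] = None
    elif conf_window or conf_confirm:
        prev = kwargs.get("confirmation") or IranoConfirmation()
        kwargs["confirmation"] = IranoConfirmation(
            window_days=int(conf_window or prev.window_days),
            confirm_days=int(conf_confirm or prev.confirm_days),
        )
    for key, value in entries.items():
        if key not in fields:
            raise ValueError(f"unknown criteria config key {key!r}")
        if key in ("name", "eligibility_dimension", "new_lesion_policy"):
            kwargs[key] = value
        elif key == "max_targets":
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return CriteriaConfig(**kwargs)


@dataclass
class TimepointAssessment:
    """Adjudication of one follow-up scan."""

    scan_day: int
    sld: float
    nadir_sld: float
    category: Category
    new_lesion_ids: tuple[str, ...] = ()
    basis: str = ""


@dataclass
class PatientAssessment:
    """Full adjudication of one patient under one criteria system."""

    patient_id: str
    criteria: str
    target_ids: tuple[str, ...]
    baseline_sld: float
    timepoints: list[TimepointAssessment]
    bor_category: Category
    bor_day: int
    bor_sld: float
    progression_day: int | None
    pfs_day: int
    pfs_event: bool
    delta_sld: float
    notes: list[str] = field(default_factory=list)

    @property
    def pfs_months(self) -> float:
        return days_to_months(self.pfs_day)

    @property
    def progressed(self) -> bool:
        return self.progression_day is not None


def select_targets(baseline: Scan, config: CriteriaConfig) -> tuple[str, ...]:
    """Choose up to ``max_targets`` measurable baseline lesions.

    A lesion is eligible when its eligibility dimension (smallest or
    longest diameter per ``config``) is at least the measurability
    cutoff; a missing smallest diameter makes a lesion ineligible under
    a smallest-diameter cutoff.  When more are eligible than allowed,
    the largest by longest diameter are taken, ties broken by
    lexicographic lesion id.  An empty result is permitted and marks
    the patient non-measurable under this criteria set.
    """
    eligible = []
    for m in baseline.measurements:
        dim = (
            m.smallest_diameter
            if config.eligibility_dimension == "smallest"
            else m.longest_diameter
        )
        if dim is not None and dim >= config.measurable_cutoff:
            eligible.append(m)
    eligible.sort(key=lambda m: (-m.longest_diameter, m.lesion_id))
    return tuple(m.lesion_id for m in eligible[: config.max_targets])


def compute_sld(
    scan: Scan,
    target_ids: tuple[str, ...],
    config: CriteriaConfig,
    new_lesion_ids: tuple[str, ...] = (),
) -> float:
    """Sum of longest diameters of target lesions at one scan (mm).

    A target absent from the scan contributes 0 (disappeared).  Under
    the ``add_to_sld`` policy the longest diameters of new lesions
    (``new_lesion_ids``, lesions absent at baseline that have appeared
    at or before this scan) present on the scan are added to the sum.
    """
    total = 0.0
    for tid in target_ids:
        m = scan.lesion(tid)
        if m is not None:
            total += m.longest_diameter
    if config.new_lesion_policy == "add_to_sld":
        for nid in new_lesion_ids:
            m = scan.lesion(nid)
            if m is not None:
                total += m.longest_diameter
    return total


def classify_timepoint(
    sld: float,
    baseline_sld: float,
    nadir_sld: float,
    new_lesions_present: bool,
    non_target_pd_flag: bool,
    config: CriteriaConfig,
    *,
    suppress_pd: bool = False,
) -> tuple[Category, str]:
    """Classify one follow-up scan; returns (category, basis note).

    Progression triggers: a new lesion under the ``immediate_pd``
    policy, reader-flagged non-target progression, or an SLD increase
    of >= ``pd_threshold`` over the nadir that is also >=
    ``pd_absolute`` mm.  Precedence is PD > CR > PR > SD.
    ``suppress_pd`` disables the progression triggers (used when a
    preliminary progression call is revoked and the timepoint must be
    re-classified on size criteria alone).
    """
    if not suppress_pd:
        if new_lesions_present and config.new_lesion_policy == "immediate_pd":
            return Category.PD, "new lesion"
        if non_target_pd_flag:
            return Category.PD, "non-target lesion progression"
        growth = sld - nadir_sld
        if (
            nadir_sld >= 0
            and sld >= nadir_sld * (1.0 + config.pd_threshold)
            and growth >= config.pd_absolute
        ):
            if nadir_sld > 0:
                pct = 100.0 * growth / nadir_sld
                return Category.PD, f"SLD +{pct:.1f}% vs nadir"
            return Category.PD, "new-lesion-driven growth from zero baseline"
    if sld == 0 and not new_lesions_present:
        return Category.CR, "all target disease disappeared"
    if baseline_sld > 0 and sld <= baseline_sld * (1.0 - config.pr_threshold):
        pct = 100.0 * (sld - baseline_sld) / baseline_sld
        return Category.PR, f"SLD {pct:.1f}% vs baseline"
    return Category.SD, ""


def _new_lesions_up_to(course: PatientCourse, scan_index: int) -> tuple[str, ...]:
    """Ids of lesions absent at baseline first seen at/before follow-up i."""
    baseline_ids = course.baseline.lesion_ids
    seen: list[str] = []
    for s in course.scans[1 : scan_index + 1]:
        for m in s.measurements:
            if m.lesion_id not in baseline_ids and m.lesion_id not in seen:
                seen.append(m.lesion_id)
    return tuple(seen)


def _raw_timepoints(
    course: PatientCourse, target_ids: tuple[str, ...], config: CriteriaConfig
) -> tuple[float, list[TimepointAssessment]]:
    """Baseline SLD and per-follow-up assessments without confirmation."""
    baseline_sld = compute_sld(course.baseline, target_ids, config)
    nadir = baseline_sld
    out: list[TimepointAssessment] = []
    for i, scan in enumerate(course.followups, start=1):
        new_ids = _new_lesions_up_to(course, i)
        sld = compute_sld(scan, target_ids, config, new_lesion_ids=new_ids)
        nadir = min(nadir, sld)
        category, basis = classify_timepoint(
            sld,
            baseline_sld,
            nadir,
            new_lesions_present=bool(new_ids),
            non_target_pd_flag=scan.non_target_pd,
            config=config,
        )
        out.append(
            TimepointAssessment(
                scan_day=scan.scan_day,
                sld=sld,
                nadir_sld=nadir,
                category=category,
                new_lesion_ids=new_ids,  # every new lesion seen up to this scan
                basis=basis,
            )
        )
    return baseline_sld, out


def apply_irano_confirmation(
    raw_timepoints: list[TimepointAssessment],
    baseline_sld: float,
    config: CriteriaConfig,
    ici_start_day: int = 0,
) -> tuple[list[TimepointAssessment], int | None, list[str]]:
    """Apply the pseudoprogression confirmation window to raw calls.

    Walks the base-rule (RANO-BM) assessments as a state machine.  A
    progression call first occurring within ``window_days`` of therapy
    start becomes preliminary; the first scan at least ``confirm_days``
    later decides it: still meeting progression criteria against the
    *same* nadir (no nadir reset inside the window) confirms it with
    the progression date backdated to the preliminary scan, otherwise
    the call is revoked, the affected scans are re-classified on size
    criteria alone, and scanning resumes for fresh progression.  A
    preliminary call with no qualifying later scan remains unconfirmed
    (the patient is censored for progression-free survival).
    Progression first seen after the window is immediate.

    Returns ``(timepoints, progression_day, notes)``.
    """
    assert config.confirmation is not None
    window = config.confirmation.window_days
    confirm = config.confirmation.confirm_days
    tps = [replace(t) for t in raw_timepoints]
    notes: list[str] = []
    i = 0
    while i < len(tps):
        t = tps[i]
        if t.category is not Category.PD:
            i += 1
            continue
        if t.scan_day - ici_start_day > window:
            return tps, t.scan_day, notes
        # preliminary call: find the first scan >= confirm_days later
        t.category = Category.PRELIMINARY_PD
        t.basis = (t.basis + "; " if t.basis else "") + "preliminary, confirmation required"
        qual = next(
            (j for j in range(i + 1, len(tps)) if tps[j].scan_day - t.scan_day >= confirm),
            None,
        )
        if qual is None:
            notes.append(
                f"preliminary progression at day {t.scan_day} unconfirmed at end of "
                f"follow-up; censored"
            )
            return tps, None, notes
        q = tps[qual]
        still_pd = (
            q.category is Category.PD
            and t.nadir_sld >= 0
            and q.sld >= t.nadir_sld * (1.0 + config.pd_threshold)
            and q.sld - t.nadir_sld >= config.pd_absolute
        ) or (q.category is Category.PD and "non-target" in q.basis)
        if still_pd:
            notes.append(
                f"progression at day {t.scan_day} confirmed at day {q.scan_day}"
            )
            return tps, t.scan_day, notes
        # revoked: re-classify the preliminary scan and any interim PD calls
        notes.append(
            f"preliminary progression at day {t.scan_day} revoked at day {q.scan_day}"
        )
        for j in range(i, qual):
            tj = tps[j]
            if tj.category in (Category.PD, Category.PRELIMINARY_PD):
                cat, basis = classify_timepoint(
                    tj.sld,
                    baseline_sld,
                    tj.nadir_sld,
                    new_lesions_present=bool(tj.new_lesion_ids),
                    non_target_pd_flag=False,
                    config=config,
                    suppress_pd=True,
                )
                tj.category = cat
                tj.basis = (basis + "; " if basis else "") + "progression revoked"
        i = qual  # the qualifying scan itself is re-examined (may be a fresh PD)
    return tps, None, notes


def determine_bor(
    timepoints: list[TimepointAssessment],
    progression_day: int | None = None,
) -> tuple[Category, int, float]:
    """Best overall response: best category before progression.

    Ranks CR > PR > SD over the scans strictly before the progression
    date (all scans when no progression); the earliest scan attaining
    the best category is the BOR date.  An unconfirmed preliminary
    progression ranks as stable disease.  If the first post-baseline
    scan is already progression, the BOR is PD at that scan.
    Returns ``(category, day, sld_at_bor)``.
    """
    if not timepoints:
        raise ValueError("no post-baseline assessments")
    pre = [
        t
        for t in timepoints
        if progression_day is None or t.scan_day < progression_day
    ]
    candidates = [t for t in pre if t.category in _BOR_RANK or t.category is Category.PRELIMINARY_PD]
    if not candidates:
        # progression at the very first follow-up
        first = timepoints[0]
        return Category.PD, first.scan_day, first.sld
    best = min(
        candidates,
        key=lambda t: (_BOR_RANK.get(t.category, _BOR_RANK[Category.SD]), t.scan_day),
    )
    cat = best.category if best.category in _BOR_RANK else Category.SD
    return cat, best.scan_day, best.sld


def assess_patient(course: PatientCourse, config: CriteriaConfig) -> PatientAssessment:
    """Adjudicate one patient's serial scans under one criteria system.

    Raises :class:`UnassessableError` when no baseline lesion meets the
    measurability cutoff.  Progression-free survival runs from baseline
    imaging to the earlier of progression and death; a patient with
    neither is censored at the last imaging date.
    """
    target_ids = select_targets(course.baseline, config)
    if not target_ids:
        raise UnassessableError(
            f"patient {course.patient_id!r}: no measurable lesion at baseline "
            f"under {config.name}"
        )
    baseline_sld, raw = _raw_timepoints(course, target_ids, config)
    notes: list[str] = []
    if config.confirmation is not None:
        timepoints, progression_day, notes = apply_irano_confirmation(
            raw, baseline_sld, config
        )
    else:
        timepoints = raw
        progression_day = next(
            (t.scan_day for t in timepoints if t.category is Category.PD), None
        )
    bor_category, bor_day, bor_sld = determine_bor(timepoints, progression_day)

    if progression_day is not None and course.os_event:
        pfs_day, pfs_event = min(progression_day, course.os_day), True
    elif progression_day is not None:
        pfs_day, pfs_event = progression_day, True
    elif course.os_event:
        pfs_day, pfs_event = course.os_day, True
    else:
        pfs_day, pfs_event = int(course.last_imaging_day), False

    return PatientAssessment(
        patient_id=course.patient_id,
        criteria=config.name,
        target_ids=target_ids,
        baseline_sld=baseline_sld,
        timepoints=timepoints,
        bor_category=bor_category,
        bor_day=bor_day,
        bor_sld=bor_sld,
        progression_day=progression_day,
        pfs_day=pfs_day,
        pfs_event=pfs_event,
        delta_sld=bor_sld - baseline_sld,
        notes=notes,
    )
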