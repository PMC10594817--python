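"""End-to-end cohort analysis: adjudicate, tabulate, compare, model.

Ties the criteria engine, endpoints, and statistics modules together
into the cohort-level workflow: adjudicate every patient under the
three criteria systems, assemble the per-patient-per-criteria endpoint
table, and run the comparison (response rates, kappa, McNemar) and
survival (KM, log-rank, Wilcoxon, Spearman, Cox) batteries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import endpoints as ep
from . import stats as st
from . import survival as sv
from .criteria import (
    Category,
    CriteriaConfig,
    IRANO_BM,
    MRECIST,
    PatientAssessment,
    RANO_BM,
    UnassessableError,
    assess_patient,
)
from .data_model import PatientCourse, days_to_months

__all__ = [
    "CohortAnalysis",
    "adjudicate_cohort",
    "build_cohort_table",
    "compare_criteria",
    "survival_battery",
]

DEFAULT_CRITERIA = (MRECIST, RANO_BM, IRANO_BM)


@dataclass
class CohortAnalysis:
    """Adjudication results for a cohort under several criteria systems."""

    assessments: dict[str, dict[str, PatientAssessment]]
    volumetrics: dict[str, ep.VolumetricSummary]
    unassessable: dict[str, list[str]]
    volume_incomplete: list[str]
    os_excluded: list[str] = field(default_factory=list)
    courses: dict[str, PatientCourse] = field(default_factory=dict)

    def co_assessed_ids(self, *criteria_names: str) -> list[str]:
        """Patients assessable under every listed criteria system."""
        sets = [set(self.assessments[c]) for c in criteria_names]
        common = set.intersection(*sets) if sets else set()
        return sorted(common)


def adjudicate_cohort(
    courses: list[PatientCourse],
    criteria: tuple[CriteriaConfig, ...] = DEFAULT_CRITERIA,
    os_reference: str = "RANO-BM",
) -> CohortAnalysis:
    """Adjudicate every patient under every criteria system.

    Patients without measurable baseline disease under a given system
    are recorded as unassessable for that system; patients with any
    lesion lacking a volume are recorded volume-incomplete and skipped
    by the volumetric endpoint.  The OS-analysis exclusion (progression
    at the first follow-up) is evaluated under ``os_reference``.
    """
    assessments: dict[str, dict[str, PatientAssessment]] = {c.name: {} for c in criteria}
    unassessable: dict[str, list[str]] = {c.name: [] for c in criteria}
    volumetrics: dict[str, ep.VolumetricSummary] = {}
    volume_incomplete: list[str] = []
    for course in courses:
        for config in criteria:
            try:
                assessments[config.name][course.patient_id] = assess_patient(
                    course, config
                )
            except UnassessableError:
                unassessable[config.name].append(course.patient_id)
        try:
            volumetrics[course.patient_id] = ep.volumetric_summary(course)
        except ep.VolumeIncompleteError:
            volume_incomplete.append(course.patient_id)
    analysis = CohortAnalysis(
        assessments=assessments,
        volumetrics=volumetrics,
        unassessable=unassessable,
        volume_incomplete=volume_incomplete,
        courses={c.patient_id: c for c in courses},
    )
    if os_reference in assessments:
        _, excluded = ep.os_analysis_filter(assessments[os_reference])
        analysis.os_excluded = excluded
    return analysis


def build_cohort_table(analysis: CohortAnalysis) -> pd.DataFrame:
    """One row per patient per criteria system with all endpoints."""
    rows = []
    for crit_name, per_patient in analysis.assessments.items():
        for pid, a in per_patient.items():
            course = analysis.courses[pid]
            vol = analysis.volumetrics.get(pid)
            rows.append(
                {
                    "patient_id": pid,
                    "criteria": crit_name,
                    "bor_category": a.bor_category.value,
                    "bor_day": a.bor_day,
                    "progression_day": a.progression_day,
                    "pfs_months": round(a.pfs_months, 4),
                    "pfs_event": int(a.pfs_event),
                    "delta_sld_mm": round(a.delta_sld, 4),
                    "delta_volume_mm3": (
                        round(vol.delta_volume, 4) if vol is not None else None
                    ),
                    "os_months": round(days_to_months(course.os_day), 4),
                    "os_event": int(course.os_event),
                    "excluded_from_os": int(pid in analysis.os_excluded),
                }
            )
    return pd.DataFrame(rows).sort_values(["criteria", "patient_id"]).reset_index(drop=True)


def compare_criteria(analysis: CohortAnalysis) -> dict:
    """Response-rate table, pairwise kappas, and McNemar tests."""
    names = list(analysis.assessments)
    common = analysis.co_assessed_ids(*names)
    cats = {
        n: [analysis.assessments[n][p].bor_category for p in common] for n in names
    }
    out = {
        "n_co_assessed": len(common),
        "response_rates": st.response_rate_table(cats),
        "kappa": {},
        "mcnemar": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            key = f"{a} vs {b}"
            out["kappa"][key] = st.weighted_kappa(cats[a], cats[b])
            p, (nb, nc) = st.mcnemar_exact(
                [c is Category.PD for c in cats[a]],
                [c is Category.PD for c in cats[b]],
            )
            out["mcnemar"][key] = {"p_value": p, "discordant": (nb, nc)}
    return out


def survival_battery(analysis: CohortAnalysis) -> dict:
    """KM medians, log-rank PD vs non-PD, paired PFS tests, Spearman, Cox."""
    names = list(analysis.assessments)
    common = analysis.co_assessed_ids(*names)
    courses = analysis.courses
    os_months = np.array([days_to_months(courses[p].os_day) for p in common])
    os_events = np.array([courses[p].os_event for p in common])

    out: dict = {
        "os_km": sv.km_fit(os_months, os_events),
        "pfs_km": {},
        "logrank": {},
        "spearman": {},
        "cox": {},
    }
    pfs = {}
    for n in names:
        a = analysis.assessments[n]
        pfs_m = np.array([a[p].pfs_months for p in common])
        pfs_e = np.array([a[p].pfs_event for p in common])
        pfs[n] = pfs_m
        out["pfs_km"][n] = sv.km_fit(pfs_m, pfs_e)
        is_pd = np.array([a[p].bor_category is Category.PD or a[p].progressed for p in common])
        try:
            out["logrank"][n] = sv.logrank_pd_vs_nonpd(os_months, os_events, is_pd, n)
        except ValueError:
            out["logrank"][n] = None
        rho, ci, p = sv.spearman_os_pfs(os_months, pfs_m)
        out["spearman"][n] = {"rho": rho, "ci": ci, "p_value": p}

    out["paired_pfs"] = sv.paired_pfs_comparison(pfs)

    # Cox of OS on each endpoint, excluding first-scan progressors
    included = [p for p in common if p not in analysis.os_excluded]
    os_m = np.array([days_to_months(courses[p].os_day) for p in included])
    os_e = np.array([courses[p].os_event for p in included])
    for n in names:
        a = analysis.assessments[n]
        delta = np.array([a[p].delta_sld for p in included])
        try:
            out["cox"][f"delta_sld_{n}"] = sv.cox_univariate(
                os_m, os_e, delta, unit_scale=1.0, covariate_unit="mm"
            )
        except Exception:  # noqa: BLE001 - fit may fail on degenerate data
            out["cox"][f"delta_sld_{n}"] = None
    # volumetry needs no measurable target lesion: include every
    # volume-complete patient that survives the first-scan-PD exclusion
    vol_ids = [
        p for p in analysis.volumetrics
        if p not in analysis.os_excluded
    ]
    if vol_ids:
        dv = np.array([analysis.volumetrics[p].delta_volume for p in vol_ids])
        os_mv = np.array([days_to_months(courses[p].os_day) for p in vol_ids])
        os_ev = np.array([courses[p].os_event for p in vol_ids])
        try:
            out["cox"]["delta_volume"] = sv.cox_univariate(
                os_mv, os_ev, dv, unit_scale=10_000.0, covariate_unit="10,000 mm^3"
            )
        except Exception:  # noqa: BLE001
            out["cox"]["delta_volume"] = None
    return out
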