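"""Delimited-file readers and writers for lesion-level cohort data.

Two comma-delimited inputs describe a cohort:

``lesions.csv``
    one row per lesion per scan with columns
    ``patient_id,scan_day,lesion_id,longest_diameter_mm,smallest_diameter_mm,volume_mm3,location``
    (the last three may be empty).  An optional ``non_target_pd`` column
    (0/1) carries the reader-supplied non-target progression flag.

``patients.csv``
    one row per patient with columns
    ``patient_id,os_day,os_event,last_imaging_day``.

Validation is total: malformed input raises :class:`ValidationError`
naming the offending row rather than silently coercing.  When a patient
has several pre-treatment scans, the latest scan with ``scan_day <= 0``
is taken as baseline and earlier ones are dropped.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .data_model import LesionMeasurement, PatientCourse, Scan, ValidationError

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_cohort_table",
    "read_cohort_table",
    "write_manifest",
    "LESION_COLUMNS",
    "PATIENT_COLUMNS",
]

LESION_COLUMNS = [
    "patient_id",
    "scan_day",
    "lesion_id",
    "longest_diameter_mm",
    "smallest_diameter_mm",
    "volume_mm3",
    "location",
]
PATIENT_COLUMNS = ["patient_id", "os_day", "os_event", "last_imaging_day"]

#: Column order of the per-patient-per-criteria endpoint table.
COHORT_TABLE_COLUMNS = [
    "patient_id",
    "criteria",
    "bor_category",
    "bor_day",
    "progression_day",
    "pfs_months",
    "pfs_event",
    "delta_sld_mm",
    "delta_volume_mm3",
    "os_months",
    "os_event",
    "excluded_from_os",
]


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _opt_float(value) -> float | None:
    if pd.isna(value) or value == "":
        return None
    return float(value)


def read_cohort(
    lesion_table_path: str | Path, patient_table_path: str | Path
) -> list[PatientCourse]:
    """Read and validate a cohort from the two delimited files.

    Returns one :class:`PatientCourse` per patient, scans sorted by
    ``scan_day``.  Raises :class:`ValidationError` on a missing column,
    a duplicate ``(patient, scan_day, lesion_id)`` row, or any domain
    invariant violation (e.g. smallest diameter exceeding the longest).
    """
    lesion_path = str(lesion_table_path)
    lesions = pd.read_csv(lesion_table_path, dtype={"patient_id": str, "lesion_id": str})
    patients = pd.read_csv(patient_table_path, dtype={"patient_id": str})
    _require_columns(lesions, LESION_COLUMNS[:4], lesion_path)
    _require_columns(patients, PATIENT_COLUMNS, str(patient_table_path))

    dup = lesions.duplicated(subset=["patient_id", "scan_day", "lesion_id"])
    if dup.any():
        row = lesions[dup].iloc[0]
        raise ValidationError(
            f"{lesion_path}: duplicate row for patient {row['patient_id']!r}, "
            f"day {row['scan_day']}, lesion {row['lesion_id']!r}"
        )

    outcome = patients.set_index("patient_id")
    courses: list[PatientCourse] = []
    for pid, grp in lesions.groupby("patient_id", sort=True):
        if pid not in outcome.index:
            raise ValidationError(f"patient {pid!r} has lesions but no outcome row")
        scans = []
        for day, scan_grp in sorted(grp.groupby("scan_day")):
            measurements = []
            for idx, row in scan_grp.iterrows():
                try:
                    measurements.append(
                        LesionMeasurement(
                            lesion_id=str(row["lesion_id"]),
                            longest_diameter=float(row["longest_diameter_mm"]),
                            smallest_diameter=_opt_float(
                                row.get("smallest_diameter_mm")
                            ),
                            volume=_opt_float(row.get("volume_mm3")),
                            location=(
                                None
                                if pd.isna(row.get("location"))
                                else str(row["location"])
                            ),
                        )
                    )
                except ValidationError as err:
                    raise ValidationError(
                        f"{lesion_path} row {idx}: {err}"
                    ) from err
            flag = bool(scan_grp["non_target_pd"].any()) if "non_target_pd" in scan_grp else False
            scans.append(
                Scan(scan_day=int(day), measurements=tuple(measurements), non_target_pd=flag)
            )
        # latest pre-treatment scan is the baseline; drop earlier ones
        pre = [s for s in scans if s.scan_day <= 0]
        post = [s for s in scans if s.scan_day > 0]
        if not pre:
            raise ValidationError(
                f"patient {pid!r}: no baseline scan (scan_day <= 0)"
            )
        scans = [pre[-1]] + post
        out = outcome.loc[pid]
        courses.append(
            PatientCourse(
                patient_id=str(pid),
                scans=scans,
                os_day=int(out["os_day"]),
                os_event=bool(int(out["os_event"])),
                last_imaging_day=int(out["last_imaging_day"]),
            )
        )
    return courses


def write_cohort(
    courses: list[PatientCourse],
    lesion_table_path: str | Path,
    patient_table_path: str | Path,
) -> None:
    """Write a cohort back to the two delimited files (read round-trips)."""
    lesion_rows = []
    patient_rows = []
    for c in courses:
        for s in c.scans:
            for m in s.measurements:
                lesion_rows.append(
                    {
                        "patient_id": c.patient_id,
                        "scan_day": s.scan_day,
                        "lesion_id": m.lesion_id,
                        "longest_diameter_mm": m.longest_diameter,
                        "smallest_diameter_mm": m.smallest_diameter,
                        "volume_mm3": m.volume,
                        "location": m.location,
                        "non_target_pd": int(s.non_target_pd),
                    }
                )
        patient_rows.append(
            {
                "patient_id": c.patient_id,
                "os_day": c.os_day,
                "os_event": int(c.os_event),
                "last_imaging_day": c.last_imaging_day,
            }
        )
    pd.DataFrame(lesion_rows, columns=LESION_COLUMNS + ["non_target_pd"]).to_csv(
        lesion_table_path, index=False
    )
    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).to_csv(
        patient_table_path, index=False
    )


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-patient-per-criteria endpoint table as CSV.

    Missing values (e.g. ``progression_day`` for a censored patient)
    are written as empty cells; ``read_cohort_table`` reproduces the
    frame exactly.
    """
    out = table.reindex(columns=COHORT_TABLE_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6g")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "criteria": str})
    return df.reindex(columns=COHORT_TABLE_COLUMNS)


def write_manifest(path: str | Path, *, seed: int | None, config: dict, counts: dict) -> None:
    """Write a small JSON run-manifest (config hash, seed, row counts)."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "counts": counts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
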