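from __future__ import annotations

import numpy as np
import pytest

from bmresponse.data_model import LesionMeasurement, PatientCourse, Scan
from bmresponse.synthetic import SyntheticConfig, generate, make_worked_example_fixtures


@pytest.fixture(scope="session")
def worked_examples():
    return make_worked_example_fixtures()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort (seed 7)."""
    return generate(SyntheticConfig(seed=7))


def random_course(rng: np.random.Generator) -> PatientCourse:
    """A random patient course stressing the adjudication rules.

    Independent of the cohort generator: diameters follow an arbitrary
    random walk with disappearance, new lesions, and occasional
    non-target progression flags, so rule edge cases (zero SLD, exact
    thresholds, late progression) are all exercised.
    """
    n_lesions = int(rng.integers(1, 7))
    n_followups = int(rng.integers(1, 7))
    base_sizes = rng.uniform(2.0, 25.0, size=n_lesions)
    days = [-int(rng.integers(0, 30))]
    d = 0
    for _ in range(n_followups):
        d += int(rng.integers(20, 70))
        days.append(d)

    scans = []
    sizes = base_sizes.copy()
    new_ids: list[tuple[str, float]] = []
    for si, day in enumerate(days):
        if si > 0:
            sizes = np.maximum(sizes * rng.uniform(0.4, 1.8, size=n_lesions), 0.0)
            sizes[sizes < 1.0] = 0.0
            if rng.random() < 0.15:
                new_ids.append((f"n{len(new_ids)}", float(rng.uniform(2.0, 12.0))))
            new_ids = [(i, s * float(rng.uniform(0.6, 1.6))) for i, s in new_ids]
        ms = [
            LesionMeasurement(
                f"l{i}",
                round(float(s), 1),
                round(float(s) * 0.8, 1),
                round(float(s) ** 3 * 0.5, 1),
            )
            for i, s in enumerate(sizes)
        ]
        if si > 0:
            ms += [
                LesionMeasurement(i, round(max(s, 0.0), 1), round(max(s, 0.0) * 0.8, 1), 1.0)
                for i, s in new_ids
                if s >= 1.0
            ]
        scans.append(
            Scan(day, tuple(ms), non_target_pd=bool(si > 0 and rng.random() < 0.05))
        )
    os_day = int(rng.integers(days[-1], days[-1] + 600))
    return PatientCourse(
        patient_id="r",
        scans=scans,
        os_day=os_day,
        os_event=bool(rng.random() < 0.6),
        last_imaging_day=days[-1],
    )
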