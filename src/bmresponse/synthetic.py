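"""Seeded synthetic cohort generator.

Emulates the statistical structure of a brain-metastasis immunotherapy
cohort so the full adjudication pipeline runs without any download:

* ~63 NSCLC patients with multiple brain metastases, many below the
  10 mm measurability cutoff (baseline longest diameters are
  log-normal with a 6 mm median);
* follow-up MRI every 4-8 weeks, 2-8 follow-ups per patient;
* heterogeneous lesion dynamics: responder / stable / progressor
  phenotypes with patient-level mixing, a configurable dissociated-
  response fraction (individual lesions deviating from the patient
  phenotype), new-lesion appearance, and a pseudoprogression fraction
  whose early growth reverses after three months;
* a *miliary* progression mode: in a configurable fraction of
  progressors the measurable (>= 10 mm) lesions stay quiescent while
  the sub-centimeter compartment grows and seeds new small lesions —
  the dissociated pattern in which total volume rises sharply while
  the target-diameter sum barely moves, so diameter criteria neither
  call early progression nor capture the change;
* lesion volumes follow a sphere rule (pi/6 * d^3) times log-normal
  noise, so diameter and volume endpoints are correlated but not
  redundant;
* overall survival is exponential with log-hazard linear in the
  *realized* volume change per 10,000 mm^3 (coefficient ``beta_volume``,
  default 1.8 ~ log 6), plus uniform administrative censoring —
  so volume change is prognostic by construction while diameter-based
  endpoints see it only through the noisy target-lesion subset.

Randomness is drawn from one stream per patient keyed by
``(seed, patient index)`` so adding patients never perturbs existing
ones; a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DAYS_PER_MONTH, LesionMeasurement, PatientCourse, Scan

__all__ = ["SyntheticConfig", "generate", "make_worked_example_fixtures"]

_PHENOTYPES = ("responder", "stable", "progressor")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Rates are per-month log-diameter drifts; diameters in mm, volumes
    in mm^3, times in days.
    """

    n_patients: int = 63
    lesions_mean: float = 6.0          # median lesion count (min 1 lesion)
    lesion_count_sigma: float = 1.0    # log-scale overdispersion of the count
    diameter_median: float = 6.0       # log-normal median of baseline longest diameter
    diameter_sigma: float = 0.65       # log-scale sd
    diameter_max: float = 18.0         # truncation: larger lesions get local therapy first
    volume_noise_sigma: float = 0.25   # log-normal per-lesion deviation from the sphere rule
    volume_scan_jitter: float = 0.08   # log-normal per-scan segmentation jitter
    scan_interval: tuple[int, int] = (28, 56)
    n_followups: tuple[int, int] = (2, 8)
    phenotype_probs: tuple[float, float, float] = (0.25, 0.40, 0.35)
    growth_rates: dict = field(
        default_factory=lambda: {
            "responder": (-0.25, 0.08),
            "stable": (0.0, 0.05),
            "progressor": (0.10, 0.05),
        }
    )
    dissociated_fraction: float = 0.15  # per-lesion chance of an independent phenotype
    small_heterogeneity_sd: float = 0.10  # patient-level drift of the sub-centimeter compartment
    compartment_independence: float = 0.5  # chance the sub-centimeter burden follows its own phenotype
    miliary_fraction: float = 0.6       # progressors whose growth is sub-centimeter only
    measurable_quiescent_rate: tuple[float, float] = (0.0, 0.05)  # >=10 mm lesions in miliary mode
    miliary_rate: tuple[float, float] = (0.30, 0.06)  # sub-centimeter compartment growth
    new_lesion_prob: float = 0.06       # per follow-up scan, doubled for progressors
    miliary_new_lesion_mean: float = 0.8  # Poisson new small lesions per scan, miliary mode
    new_lesion_median: float = 3.0      # mm (Poisson-seeded miliary lesions are small)
    pseudoprogression_fraction: float = 0.10
    pseudo_reversal_day: int = 100      # growth flips to shrinkage after this day
    baseline_os_median_months: float = 23.7
    beta_volume: float = 1.8            # log-HR per 10,000 mm^3 of realized volume change
    censor_months: tuple[float, float] = (12.0, 84.0)
    measurement_sd: float = 0.4         # mm additive measurement jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.lesions_mean <= 0:
            raise ValueError("invalid cohort size parameters")
        if self.diameter_median <= 0 or self.diameter_sigma <= 0:
            raise ValueError("invalid diameter distribution")
        if not math.isclose(sum(self.phenotype_probs), 1.0, abs_tol=1e-9):
            raise ValueError("phenotype probabilities must sum to 1")
        if self.scan_interval[0] > self.scan_interval[1] or self.scan_interval[0] < 1:
            raise ValueError("invalid scan interval")


def _volume_from_diameter(
    d: float, lesion_factor: float, rng: np.random.Generator, jitter: float
) -> float:
    """Sphere-rule volume with a lesion-systematic deviation factor.

    The deviation from the sphere rule (shape, enhancement pattern) is a
    property of the lesion, so it is drawn once per lesion; only a small
    segmentation jitter is redrawn per scan.
    """
    if d <= 0:
        return 0.0
    return math.pi / 6.0 * d**3 * lesion_factor * float(rng.lognormal(0.0, jitter))


def _simulate_patient(
    pid: str, idx: int, cfg: SyntheticConfig
) -> tuple[PatientCourse, dict]:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(idx,)))

    phenotype = _PHENOTYPES[rng.choice(3, p=cfg.phenotype_probs)]
    pseudo = phenotype == "progressor" and rng.random() < (
        cfg.pseudoprogression_fraction / cfg.phenotype_probs[2]
    )
    miliary = (
        phenotype == "progressor"
        and not pseudo
        and rng.random() < cfg.miliary_fraction
    )

    # overdispersed (Poisson-log-normal) lesion count: most patients carry a
    # handful of metastases, a tail carries dozens of small foci
    lam = cfg.lesions_mean * float(rng.lognormal(0.0, cfg.lesion_count_sigma))
    n_lesions = max(1, int(rng.poisson(lam)))
    # dissociated response at the patient level: the sub-centimeter
    # compartment follows the measurable-target phenotype only partially,
    # plus a shared per-patient rate drift — total burden and target
    # diameters can take different courses
    if rng.random() < cfg.compartment_independence:
        compartment_pheno = _PHENOTYPES[rng.choice(3, p=cfg.phenotype_probs)]
    else:
        compartment_pheno = phenotype
    small_shift = float(rng.normal(0.0, cfg.small_heterogeneity_sd))
    lesion_pheno = []
    lesion_d0 = []
    lesion_vf = []
    rates = []
    for _ in range(n_lesions):
        d0 = float(rng.lognormal(math.log(cfg.diameter_median), cfg.diameter_sigma))
        while d0 > cfg.diameter_max:  # truncated: large BMs are locally treated upfront
            d0 = float(rng.lognormal(math.log(cfg.diameter_median), cfg.diameter_sigma))
        lesion_d0.append(d0)
        lesion_vf.append(float(rng.lognormal(0.0, cfg.volume_noise_sigma)))
        base_pheno = phenotype if d0 >= 10.0 else compartment_pheno
        if rng.random() < cfg.dissociated_fraction:
            pheno = _PHENOTYPES[rng.choice(3, p=cfg.phenotype_probs)]
        else:
            pheno = base_pheno
        # miliary progression spares the measurable lesions: only the
        # sub-centimeter compartment (and new lesions) grows
        if miliary and d0 >= 10.0:
            lesion_pheno.append("stable")
            rates.append(float(rng.normal(*cfg.measurable_quiescent_rate)))
        elif miliary:
            lesion_pheno.append(pheno)
            rates.append(float(rng.normal(*cfg.miliary_rate)))
        else:
            lesion_pheno.append(pheno)
            rate = float(rng.normal(*cfg.growth_rates[pheno]))
            if d0 < 10.0:
                rate += small_shift
            rates.append(rate)

    baseline_day = -int(rng.integers(0, 31))
    n_fu = int(rng.integers(cfg.n_followups[0], cfg.n_followups[1] + 1))
    days = [baseline_day]
    day = 0
    for _ in range(n_fu):
        day += int(rng.integers(cfg.scan_interval[0], cfg.scan_interval[1] + 1))
        days.append(day)

    def diameter_at(d0: float, rate: float, t: float, is_pseudo: bool) -> float:
        months = max(t, 0.0) / DAYS_PER_MONTH
        if is_pseudo and rate > 0:
            if t <= cfg.pseudo_reversal_day:
                log_d = math.log(d0) + rate * months
            else:
                # inflammatory enhancement resolved between scans: back to
                # baseline size, then slow regression
                peak = cfg.pseudo_reversal_day / DAYS_PER_MONTH
                log_d = math.log(d0) - 0.08 * (months - peak)
        else:
            log_d = math.log(d0) + rate * months
        return math.exp(log_d)

    scans = []
    new_lesion_count = 0
    new_lesions: list[tuple[str, int, float, float, float]] = []  # id, appear_day, d0, rate, vol factor
    for si, d in enumerate(days):
        measurements = []
        for li in range(n_lesions):
            size = diameter_at(lesion_d0[li], rates[li], d, pseudo)
            size += float(rng.normal(0.0, cfg.measurement_sd))
            if size < 1.0:
                size = 0.0
            smallest = size * float(rng.uniform(0.65, 0.98)) if size > 0 else 0.0
            measurements.append(
                LesionMeasurement(
                    lesion_id=f"L{li:02d}",
                    longest_diameter=round(size, 1),
                    smallest_diameter=round(smallest, 1),
                    volume=round(
                        _volume_from_diameter(
                            size, lesion_vf[li], rng, cfg.volume_scan_jitter
                        ),
                        1,
                    ),
                )
            )
        if si > 0:
            if miliary:
                n_new = int(rng.poisson(cfg.miliary_new_lesion_mean))
            else:
                p_new = cfg.new_lesion_prob * (2.0 if phenotype == "progressor" else 1.0)
                n_new = int(rng.random() < p_new)
            for _ in range(n_new):
                new_lesion_count += 1
                nd0 = float(rng.lognormal(math.log(cfg.new_lesion_median), 0.4))
                growth = cfg.miliary_rate if miliary else cfg.growth_rates[phenotype]
                nrate = float(rng.normal(*growth))
                nvf = float(rng.lognormal(0.0, cfg.volume_noise_sigma))
                new_lesions.append((f"N{new_lesion_count:02d}", d, nd0, nrate, nvf))
        for nid, appear_day, nd0, nrate, nvf in new_lesions:
            if d >= appear_day:
                size = diameter_at(nd0, nrate, d - appear_day, False)
                if size < 1.0:
                    size = 0.0
                smallest = size * float(rng.uniform(0.65, 0.98)) if size > 0 else 0.0
                measurements.append(
                    LesionMeasurement(
                        lesion_id=nid,
                        longest_diameter=round(size, 1),
                        smallest_diameter=round(smallest, 1),
                        volume=round(
                            _volume_from_diameter(size, nvf, rng, cfg.volume_scan_jitter),
                            1,
                        ),
                    )
                )
        scans.append(Scan(scan_day=d, measurements=tuple(measurements)))

    # realized volume change: smallest follow-up total volume minus baseline
    def total(s: Scan) -> float:
        return sum(m.volume or 0.0 for m in s.measurements)

    baseline_volume = total(scans[0])
    bor_volume = min(total(s) for s in scans[1:])
    delta_volume = bor_volume - baseline_volume

    lp = cfg.beta_volume * delta_volume / 10_000.0
    lam0 = math.log(2.0) / (cfg.baseline_os_median_months * DAYS_PER_MONTH)
    death_day = float(rng.exponential(1.0 / (lam0 * math.exp(lp))))
    censor_day = float(
        rng.uniform(cfg.censor_months[0], cfg.censor_months[1]) * DAYS_PER_MONTH
    )
    min_os = scans[1].scan_day + 1  # survival long enough for one follow-up
    death_day = max(death_day, min_os)
    censor_day = max(censor_day, min_os)
    if death_day <= censor_day:
        os_day, os_event = int(round(death_day)), True
    else:
        os_day, os_event = int(round(censor_day)), False
    scans = [s for s in scans if s.scan_day <= os_day]

    course = PatientCourse(
        patient_id=pid,
        scans=scans,
        os_day=os_day,
        os_event=os_event,
        last_imaging_day=scans[-1].scan_day,
    )
    truth = {
        "patient_id": pid,
        "phenotype": phenotype,
        "pseudoprogression": pseudo,
        "miliary": miliary,
        "n_lesions": n_lesions,
        "true_delta_volume": delta_volume,
        "linear_predictor": lp,
        "death_day": death_day,
        "censored": not os_event,
    }
    return course, truth


def generate(config: SyntheticConfig | None = None) -> tuple[list[PatientCourse], pd.DataFrame]:
    """Generate a synthetic cohort plus its ground-truth table.

    Returns ``(courses, truth)`` where ``truth`` has one row per
    patient with the latent phenotype, the realized volume change the
    survival hazard was conditioned on, and the censoring status.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    courses, truths = [], []
    for i in range(cfg.n_patients):
        course, truth = _simulate_patient(f"P{i:03d}", i, cfg)
        courses.append(course)
        truths.append(truth)
    return courses, pd.DataFrame(truths)


def make_worked_example_fixtures() -> dict[str, PatientCourse]:
    """Hand-coded mini-patients reproducing published worked examples.

    ``new_lesion_absorption``: a 13 mm target shrinking to 5 mm with a new 6 mm lesion
    at week 8 — progression by mRECIST (new lesion) but stable disease
    by RANO-BM (SLD 11 mm, -15.4% from baseline).

    ``pseudoprogression_reversal``: targets of 13 and 8 mm growing at week 20 (progression
    by mRECIST and RANO-BM) then regressing at week 40 — within the
    6-month window, so iRANO-BM revokes the call: stable disease.

    ``miliary_volume_growth``: total volume 1459.1 mm^3 over 35 lesions growing to
    2643.4 mm^3 (+81.2%) while the 5 and 9 mm target diameters barely
    change.  ``focal_volume_growth``: 778.5 mm^3 growing to 1329.4 mm^3 (+70.8%)
    with a single 12 mm target among sub-5 mm lesions.

    The lesion-level splits other than the printed target diameters
    and totals are synthetic (only the totals were published).
    """
    fixtures: dict[str, PatientCourse] = {}

    fixtures["new_lesion_absorption"] = PatientCourse(
        patient_id="new_lesion_absorption",
        scans=[
            Scan(0, (LesionMeasurement("T1", 13.0, 11.0, 600.0),)),
            Scan(
                56,
                (
                    LesionMeasurement("T1", 5.0, 4.0, 60.0),
                    LesionMeasurement("NEW1", 6.0, 5.0, 90.0),
                ),
            ),
        ],
        os_day=600,
        os_event=False,
        last_imaging_day=56,
    )

    fixtures["pseudoprogression_reversal"] = PatientCourse(
        patient_id="pseudoprogression_reversal",
        scans=[
            Scan(
                0,
                (
                    LesionMeasurement("T1", 13.0, 11.0, 700.0),
                    LesionMeasurement("T2", 8.0, 7.0, 200.0),
                ),
            ),
            Scan(
                140,  # week 20: unequivocal growth of both targets
                (
                    LesionMeasurement("T1", 19.0, 16.0, 1900.0),
                    LesionMeasurement("T2", 11.0, 9.0, 500.0),
                ),
            ),
            Scan(
                280,  # week 40: regression below the progression bar
                (
                    LesionMeasurement("T1", 12.0, 10.0, 550.0),
                    LesionMeasurement("T2", 7.0, 6.0, 150.0),
                ),
            ),
        ],
        os_day=700,
        os_event=False,
        last_imaging_day=280,
    )

    def _volume_scan(day: int, targets: list[tuple[str, float, float]],
                     n_small: int, total: float) -> Scan:
        """Scan whose lesion volumes sum exactly to ``total`` mm^3."""
        ms = []
        target_vol = 0.0
        for lid, longest, vol in targets:
            ms.append(LesionMeasurement(lid, longest, longest * 0.85, vol))
            target_vol += vol
        rest = total - target_vol
        per = round(rest / n_small, 6)
        for i in range(n_small - 1):
            ms.append(LesionMeasurement(f"S{i:02d}", 3.0, 2.0, per))
            rest -= per
        ms.append(LesionMeasurement(f"S{n_small - 1:02d}", 3.0, 2.0, round(rest, 6)))
        return Scan(day, tuple(ms))

    fixtures["miliary_volume_growth"] = PatientCourse(
        patient_id="miliary_volume_growth",
        scans=[
            _volume_scan(0, [("T1", 9.0, 300.0), ("T2", 5.0, 65.0)], 33, 1459.1),
            _volume_scan(84, [("T1", 9.0, 310.0), ("T2", 5.0, 66.0)], 58, 2643.4),
        ],
        os_day=int(round(10 * DAYS_PER_MONTH)),
        os_event=True,
        last_imaging_day=84,
    )
    fixtures["focal_volume_growth"] = PatientCourse(
        patient_id="focal_volume_growth",
        scans=[
            _volume_scan(0, [("T1", 12.0, 450.0)], 15, 778.5),
            _volume_scan(84, [("T1", 14.0, 600.0)], 20, 1329.4),
        ],
        os_day=int(round(14 * DAYS_PER_MONTH)),
        os_event=True,
        last_imaging_day=84,
    )
    return fixtures
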