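# bmresponse

Response-criteria adjudication and volumetric surrogate endpoints for
brain metastases under immune-checkpoint-inhibitor (ICI) therapy.

## The problem

Assessing how brain metastases (BM) respond to immunotherapy on serial
MRI is hard: many lesions are below the 10 mm measurability cutoff of
the standard criteria, patients often carry dozens of small lesions,
some lesions shrink while others grow (dissociated response), and
apparent early growth can be pseudoprogression that later resolves.
Different published criteria handle these situations differently, so
the same patient can be a responder under one rule set and a
progressor under another — and a trial's progression-free survival
(PFS) depends on which rule set was used.

`bmresponse` implements, for longitudinal per-lesion measurement
tables:

* **Criteria engines** for three diameter-based rule sets:
  * **mRECIST** — targets measurable at ≥ 5 mm in the *smallest*
    diameter (up to five); any new lesion is immediate progression;
  * **RANO-BM** — targets measurable at ≥ 10 mm in the longest
    diameter; a new lesion is *not* automatic progression: its diameter
    is added to the sum of longest diameters (SLD) and progression is
    judged on the combined sum;
  * **iRANO-BM** — RANO-BM plus a pseudoprogression guard: progression
    first seen within 6 months of ICI start is preliminary and must
    still hold on a scan ≥ 3 months later (against the same nadir), or
    it is revoked.

  Common thresholds: CR when all target disease disappears; PR at a
  ≥ 30 % SLD decrease from baseline; PD at a ≥ 20 % SLD increase over
  the nadir that is also an absolute increase ≥ 5 mm; SD otherwise;
  precedence PD > CR > PR > SD. The nadir is the smallest SLD on study,
  baseline included.

* **Quantitative endpoints**, subtraction-based (not ratios, since
  sub-measurable baseline lesions give zero denominators):

  ΔSLD = SLD(BOR) − SLD(baseline) (mm, per criteria system), and
  ΔV = V(BOR) − V(baseline) (mm³) where V is the total volume of *all*
  lesions and the volumetric best-overall-response (BOR) date is the
  follow-up scan with the smallest total volume. Patients progressing
  at the very first follow-up stop ICI after one course and are
  excluded from overall-survival (OS) modeling.

* **Comparison statistics**: best-response rate tables (ORR = CR+PR,
  DCR = CR+PR+SD), quadratically weighted kappa on the ordered
  CR < PR < SD < PD scale (κ = 1 − Σv·O / Σv·E with disagreement
  weights v_ij = (i−j)²/(k−1)²), the exact McNemar test on paired PD
  assignments, and the power of the paired z-test.

* **Survival analyses**: Kaplan–Meier medians with CIs, log-rank
  (progressors vs non-progressors), pairwise Wilcoxon signed-rank on
  PFS with Bonferroni correction (three comparisons, p < 0.017),
  Spearman OS–PFS correlation, and single-covariate Cox
  proportional-hazards regression of OS on ΔSLD (per mm) and ΔV
  (per 10 000 mm³), with Efron tie handling.

* A **seeded synthetic cohort generator** that emulates the data
  structure such analyses assume — 63 patients, overdispersed lesion
  counts with many sub-centimeter lesions, 4–8-week scans,
  responder/stable/progressor dynamics with dissociated and miliary
  (sub-centimeter-only) progression, pseudoprogression, and an OS
  hazard log-linear in realized ΔV — so the whole pipeline runs and is
  testable without any patient data.

## Worked example

```bash
bmresponse simulate --seed 7 --out-dir cohort   # lesions.csv, patients.csv, truth.csv
bmresponse assess cohort --out table.csv        # per patient × criteria endpoints
bmresponse compare cohort
bmresponse survive cohort
```

`compare` prints (seed 7, abridged):

```
Weighted kappa (quadratic weights):
  mRECIST vs RANO-BM: 0.446 (moderate)
  mRECIST vs iRANO-BM: 0.429 (moderate)
  RANO-BM vs iRANO-BM: 0.937 (almost perfect)

Exact McNemar on PD assignment:
  mRECIST vs RANO-BM: p = 0.01562, discordant = (7, 0)
```

mRECIST calls progression in seven patients that RANO-BM does not
(new lesions are immediate PD only under mRECIST), a significant
difference in PD assignment; the two RANO variants agree almost
perfectly here. `survive` prints:

```
median PFS by criteria (months):
  mRECIST: 4.63
  RANO-BM: 5.59
  iRANO-BM: 7.79

Cox OS regressions (single covariate):
  delta_sld_mRECIST: HR 1.07 per mm (95% CI 1.02-1.13, p = 0.00744)
  delta_sld_RANO-BM: HR 1.07 per mm (95% CI 1-1.14, p = 0.0435)
  delta_sld_iRANO-BM: HR 1.06 per mm (95% CI 0.999-1.13, p = 0.052)
  delta_volume: HR 17.4 per 10,000 mm^3 (95% CI 3.64-82.7, p = 0.000342)
```

PFS lengthens from mRECIST to RANO-BM to iRANO-BM — each step makes
progression harder to call (new-lesion absorption, then
pseudoprogression confirmation). Each mm of diameter growth at BOR
multiplies the death hazard by ~1.07; the volume endpoint, which sees
every lesion rather than up to five targets, carries a much stronger
association with OS per 10 000 mm³.

The same API is available as a library:

```python
from bmresponse import assess_patient, RANO_BM, IRANO_BM, make_worked_example_fixtures

course = make_worked_example_fixtures()["pseudoprogression_reversal"]       # growth at wk 20, regression at wk 40
assess_patient(course, RANO_BM).bor_category  # <Category.PD> at day 140
assess_patient(course, IRANO_BM).bor_category # <Category.SD> — early PD revoked
```

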