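# Methods

## Data model and time conventions

The atomic observation is one lesion's measurement on one MRI scan:
longest diameter (mm), optional smallest diameter (mm), optional
segmented volume (mm³). Scan days are integer days from ICI start;
baseline is the latest scan on or before day 0 (and within 60 days
before it — baseline imaging is acquired within two months of therapy
start). OS and PFS run from the baseline imaging date; months are
days / 30.4375, a fixed divisor chosen so reported month values are
exactly reproducible. A diameter of 0 encodes complete disappearance
of a previously seen lesion. Validation is total: malformed rows raise
typed errors naming the offending record; nothing is silently coerced.
Missing volumes are permitted (2D-only datasets remain assessable by
diameters); volumetric endpoints skip and report such patients.
One measurement table is shared by all criteria systems — the engines
differ in eligibility and policy, not in the measurements themselves.

## Adjudication engines

Target selection takes up to five baseline lesions whose eligibility
dimension meets the measurability cutoff — smallest diameter ≥ 5 mm
for mRECIST, longest diameter ≥ 10 mm for RANO-BM/iRANO-BM (3 mm
slices, so the thin-slice 5 mm concession does not apply) — largest
first by longest diameter, ties broken by lexicographic lesion id. The
SLD always sums longest diameters. A patient with no eligible baseline
lesion is unassessable under that system and is reported and excluded
from that system's tables; a sub-cutoff lesion is never promoted to
target even where a human reader might improvise one.

Per-timepoint classification: PD if (a) a new lesion has appeared and
the policy is immediate-PD (mRECIST), or (b) the reader-supplied
non-target-progression flag is set (an input, not a computed rule,
because no quantitative rule exists for "unequivocal" non-target
progression), or (c) SLD ≥ 1.2 × nadir with an absolute increase
≥ 5 mm; otherwise CR if SLD = 0 and no new lesion has appeared, PR if
SLD ≤ 0.7 × baseline, else SD. Under the RANO-BM/iRANO-BM policy a new
lesion's diameter is *added to the SLD* from its first appearance
onward (so new-lesion burden can eventually trip the 20 %/5 mm rule
instead of triggering progression by fiat). The nadir is the smallest
SLD up to and including the current scan, baseline included.

The pseudoprogression guard (iRANO-BM) is a state machine over the
base-rule calls: a PD first occurring within 182 days of ICI start
becomes preliminary; the first scan at least 91 days later decides it.
Still meeting PD criteria against the *same* nadir (no nadir reset in
the window) confirms, with the progression date backdated to the
preliminary scan; otherwise the call is revoked, affected scans are
re-classified on size criteria alone, and scanning resumes — a later
fresh PD starts a new cycle (immediate if past the window). Boundaries
are inclusive ("within 6 months" means ≤ 182 days). A preliminary call
with no qualifying later scan stays unconfirmed: the patient is
censored for PFS at the last imaging date (confirmation is required
for progression, so the conservative reading is censoring, logged per
patient). For best-overall-response ranking an unconfirmed preliminary
call counts as stable disease (it is neither a response nor confirmed
progression).

BOR is the best category (CR > PR > SD) among scans strictly before
the progression date, its date the earliest scan attaining it; if the
first follow-up already shows progression, BOR is PD at that scan.
PFS events at the earlier of progression and death; otherwise the
patient is censored at the last imaging date.

## Endpoints

ΔSLD = SLD(BOR) − SLD(baseline) per criteria system; ΔV = V(BOR) −
V(baseline) with V the total volume of all lesions and the volumetric
BOR the follow-up scan minimizing V (earliest on ties). Baseline is
excluded from the minimization — otherwise the change could never be
positive, and the worked examples have positive changes. Subtraction
rather than a ratio is primary (zero denominators for sub-measurable
disease); percent change is auxiliary. The diameter endpoint mirrors
the volumetric convention (BOR among follow-ups only). Growth is
positive: endpoints are defined as follow-up minus baseline
throughout. Patients whose first follow-up shows progression under the
reference criteria (RANO-BM, configurable) are excluded from OS
modeling: they received a single ICI course and their subsequent
treatment confounds the endpoint.

## Statistics

* Weighted kappa uses quadratic (Fleiss-Cohen) weights on the ordered
  CR < PR < SD < PD scale: κ = 1 − Σ v_ij O_ij / Σ v_ij E_ij with
  disagreement weights v_ij = (i−j)²/(k−1)² and E from marginal
  products. The output records the weight convention explicitly
  (agreement w = 1 − v) to avoid the classic ambiguity. Bands: poor
  ≤ 0.20 < mild ≤ 0.40 < moderate ≤ 0.60 < substantial ≤ 0.80 <
  almost perfect.
* McNemar on PD assignment is the exact binomial test on discordant
  pairs: p = min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½). The exact
  (not chi-square) form is used; the discordant counts it is checked
  against in tests — (6,0), (10,0), (4,0) — are internal-consistency
  reconstructions from the nesting structure of the three criteria,
  not published tables.
* Paired z-test power: Φ(√n·|δ|/σ_d − z_{1−α/2}) plus the opposite
  tail.
* Wilcoxon signed-rank on paired PFS drops zero differences, uses the
  exact null when ≤ 25 untied nonzero pairs and the
  continuity-corrected normal approximation otherwise; three pairwise
  comparisons are Bonferroni-corrected (significance at p < 0.017).
* Kaplan–Meier and Cox go through lifelines: product-limit estimate
  with Brookmeyer–Crowley-style median CIs; Cox partial likelihood
  with Efron tie handling, Wald CIs and p-values. Covariates are
  rescaled so hazard ratios are per 1 mm (ΔSLD) or per 10 000 mm³
  (ΔV). Spearman correlation uses mid-ranks and a Fisher-transform CI.
* The quadratic-kappa implementation is cross-checked in tests against
  statsmodels' independent implementation; the two routes are kept
  separate.

## Synthetic cohort

The generator emulates the data structure of an ICI brain-metastasis
cohort (63 patients by default) so every stage runs with no download.
It is an emulation of *statistical structure*, not of images or
anatomy.

* **Lesion counts** are overdispersed (Poisson mixed over a log-normal
  rate, median 6, minimum 1): most patients carry a handful of
  metastases, a tail carries dozens of small foci (published
  volumetric counts for such cohorts reach 35–60 lesions per patient).
* **Baseline diameters** are log-normal (median 6 mm, σ = 0.65)
  truncated at 18 mm — the majority of lesions are below the 10 mm
  cutoff, and large symptomatic metastases are treated locally before
  ICI monotherapy (two-thirds of such cohorts have prior local
  radiotherapy), so very large untreated lesions do not occur.
* **Volumes** follow the sphere rule π/6·d³ times a lesion-systematic
  log-normal factor (σ = 0.25) plus a small per-scan segmentation
  jitter (σ = 0.08). The deviation from sphericity is a property of
  the lesion, so it is drawn once per lesion; making it independent
  per scan would let the minimum-over-scans endpoint harvest noise
  minima.
* **Dynamics**: patients are responders / stable / progressors
  (0.25/0.40/0.35) with per-month log-diameter drifts of −0.25, 0.00
  and +0.10 (SDs 0.08/0.05/0.05). The slow progressor drift places
  diameter-based median PFS in the 4–10-month range at 4–8-week scan
  intervals rather than forcing progression at the first follow-up.
  Three dissociation mechanisms reflect how total burden and target
  diameters can diverge: a per-lesion chance (0.15) of an independent
  phenotype; a patient-level *compartment phenotype* for sub-10 mm
  lesions that follows the target phenotype with probability only 0.3
  (heterogeneity of sub-centimeter responses); and a *miliary* mode in
  60 % of progressors, in which measurable lesions stay quiescent
  while the small compartment grows briskly (+0.30/month) and seeds
  new ~3 mm lesions (Poisson 0.8 per scan) — total volume rises
  sharply while the target SLD barely moves.
* **Pseudoprogression** (10 % of patients): growth that resolves to
  baseline size after day 100 and regresses slowly thereafter. At
  4–8-week sampling the between-scan resolution step is invisible;
  scans before ~3 months show growth, scans after show resolution, so
  confirmation-window logic always sees the reversal.
* **Survival**: exponential with baseline median 23.7 months and
  log-hazard β·ΔV/10⁴ with β = 1.8 (≈ log of the hazard ratio a
  volumetric Cox analysis of such a cohort reports), where ΔV is the
  *realized* minimum-follow-up volume change — so the volumetric
  endpoint is prognostic by construction and the diameter endpoints
  see the signal only through the (truncated, dissociated) target
  subset. Administrative censoring is uniform over 12–84 months,
  emulating a multi-year accrual window with analysis at its end;
  about two-thirds of patients die on study. Scans after death are
  dropped (death must postdate the first follow-up).
* **Reproducibility**: one random stream per patient keyed by
  (seed, patient index) — adding patients never perturbs existing
  ones; a fixed seed yields byte-identical files. A ground-truth table
  (phenotype, realized ΔV, linear predictor, censoring) accompanies
  every cohort for recovery tests.

What passing tests on this cohort do **not** show: performance on real
MRI measurements (reader variability, non-log-linear growth,
segmentation bias correlated with size), non-exponential survival, or
hazard links other than log-linear-in-ΔV. The generator exists to
exercise the pipeline's logic and to verify estimator behavior under a
known truth, not to certify clinical operating characteristics.

## Numerical and design choices

* Thresholds (−30 %, +20 %, 5 mm) and the nadir definition are the
  published RECIST 1.1 / RANO-BM values; all are config fields, not
  hard-coded, and three presets (mRECIST, RANO-BM, iRANO-BM) ship with
  the package, loadable/overridable from plain-text key=value files.
* Ties in target selection: lexicographic lesion id, making target
  sets deterministic.
* A target absent from a follow-up scan contributes 0 mm to the SLD.
* Degenerate baselines: SLD 0 at baseline with later growth is flagged
  as new-lesion-driven; percent volume change is undefined (reported
  absent) when baseline volume is 0.
* Kappa is undefined (reported absent, with note) when fewer than two
  distinct categories occur; a degenerate zero expected-disagreement
  denominator returns κ = 1.
* Cox refuses constant covariates (non-identifiable) and datasets
  without events; the log-rank helper refuses an empty group, naming
  the criteria system.
* The month divisor (30.4375 = 365.25/12), the 182/91-day windows, and
  inclusive boundaries are fixed constants of the implementation.

## Known limitations

Corticosteroid dosing and clinical status (components of the full
published RANO criteria) are out of scope, as is any image processing:
diameters and volumes are inputs. Non-target progression is an input
flag, not a computed rule. Confidence intervals for kappa are not
provided. The Cox models are single-covariate by design; no
multivariable adjustment is attempted.
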