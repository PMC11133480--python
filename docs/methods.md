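# Methods

`cxsurv` re-implements, as a tested library, the computational chain used to
analyse an early-phase radiotherapy + CXCL12-inhibitor glioblastoma cohort:
single-cell phenotype gating of multiplexed immunofluorescence (mIF) tables,
a composite CXCL12-positivity biomarker (EG12), modified-RANO (mRANO)
radiographic response assessment with PFS/OS event derivation, and the
surrounding trial statistics. A synthetic cohort generator provides inputs
with the statistical structure the chain assumes, so every stage is testable
without patient data.

## Phenotype gating

Input is one row per segmented cell: nuclear area (µm²) and, per marker, a
nucleus(/cytoplasm) "% completeness" fraction in [0, 1] as exported by
image-analysis software. Cells are analysable when DAPI completeness ≥ 0.15
and nuclear area lies in [12, 1000] µm² (both bounds inclusive). Marker
positivity thresholds (completeness fractions): CXCL12 0.35, CD68 0.20,
CD31 0.30, Ki-67 0.30, α-SMA 0.35, GFAP 0.30. Comparisons are inclusive
(≥); "threshold for positivity" does not state strictness and inclusive is
the common image-analysis convention.

Gates: endothelial = CD31⁺; pericyte = α-SMA⁺ CD31⁻; macrophage/microglia =
CD68⁺; glioma = GFAP⁺ CD68⁻ CD31⁻ α-SMA⁻ (all DAPI⁺ via the filter). As
written, the endothelial and macrophage gates are not mutually exclusive; a
CD31⁺CD68⁺ cell increments both counts and the overlap is reported
separately. E12/P12/M12/G12 are the CXCL12⁺ percentages within each gate;
the total CXCL12⁺ percentage uses all filtered cells as denominator. A
phenotype with zero members reports a *missing* frequency, never 0, so the
composite score cannot absorb spurious zeros.

## EG12 composite biomarker

With E12 and G12 in percent,

    EG12_i = ((E12_i − med(E12)) + (G12_i − med(G12))) / 2,

medians taken within each cohort (treatment arm) separately; the score is
signed. Dichotomization is at the cohort median: strictly above → high, at
or below → low, so an even number of distinct scores splits into equal
halves and ties deterministically go to "low".

Spearman's rank correlation (tie-corrected) relates biomarkers to PFS using
only patients with an *observed* PFS event — a cohort of ten with one
censored patient contributes n = 9. The p-value uses the t approximation
with n − 2 df (the common package default); a full-permutation exact p is
available for n < 9 and agrees with the approximation to within a few
hundredths in tests.

## mRANO response engine

Target lesions (TL) are baseline lesions measurable in two perpendicular
diameters, both ≥ 10.0 mm (inclusive; only the failing condition "<10 mm"
is stated, so the boundary was fixed inclusively). SPD = Σ d₁·d₂ over TLs.
Timepoint classification: PD at ≥ +25% vs the nadir (minimum of baseline
and prior scans — the standard mRANO reference, since the text states the
thresholds but not the reference for each), or a new measurable lesion; PR
at ≤ −50% vs baseline; CR when all TLs and NTLs are absent; SD otherwise.
New non-measurable lesions and NTL changes affect only an otherwise
complete response. Patients without a measurable baseline lesion are
followed on NTLs (SD unless resolution or a new measurable lesion).

Preliminary PR/CR/PD require confirmation by the next scan at least 42 days
later (q8w schedule with real-world jitter). A histopathologically
confirmed pseudo-progression voids the PD call at that scan. The PFS event
day is the earliest of: the *preliminary* scan date of a sequentially
confirmed PD; a scan with simultaneous clinical progression; death before
progression. An unconfirmed preliminary PD not followed by SD/PR/CR still
counts when treatment stopped for clinical progression, no further
assessments occurred, or the patient died. Otherwise PFS is censored at new
anticancer therapy, else at the last assessment. OS is death from first
treatment day, censored at last contact. Event days are always recorded
scan/event days, never interpolated, and PFS ≤ OS is enforced.

The engine is checked exhaustively against a brute-force transcription of
the rule list (independent code path) over ~4,000 combinations of SPD
courses and clinical-event orderings.

## Survival and trial statistics

Kaplan–Meier estimation, the log-rank test and Cox regression are delegated
to `lifelines` (Efron tie handling; Wald 95% CI); the median is the first
time S(t) ≤ 0.5 and the 6-month PFS rate is read at day 183 (365.25/2,
rounded). Monotone likelihood at n = 10 is surfaced as a warning on the
result, not replaced by another estimator, since plain HR/CI is what such
trials report. Mann–Whitney U uses exact tie-aware enumeration of all
C(n+m, n) assignments for n+m ≤ 12 and the tie-corrected normal
approximation otherwise. AE tabulation counts CTCAE grades 1–5 and
attribution categories (none / GBM / RT / drug and their combinations);
percentages are recomputed from counts at print time, one decimal, half
away from zero. Note 4/84 = 4.8% at this rounding. PK series are summarised
by the first day within 10% of the final-week mean, the plateau mean, and
flags for the 1.5 µM pharmacologic threshold and drug-over-target excess.
The modified 3+3 rules: 0/3 DLT → escalate, 1/3 → expand to six, ≥ 2 among
3–6 → stop (MTD one level below); the 600 mg/week top dose, if tolerated,
is the RP2D.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions.

* **Cell tables.** Types are drawn from a mixture (glioma 0.48, Mϕ/microglia
  0.24, other 0.20, endothelial 0.04, pericyte 0.04 — endothelial cells
  roughly twelve-fold rarer than glioma cells, as in such tissue). Marker
  completeness is Beta(8, 2) for a cell's own markers and Beta(1, 19)
  otherwise — Beta keeps fractions in [0, 1]; these shapes give ≥ 95%
  per-class gate recall with < 2% per-marker leak. CXCL12 positivity is
  Bernoulli with patient- and type-specific rates whose cohort means are
  ordered E 0.55 > P 0.35 > M 0.20 > G 0.10. Patient rates are Beta around
  those means with concentration κ = 150; κ trades patient heterogeneity
  against ordering stability, and this value keeps the cohort-level
  ordering E12 > P12 > M12 > G12 recoverable in ≥ 95% of seeds at 10,000
  cells/sample (verified on 120 seeds) while still providing the spread the
  biomarker analyses need. Nuclear areas are log-normal (median 60 µm²,
  σ = 0.8), so a realistic few percent fall outside the filter window.
* **Survival.** The latent EG12 z-score is built from the patient's own
  endothelial and glioma rate deviations (standardized, averaged, rescaled
  to unit variance). PFS is exponential with log-hazard log(h₀) +
  β·z in the APTAMER arm and log(h₀) in SOC — the simplest
  proportional-hazards-consistent choice, making Cox recovery well-posed.
  Defaults h₀ = ln 2 / 174 d⁻¹ and β = −1.5. OS = PFS + an exponential
  post-progression time (median 215 d), so PFS ≤ OS by construction. About
  one patient in ten is censored for PFS at a new-therapy start.
* **Lesions.** Piecewise-exponential diameter courses: optional shrinkage
  from day 0, regrowth from one scan interval before the true progression
  day, multiplicative log-normal noise (σ = 0.05 per measurement;
  measurement error is otherwise unspecified). Diameters below 1 mm are
  recorded absent. About 10% of patients carry only sub-measurable disease
  (NTL-only follow-up); a similar fraction get a transient one-visit bump
  flagged as pseudo-progression.
* **PK.** C(t) = C_ss·(1 − e^{−kt}) with k = ln 2 / 1.75 d⁻¹ (within 10% of
  plateau after ~1 week) and C_ss dose-proportional at 2.0 µM per 200
  mg/week — above the 1.5 µM threshold at the lowest dose; the CXCL12
  plateau (0.5 µM) stays below the drug level. Only qualitative claims
  anchor these plateaus, so they are calibrated to "above threshold at 200
  mg" and "steady state in about a week", not to numeric curves.
* **Seeding.** All randomness derives from `numpy` `SeedSequence(seed,
  spawn_key=(stream, patient))`, with patient ids hashed by CRC32, so
  cohorts are byte-reproducible across processes and adding patients never
  perturbs existing ones.

What the generator does **not** emulate: spatial structure and segmentation
artefacts in mIF (marker intensities are independent given the type; no
doublets, no intensity drift across imaging cycles), non-proportional or
time-varying treatment effects, informative censoring, correlated lesion
courses within a patient beyond the shared progression day, and PK
inter-patient variability beyond measurement noise. Passing tests therefore
demonstrate the *analysis chain* is correct and calibrated under a clean
generative model, not that it is robust to real-world imaging or imaging-
schedule pathology.

## Problem sizes

Default test and acceptance runs use cohorts of 10–50 patients, 400–10,000
cells per sample, 1,000 replicates for null calibration and 200 for effect
recovery — sizes chosen so the whole suite runs in a few minutes on one
core while leaving Monte-Carlo bands (± 2 percentage points on a 5% rate at
1,000 replicates) tight enough to detect real miscalibration.

## Known limitations

* Cox and log-rank at n = 10 are fragile; complete separation yields
  monotone likelihoods, reported with warnings and an optional light ridge.
* The per-patient recomputation entry point
  (`biomarker.recompute_from_patient_table`) expects the published
  per-patient value table, which ships with the original article, not with
  this package; it is exercised on a synthetic stand-in in the tests.
* The mRANO engine consumes scalar per-visit measurements; volumetric
  criteria, DICOM handling and perfusion-map computation are out of scope.
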