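# Methods

This note documents the models, statistical conventions and design choices
behind `ctcdx`, and what the synthetic generators do and do not emulate.

## Cell classification rule

A segmented nucleus (DAPI-positive by construction) is classified against
the arithmetic means of the per-cell total fluorescence intensities taken
over **all** segmented cells on its slide:

| call | conditions |
|---|---|
| MSLN_POS_CTC | area ≥ 47 µm² AND ckmix ≥ mean(ckmix) AND msln ≥ mean(msln) AND cd45 < mean(cd45) |
| CTC | ckmix ≥ mean(ckmix) AND cd45 < mean(cd45) |
| WBC | ckmix < mean(ckmix) AND cd45 ≥ mean(cd45) |
| UNCLASSIFIED | anything else |

Rules are evaluated top-down, so an MSLN-positive call implies the CTC
conditions and every cell receives exactly one label.  Boundary handling is
exact: tumor gates are inclusive (≥), the CD45 gate strict (<).  Because all
gates are relative to slide means, rescaling every intensity on a slide by a
common factor changes nothing (a tested invariant).

Choices made where the rule statement was genuinely open:

* The MSLN/CKmix criterion is read as **two per-channel comparisons**
  (each channel against its own slide mean); this matches the
  CKmix+/MSLN+ marker notation.  A joint-sum variant
  (msln + ckmix ≥ mean(msln) + mean(ckmix)) sits behind
  `RuleConfig(joint_vs_perchannel=True)`.
* The 47 µm² nuclear-area criterion gates only the MSLN-positive call,
  because it is stated only for that class;
  `RuleConfig(apply_area_to_plain_ctc=True)` extends it to all CTCs.
* Slide averages include every segmented cell (tumor and leukocyte alike).
* Qualitative manual criteria (morphological integrity, halos, debris) are
  not classification inputs; they would be represented only as a QC column.
* Per-patient counts are per 2 mL of blood (the draw volume convention);
  the CTC count includes the MSLN-positive subset, consistent with
  CTC ≥ MSLN(+)CTC in both reported groups.

`ihc_score(pct, intensity)` implements the tissue-staining score: the
percent-positive bin (0: <5%, 1: 5–25%, 2: 26–50%, 3: 51–75%, 4: >75%)
multiplied by the intensity grade (0–3).

## Diagnostic statistics

* **Group summaries**: sample SD (n−1); 95% CI as mean ± 1.96·SD/√n.  The
  z-based normal approximation (not t) is used because the published
  summary-table intervals reproduce under z but not under t.  Report-layer
  rounding is half-up to one decimal, matching the tables.  Benign-group
  count CIs do not reproduce from the rounded summaries (they were
  evidently computed on raw data), so they are not asserted anywhere.
* **Detection rate**: percent of patients with ≥ 1 cell.
* **Mann-Whitney U**: midrank-based U; exact two-sided p by full
  enumeration when n₁+n₂ ≤ 12 without ties, otherwise the normal
  approximation with tie and continuity correction.  How the original
  analysis software handled count ties is not documented, so no claim is
  made to match unpublished p-values.
* **ROC**: candidate thresholds are midpoints between consecutive distinct
  pooled values plus ∓∞ sentinels; "value > threshold" is test-positive.
  AUC is the trapezoid over the ROC path, which with midpoint thresholds
  equals the tie-corrected rank statistic (concordant + ties/2)/(n₁n₂) — an
  identity checked exhaustively in the tests.
* **Youden cutoff**: maximizes J = sens + spec − 1 over the candidate set;
  ties break toward higher specificity, then higher threshold (a
  rule-out-oriented convention).  Both the midpoint and the smallest
  observed value called positive are reported; the latter is the display
  convention for counts and serum values (midpoint 0.5 cells ⇒
  "1 cell / 2 mL").
* **Combined models**: each marker binarized at its own Youden-optimal
  observed-value cutoff (value ≥ cutoff → 1); per-patient total score
  evaluated by the same ROC/Youden machinery.  Score cutoffs therefore come
  out as x.5 points: 0.5 ≡ logical OR of the markers, 1.5 on three markers
  ≡ at-least-2-of-3 (both tested identities).
* **Missingness**: complete-case per marker and per combined model.  This
  convention is what makes the published evaluable group sizes (14/15 and
  19/20 for CA125, 13/15 and 19/20 for HE4) and percentages (71.43% =
  10/14, 84.62% = 11/13, 94.74% = 18/19, 89.47% = 17/19) internally
  consistent.
* Two-sided tests, α = 0.05 throughout.  DeLong CIs and AUC-difference
  tests are out of scope (not part of the modelled analysis), as is any
  survival analysis.

## Count reconstruction from printed summaries

`reconstruct_counts` enumerates all integer multisets of size n within the
printed range whose mean and sample SD round (half-up, one decimal) to the
printed values, with optional constraints from the printed median and from
a detection rate or specificity (number of positive entries).  The search
runs over non-increasing vectors with pruning on partial sums and sums of
squares, so it is deterministic and permutation-free.  Both printed range
endpoints must be attained (the "Range" row reports observed extremes).

Half-up rounding is assumed for the printed summaries and is decisive: the
benign MSLN(+)CTC reconstruction (n=20, range 0–1, mean→0.1, SD→0.2) is
unique — 19 zeros and one 1 — precisely because 0.05 rounds up to 0.1.
The benign CTC vector is unique once the printed 80% specificity (4
positives) is imposed.  The EOC vectors are **not** unique; the reference
cohort stores the first admissible witness of the deterministic enumeration
that also reproduces the published Youden operating points and admits a
per-patient pairing with msln_i ≤ ctc_i, and flags it non-canonical in the
provenance sidecar.  Tests assert only constraint-implied quantities of
these witnesses (summary rows, detection rates, operating points), never
individual values.

Serum values in the reference cohort are synthetic placeholders.  The
published per-patient values are unknown; the placeholders are constructed
so that every published operating point — single-marker cutoffs (132 U/mL,
56 pmol/L), sensitivities/specificities, evaluable-n pattern, and all six
combined-model score cutoffs with their performance — is reproduced exactly
by the package's own Youden search.  The joint positivity/missingness
pattern across the four markers is pinned down by those operating points
(for example, the single CA125-positive control must be the same patient as
the single MSLN(+)CTC-positive control, and the case missing CA125 must
also miss HE4 so that the three-marker models have 13 evaluable cases and
19 controls).  Published AUCs depend on the full unpublished value
distributions and are deliberately not reproduction targets.

## Synthetic generators

**Cohorts.** Counts are zero-inflated negative binomial per group and
marker: mean (1−π)µ, variance (1−π)µ(1+µ/k+πµ).  Defaults are calibrated to
the study conditions: EOC MSLN(+)CTC π=0.30, µ=2.7/0.7, k=4 (mean 2.7,
SD ≈ 2.9, zero mass ≈ 1/3); EOC CTC π=0.10, µ=5/0.9, k=2.1 (mean 5.0,
SD ≈ 4.6); benign groups are mostly structural zeros with means 0.05 and
0.35.  Independent draws are coupled by ctc := max(ctc, msln) to enforce
the subset constraint; this inflates the CTC mean by well under one SE at
the default group sizes.  Serum markers are log-normal, moment-matched to
the printed group means/SDs (e.g. EOC CA125 mean 1357.8, SD 1538.2);
missingness is completely at random with per-group probabilities matching
the evaluable-n pattern.  Ages are uniform 30–75 — a placeholder, not a
demographic model.

**Slides.** Each true tumor cell survives capture independently with
probability `capture_efficiency` (default 0.75, the midpoint of the
reported 67.58–78.81% spike-in range); the leukocyte background is
Poisson(n_wbc), default 2000.  Nuclear areas are gamma: leukocytes
30 ± 3 µm², tumor cells 80 ± 8 µm², so the 47 µm² gate sits > 4 SD from
both means.  Channel intensities are log-normal per class and channel with
a **shared per-cell brightness factor**: within a cell the four channels
are comonotone (cells stain brightly or dimly as a whole), and each
marginal is the configured log-normal.  This correlation is what makes the
mean-relative rule exact on well-separated slides: a leukocyte above the
slide's CKmix mean is, through the same brightness factor, also above the
CD45 mean, so it can never satisfy both CTC gates; MSLN-negative cells sit
a guaranteed margin below the slide MSLN mean because leukocytes (the
dominant population) carry a higher MSLN-channel background (nonspecific
uptake) than MSLN-negative tumor cells.  Positive/negative populations are
separated by ≥ 4 log-SD.

**Rendering.** Cells are drawn as hard disks of their nuclear area,
flux-normalized to the specified channel totals, convolved with a Gaussian
PSF (flux-conserving; cells are placed with an edge margin), over a
constant background with optional Poisson shot noise and Gaussian read
noise (both off by default).  A density guard rejects slides whose summed
disk area exceeds 20% of the field.  Segmentation inverts this: Otsu
threshold on DAPI, connected components, area = pixel count × pixel size²,
channel totals summed over the component footprint dilated by 6 px (to
recapture PSF-smeared flux) minus the median background.  Without noise,
totals are recovered within 1%.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: optical cell overlap and segmentation merge
errors at high density (tests render sparse or controlled fields),
staining-batch effects, autofluorescence structure beyond a constant
background, debris and apoptotic fragments, reader disagreement in manual
review, EpCAM-expression heterogeneity of capture, and any biological
correlation between serum markers and CTC counts within a patient (the
cohort generator draws them independently given the group).

## Problem sizes and numerics

Property suites run at deliberately small scale — 1000 random cohorts of
≤ 15 per group for the AUC/U identity, 500 patients per group for
operating-point recovery, slides of a few hundred cells — chosen so the
full suite completes in seconds while still exercising every identity
exhaustively at those sizes.  Exact rational arithmetic (`fractions`)
drives the reconstruction's rounding bands; `decimal` half-up rounding is
used wherever printed-table values are compared.  All randomness flows from
explicit `numpy` generators seeded per run; identical configuration and
seed give bit-identical tables.
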