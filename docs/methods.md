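# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Image model and units

CT and PET volumes are 3-D scalar grids with millimetre voxel spacing,
assumed hardware-aligned on one common grid (shapes equal, spacings equal
within 10⁻⁶ mm); registration and resampling are out of scope and a grid
mismatch is a hard error. CT carries Hounsfield units, PET carries
standardized uptake values; conversion from raw DICOM/activity data is
likewise out of scope — inputs are already-converted NIfTI grids. Voxel
`(i, j, k)` has its center at world coordinate `(i·sx, j·sy, k·sz)`;
volumes are reported in cm³ as voxel count × voxel volume (mm³) / 1000.

## Active-marrow quantification

Pelvic bone (BM_TOT) is the set of voxels with **HU ≥ 150** (inclusive)
inside an operator-supplied axial slab plus optional lateral crop; no
morphological cleanup is applied, and manual correction enters only as an
ordered list of single-voxel add/remove edits. The activity threshold is
the **mean SUV over the final (corrected) bone mask** — the averaging
region is not uniquely determined by the clinical description, so it is
an explicit choice here, applied after edits. BM_ACT collects bone voxels
with **SUV ≥ that mean** (inclusive), and BM_ACT% = 100 · BM_ACT / BM_TOT.
Because the threshold is the sample mean, BM_ACT% is exactly invariant
under positive rescaling of the SUV map (a property test asserts this);
additive shifts can change it only by moving voxels across the mean.

Groups: `<30%`, `[30%, 40%]`, `>40%` — the middle bin is closed on both
ends, the only partition consistent with the stated bin labels.

## Tumor metabolic parameters

The lesion VOI is an axis-aligned ellipsoid in millimetres; a voxel
belongs to it iff its **center** satisfies Σ((x−c)/r)² ≤ 1 (no
partial-volume weighting). SUVmax is the maximum SUV over the VOI. The
MTV segmentation takes VOI voxels with **SUV > 0.40 · SUVmax** — strict,
in contrast to the inclusive bone/marrow thresholds, mirroring the
wording of the respective clinical definitions; both thresholds are
config-overridable. The strict threshold guarantees a nonempty MTV (the
max voxel always qualifies). TLG = MTV × mean SUV of the MTV region,
an identity asserted to 10⁻⁹.

When an interference mask is supplied (bladder urine etc.), the PET is
copied and zeroed inside the mask **before** any metric, so SUVmax is
taken on the cleared volume.

## Hematologic toxicity grading

For each of WBC, ANC, HGB, PLT, the nadir is the minimum over all
recorded values, baseline included by default (inert for cohorts with no
pre-treatment cytopenia, but configurable). Grades come from a
CTCAE-v5-style table shipped as YAML (`pelvimarrow/data/ctcae_v5.yaml`):
per analyte, four strictly decreasing lower bounds for grades 1–4, with
grade 0 at or above the first bound (the lower limit of normal). A value
exactly equal to a bound takes the **milder** grade, following the
"< x – y" phrasing of the grade ranges. The numeric bounds are not
facts of the clinical study being operationalized; they are standard
CTCAE values with adult-female lower limits of normal (WBC 4.0, ANC 2.0 ×10⁹/L,
HGB 120 g/L, PLT 150 ×10⁹/L) and one operational choice: anemia grade 4,
defined clinically in CTCAE, gets a numeric bound of 65 g/L. All tests
are conditioned on this shipped table, and the table is user-editable.

Overall HT = max of the four toxicity grades, capped at 4 by the table;
the severe group is G3+ (overall ≥ 3), the rest G0–2. The group label
"more severe than grade 3" in the source description conflicts with its
own "grade 3–4" usage; the implementation follows the usage (≥ 3).

## Statistical battery

- **Normality gate**: one-sample Kolmogorov–Smirnov with Lilliefors
  correction (mean/SD estimated), table p-values; "normal" means
  p ≥ 0.05. Samples with n < 4 or zero variance take the rank-based
  branch. The gate is a pure function of the samples, so the method
  choice is deterministic.
- **Two-group continuous**: pooled-variance Student t if both samples
  pass the gate, else Mann–Whitney U reported as the tie-corrected
  asymptotic Z **without** continuity correction (matching Z-style
  reporting in the clinical literature).
- **Paired changes**: the same gate on the differences selects paired t
  vs Wilcoxon signed-rank (two-sided).
- **Categorical**: Pearson χ² = Σ(O−E)²/E with df = (r−1)(c−1); on 2×2
  tables, mode `auto` applies the Yates continuity correction iff any
  expected count is below 5. This rule was chosen because it reproduces
  the reference pairwise triplet exactly: [[10,3],[3,10]] → 7.538 and
  [[3,10],[9,6]] → 3.877 uncorrected (min expected ≥ 5), while
  [[10,3],[9,6]] → 0.303 with Yates (min expected 4.18). Fisher's exact
  test (two-sided, hypergeometric tail sum) is used for 2×2 tables with
  expected counts below 1 in the cohort battery, and available directly.
- **Multiplicity**: Holm–Bonferroni step-down with monotonicity
  enforcement, order-preserving with the input. Pairwise post-hoc
  p-values are reported both raw and adjusted, because the reference
  publication prints raw pairwise values while stating a Holm procedure.
- **Logistic regression**: maximum likelihood (Newton/IRLS via
  statsmodels), dummy coding with a declared reference level — the
  30–40% BM_ACT% group for the marrow-group factor. OR = exp(β) with
  Wald 95% CI = exp(β ± 1.96·SE). Non-convergence and separation
  (detected as exploding standard errors) raise instead of returning a
  silently broken fit. The univariate screen for model entry is p < 0.1.

One known discrepancy is documented rather than reconciled: the overall
3×2 grouped-BM_ACT% statistic recomputed from the published counts is
Pearson χ² = 7.962 (p = 0.019), which matches neither the printed 7.769
nor the likelihood-ratio or trend variants; the package reports the
Pearson value.

## Synthetic data

**Phantom.** CT: air (−1000 HU), a soft-tissue cylinder (40 HU), and a
bone annulus (400 HU; radial 40–48 mm over a 96 mm axial slab) standing
in for the pelvic ring — only the annulus exceeds the 150 HU threshold,
so the bone voxel count is known by construction. PET: bone voxels carry
a two-component marrow model — a fraction *f* of them (randomly placed,
seed-controlled) at SUV 3.0, the rest at SUV 0.5 — so the ≥-mean active
set is exactly the high component and recovered BM_ACT% equals *f*
exactly. *f* is realized as round(f·N)/N on the N bone voxels and the
truth record carries the realized value (the difference is < 0.001% at
the default ~63k bone voxels). The lesion is a spherical Gaussian,
SUV(r) = P·exp(−r²/2σ²), with its center snapped to a voxel center so
SUVmax = P is attained exactly; the 40% isocontour radius is
r\* = σ√(2 ln 2.5) and the analytic MTV is (4/3)πr\*³. The default σ
(15.59 mm) targets 39.4 cm³, and the default peak is 17.5, the values of
the published example case. An optional SUV-30 bladder sphere sits inside
the VOI but outside the 40% isocontour, so interference clearing changes
SUVmax (30 → 17.5) without touching the MTV. Marrow SUVs *replace* the
lesion tail inside bone (rather than adding) to keep the active set
exact. The phantom emulates geometry and intensities only — no scanner
noise, point-spread blur, attenuation or anatomic realism — so passing
tests certify the quantification arithmetic, not robustness to image
degradation.

**Cohorts.** Covariates are drawn from the reference trial's Table-1
statistics (age 52.6 ± 10.4, BMI 22.6 ± 3.0, FIGO 6/32/3,
differentiation 7/24/10, etc.), independent of outcome except through
the group-conditional toxicity probabilities — motivated by the trial's
null univariate results for everything except the marrow grouping.
BM_ACT% is uniform within its group's interval (truncated to [5, 70]
overall); group membership has probabilities 13/41, 13/41, 15/41 and
G3+ probabilities 3/13, 10/13, 6/15 conditional on group. The overall
grade given severity follows the observed grade split; per-analyte
grades are then assigned by letting one "carrier" analyte (chosen with
probability proportional to the observed per-toxicity share of that
grade) realize the overall grade while the others draw from their
observed marginals truncated at the overall — a documented approximation
of the unreported joint cytopenia distribution.

**Blood series** are built backwards from the target grades: each nadir
is drawn from a truncated normal centered on the printed nadir mean/SD,
truncated to the target grade's threshold interval (shrunk 2% from each
edge so floating-point boundaries cannot flip the grade), with baselines
truncated into the normal range; values then interpolate baseline →
nadir (day 28) → 40% recovery (day 42) over weekly timepoints. Re-grading
therefore reproduces the intended grades with probability 1, which the
round-trip tests assert.

**Fixture cohort.** `realize_table3_cohort()` is deterministic: group
labels realize the published 3×2 cross-tabulation [[10,3],[3,10],[9,6]]
exactly, and a frozen 41×4 grade matrix (solved once by constrained
assignment) realizes every per-toxicity grade marginal and the overall
grade distribution (2, 2, 18, 15, 4) simultaneously, with each patient's
maximum grade equal to their overall grade.

## Problem sizes and numerical choices

Defaults were chosen as the smallest sizes that make each claim sharp:
the phantom grid is 96³ at 1.5 mm (~63k bone voxels; MTV discretization
error 0.7%, comfortably inside the 5% bound); oracle sweeps use 1,000
random tables for χ² (tolerance 10⁻¹⁰) and exhaustive enumeration of all
2×2 tables with total n ≤ 40 for Fisher; recovery simulations use 50
seeds at n = 5000 (median absolute coefficient error ≈ 0.05, bound 0.1)
and 200 seeds at n = 41 for the paired comparison. Spacing tolerance for
paired grids is 10⁻⁶ mm; identity checks (TLG, OR = exp β) are asserted
at 10⁻⁹–10⁻¹².

## Limitations

- The anatomical ROI is supplied externally; there is no vertebra
  detection, and the phantom's "pelvis" is a cylinder, not anatomy.
- The CTCAE numeric bounds and the anemia grade-4 cut are configuration,
  not facts of the operationalized study; cohorts generated under a
  different table will re-grade differently by design.
- Per-group BM_ACT% distributions and the joint distribution of the four
  cytopenias are assumptions (uniform-within-group; carrier-analyte
  scheme), since only margins are published.
- Adjusted odds ratios and the univariate SUVmax Z-statistic of the
  reference trial require patient-level data that was never deposited;
  the package reproduces the reproducible quantities and replaces the
  rest with parameter-recovery simulations on synthetic cohorts.
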