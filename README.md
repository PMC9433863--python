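# pelvimarrow

Quantification and statistics for predicting hematologic toxicity (HT)
during pelvic chemoradiotherapy from baseline ¹⁸F-FDG PET/CT.

Concurrent chemoradiotherapy for locally advanced cervical cancer
irradiates much of the pelvic skeleton, and the pelvis holds a large share
of an adult's hematopoietically active (red) bone marrow. Patients whose
active marrow is unfavorably distributed develop severe cytopenias —
leukopenia, neutropenia, anemia, thrombocytopenia — that delay or
interrupt treatment. This package implements the baseline-imaging analysis
that links the PET/CT-derived distribution of active marrow (and tumor
metabolic burden) to the worst on-treatment toxicity grade.

## What it computes

**Active-marrow quantities** from a paired CT/PET on one grid:

- **BM_TOT** — pelvic bone volume, segmented on CT as HU ≥ 150 inside an
  operator-supplied pelvic slab (L4–L5 through the ischial tuberosities),
  with optional manual voxel edits;
- **BM_ACT** — the subvolume of BM_TOT with SUV ≥ the patient's mean bone
  SUV;
- **BM_ACT%** = BM_ACT / BM_TOT, grouped as &lt;30%, 30–40%, &gt;40%.

**Tumor metabolic parameters** from an ellipsoid VOI around the primary
lesion, after zeroing any interfering high-uptake structure (e.g. bladder
urine):

- **SUVmax** — maximum SUV inside the VOI;
- **MTV** — volume of VOI voxels with SUV &gt; 40% · SUVmax;
- **TLG** — MTV × mean SUV of the MTV region.

**Hematologic toxicity**: nadirs of WBC, ANC, HGB and PLT graded against a
CTCAE-v5-style threshold table (shipped as editable YAML); overall HT =
max of the four grades; patients split into G0–2 vs G3+.

**Statistics**: Lilliefors-gated Student t / Mann–Whitney U comparisons,
paired t / Wilcoxon signed-rank for baseline-vs-nadir changes, Pearson
chi-square (automatic Yates correction on 2×2 tables with expected counts
&lt; 5) and Fisher's exact test, Holm–Bonferroni-adjusted pairwise group
comparisons, and binary logistic regression with Wald 95% CIs on odds
ratios (reference level: the 30–40% BM_ACT% group).

Because no patient images or records are distributed, the
`synthetic_data` module generates (a) PET/CT phantoms whose BM_ACT%,
SUVmax and 40%-isocontour MTV are known analytically, and (b) cohorts
whose covariates, grade distribution and grouped-BM_ACT% × HT
cross-tabulation follow the reference 41-patient trial — including a
deterministic fixture cohort that realizes the published counts exactly.

## Worked example

```python
from pelvimarrow import marrow_quant, synthetic_data, tumor_quant

phantom = synthetic_data.generate_phantom(
    synthetic_data.PhantomConfig(active_fraction=0.312, seed=1)
)

bone = marrow_quant.segment_bone(phantom["ct"], phantom["roi"])       # HU >= 150
bm = marrow_quant.compute_bm_metrics(phantom["pet"], bone)
tm = tumor_quant.tumor_metrics(
    phantom["pet"], phantom["voi"], interference=phantom["interference"]
)

print(f"BM_TOT  = {bm.bm_tot_volume:.1f} cm^3")
print(f"BM_ACT% = {bm.bm_act_pct:.1f}  (group {marrow_quant.classify_bm_act_group(bm.bm_act_pct)})")
print(f"SUVmax  = {tm.suvmax}")
print(f"MTV     = {tm.mtv:.1f} cm^3   TLG = {tm.tlg:.0f}")
```

prints

```
BM_TOT  = 214.1 cm^3
BM_ACT% = 31.2  (group MID30_40)
SUVmax  = 17.5
MTV     = 39.7 cm^3   TLG = 412
```

i.e. the pipeline recovers the phantom's generating parameters: the active
fraction 31.2% exactly (falling in the 30–40% group), the configured
lesion peak 17.5 exactly (the interfering SUV-30 bladder is cleared
first), and the 39.4 cm³ analytic 40%-isocontour volume to within the
voxel discretization (0.7% at 1.5 mm spacing).

## Analysis scripts

The numbered drivers under `analysis/` run the full study on synthetic
data and write tables under `results/` (bulky NIfTI volumes go to
`scratch/`):

```bash
python analysis/01_simulate.py   # phantom + fixture cohort + sampled cohort
python analysis/02_quantify.py   # phantom quantification vs ground truth
python analysis/03_grade.py      # CTCAE grading and toxicity tables
python analysis/04_stats.py      # univariate battery, post-hoc, logistic model
```

The same stages are available behind a CLI
(`pelvimarrow {simulate|quant|grade|stats|all} --out DIR`) for running on
real NIfTI/CSV inputs.

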