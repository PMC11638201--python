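# mmpatterns

Multimorbidity pattern discovery for survey cohorts, with a dual-criterion
hypertension sensitivity analysis.

## The problem

Multimorbidity — carrying two or more chronic conditions at once — is usually
quantified from self-reported disease checklists in large health surveys.
Hypertension is the one condition whose status also depends on a measured
quantity and on a guideline choice: the conventional diagnostic threshold is
140/90 mmHg (2018 Chinese Hypertension League), while the 2017 ACC/AHA
guideline lowered it to 130/80 mmHg. Lowering the threshold reclassifies
everyone whose blood pressure falls in the 130/80–140/90 band, which changes
multimorbidity prevalence and could, in principle, reshape which diseases
cluster together. This package implements the full analysis needed to ask
that question of a cohort: it derives disease status for 26 chronic
conditions under any named blood-pressure criterion, discovers multimorbidity
patterns by clustering the diseases, and replicates everything under both
criteria and within population subgroups.

## The method

For each pair of diseases *(i, j)* with 2×2 joint counts *a* (both), *b*
(*i* only), *c* (*j* only), *d* (neither), the association is Yule's Q:

```
Q = (ad − bc) / (ad + bc)        Q ∈ [−1, 1], 0 at independence
```

Degenerate tables (ad + bc = 0) receive a logged Haldane–Anscombe 0.5
continuity correction. The dissimilarity `d = 1 − Q` feeds agglomerative
clustering with Ward's method via the Lance–Williams update

```
d(k, i∪j) = [(nᵢ+nₖ)·d(k,i) + (nⱼ+nₖ)·d(k,j) − nₖ·d(i,j)] / (nᵢ+nⱼ+nₖ)
```

applied to the dissimilarities as supplied (the `ward.D` dialect; a
`square_dissimilarity` switch gives the `ward.D2`/SciPy behaviour). Cutting
the dendrogram at k = 4 yields the multimorbidity patterns; the
hypertension-containing ("cardiometabolic") pattern — hypertension, diabetes,
acute myocardial infarction, angina, stroke/TIA — is analysed in depth:
pattern prevalence (≥2 member conditions), exact combination frequencies,
component-disease mix, and the share of each disease's carriers who are
pattern-multimorbid. Because the real survey data are not public, a
latent-threshold synthetic-cohort generator with four planted disease blocks
provides ground truth for every test.

## Worked example

```python
from mmpatterns import MultimorbidityModel, simulate

cohort = simulate.generate(simulate.SyntheticConfig(seed=1))
results = MultimorbidityModel(cohort).fit()
print(results.summary())
```

```
                    Multimorbidity Pattern Analysis
========================================================================
Participants:     20,000    Diseases: 26    k: 4
Focal pattern: cardiometabolic (acute_mi, angina, diabetes, hypertension, stroke_tia)
------------------------------------------------------------------------
criterion    threshold    htn %  multimorb %  pattern %
CHL2018         140/90     23.4         16.8        5.3
ACCAHA2017      130/80     46.8         21.1        6.7
------------------------------------------------------------------------
  [1] cardiometabolic: hypertension, diabetes, angina, acute_mi, stroke_tia, pulmonary_heart_disease, traumatic_brain_injury, other_ihd, rheumatic_heart_disease
  [2] respiratory: copd, pulmonary_tb, emphysema, chronic_bronchitis, asthma
  [3] digestive-bone-kidney: gallstones_cholecystitis, fracture, chronic_hepatitis_cirrhosis, chronic_kidney_disease, peptic_ulcer, osteoporosis, rheumatoid_arthritis
  [4] mental-cancer: anxiety, cancer, depression, neurasthenia, other_mental
------------------------------------------------------------------------
  pattern stability ARI CHL2018 vs ACCAHA2017: 1.000
========================================================================
```

Reading the table: switching from the 140/90 to the 130/80 criterion doubles
diagnosed hypertension (23.4% → 46.8%) and raises multimorbidity prevalence
(16.8% → 21.1%) and cardiometabolic-pattern prevalence (5.3% → 6.7%), yet
the four patterns recovered by the k = 4 cut are identical under both
criteria (adjusted Rand index 1.000): the criterion revision expands *who*
is multimorbid without changing *which* diseases travel together. The four
unplanted "noise" diseases (other IHD, pulmonary/rheumatic heart disease,
traumatic brain injury) attach to whichever cluster is nearest; the planted
block members are recovered exactly.

A command-line interface wraps the same pipeline:

```
mmpatterns simulate --out cohort.csv --seed 1 --n 20000
mmpatterns run --config config.yaml --out results/
```

`run` emits, per criterion, the association and dissimilarity matrices,
dendrogram (Newick + merge table), pattern assignment, stratified prevalence
tables, combination frequencies and per-disease pattern shares, plus
per-stratum replications and a run manifest.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on the default synthetic world
(seeded by `--seed`): cohort generation, disease matrices under both
criteria, Yule's Q / Ward clustering, pattern assignment, prevalence and
stability summaries, and a sex-stratified replication, then writes the
results JSON to `--out`.
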