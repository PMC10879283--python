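# ftdx — explainable differential diagnosis of FTD subtypes from structural-MRI morphometry

Frontotemporal dementia presents as three core clinical syndromes —
behavioral-variant FTD (bvFTD) and the semantic (svPPA) and nonfluent
(nfvPPA) variants of primary progressive aphasia — whose early atrophy
patterns overlap enough that single-scan visual reads are unreliable.
`ftdx` implements, end to end, a classifier-plus-explanation pipeline
for separating the three syndromes from parcellated T1 morphometry:
735 features per subject (mean cortical thickness and volume over 360
HCP-MMP1-style patches, plus 15 subcortical volumes).

The pipeline has four stages:

1. **W-score harmonization.** Each feature is regressed (OLS, reference
   group = bvFTD) on age, sex, TIV and a cohort×scanner factor; every
   subject becomes a standardized residual
   `w = (x − designᵀβ) / σ_ref`, removing multi-site batch effects and
   demographic trends while preserving disease contrast. Strict
   fit/transform separation keeps cross-validation leakage-free.
2. **Parallel multi-type feature embedding.** A two-level MLP embeds
   thickness (360→128→32) and volume (375→128→32) through separate
   arms, concatenates the embeddings and fuses them (64→32→3 logits).
   Training: SGD (lr 1e−3, weight decay 1e−5), class-weighted cross
   entropy (weights ∝ inverse class frequency) for the 173/63/41
   imbalance, dropout 0.2, early stopping on validation balanced
   accuracy.
3. **Nested 10-fold cross-validation with ensembling.** Each outer fold
   holds out ~10% for testing; nine stratified inner rotations of the
   remaining 90% (≈80% train / 10% validation each) yield nine models
   whose mean softmax is the fold's prediction. Per-class balanced
   accuracy = (sensitivity + specificity)/2, one-vs-rest; the overall
   score is the three-class mean.
4. **Explanation.** Integrated-Gradient attribution maps per subtype
   (population mean over subjects and ensemble members) and classical
   patch-wise one-vs-rest linear models with Benjamini–Hochberg FDR at
   0.05 as the statistical counterpart.

The clinical cohorts such a model is trained on are access-restricted,
so the package ships a synthetic-cohort simulator that reproduces the
published sample's structure (class sizes 173/63/41, age 63.7 ± 7.7,
54.5% male, two cohorts with scanner-level batch effects, planted
subtype-specific atrophy with known ground truth). Every quantitative
claim in the test suite is a recovery test against that ground truth.

## Worked example

```python
from ftdx import SimulationConfig, generate_cohort, run_nested_cv

cfg = SimulationConfig(
    n_per_class={"bvFTD": 44, "nfvPPA": 16, "svPPA": 12}, seed=7
)
table, truth = generate_cohort(cfg)        # 72 subjects x 735 features
result = run_nested_cv(
    table, seed=7, k=4, max_epochs=150, patience=150, batch_size=8
)
print(result.report["per_class_balanced_accuracy"])
print(result.report["overall_balanced_accuracy"])
print(result.report["confusion"])
```

prints

```
{'bvFTD': 0.937, 'nfvPPA': 0.951, 'svPPA': 0.983}
0.957
[[40  2  2]
 [ 1 15  0]
 [ 0  0 12]]
```

i.e. with the default planted atrophy (Cohen's d = 2 per patch) the
nested-CV ensemble recovers the three subtypes almost perfectly even at
this reduced cohort size: the pooled confusion matrix shows 40/44 bvFTD,
15/16 nfvPPA and 12/12 svPPA test subjects correctly classified, and
the per-class balanced accuracies (sensitivity and specificity against
the other two classes) average to 0.957. On the published scale
(n = 277) the same run reaches overall balanced accuracy ≥ 0.95; a
label-permuted control stays at the 0.5 chance level.

The same pipeline is scriptable from the shell:

```bash
ftdx simulate --seed 7 --out-dir data/
ftdx train --features data/features.csv --metadata data/metadata.csv \
     --seed 7 --out metrics.json
ftdx explain --features data/features.csv --metadata data/metadata.csv \
     --out importance.csv
ftdx statmap --features data/features.csv --metadata data/metadata.csv \
     --subtype svPPA --out statmap.csv
```

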