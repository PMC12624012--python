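# cpsrec — data-augmented ML for personalized carbohydrate–protein supplementation

`cpsrec` is a Python pipeline for building **personalized carbohydrate–protein
supplement (CPS) recommendations** for endurance athletes from small tabular
cohorts.  The setting: each record is one 60-minute rowing-ergometer trial
described by 46 numeric baseline indicators (anthropometry, sleep, HRV, blood
markers, lifestyle, beverage composition) plus the supplement dose columns
`CHO` and `PRO` (g of carbohydrate / protein per kg body mass per hour), with
total **rowing distance in meters** as the outcome.  Cohorts like this are
expensive to collect, so the sample (~231 records) is small relative to the
feature count — the pipeline's core idea is to counter that scarcity with
**tabular data augmentation** embedded in a leakage-safe modeling protocol.

The pipeline stages, each an importable module:

1. **`cohort`** — a seeded synthetic-cohort generator (the real study data are
   private) with planted collinear pairs, realistic marginals, and an
   individual-specific quadratic dose–response with a known interior optimum,
   so every downstream stage has a ground-truth oracle.
2. **`partitioning`** — 80/20 development/hold-out split stratified on
   quartile bins of the outcome; quartile-stratified 5-fold CV.
3. **`selection`** — hybrid feature selection: Pearson collinearity screen
   (|r| > 0.80), tuned XGBoost total-gain importances, and explicit
   keep/drop domain rules.  The published 21-feature working subset ships as
   `SELECTED_FEATURES`.
4. **`augmentation`** — three augmenters on the original scale with
   1%-extended range clipping and hard zero floors for nutrients:
   **Mixup** (λ ~ Beta(0.2, 0.2) convex combinations of feature *and*
   outcome), **Gaussian noise injection** (σ = 5% of each feature's SD), and
   a **WGAN-GP** (critic with gradient penalty λ_gp = 10, five critic steps
   per generator step, Adam(5·10⁻⁵, β₁ = 0.5, β₂ = 0.9)) implemented in
   NumPy with exact double-backprop for the penalty.
5. **`fidelity`** — Mann–Whitney U per column with Benjamini–Hochberg FDR,
   correlation-matrix preservation metrics, shared-bandwidth KDE curves, and
   a deterministic lexicographic ranking of augmentation methods.
6. **`modeling`** — three regressor families with family-specific scaling
   (XGBoost unscaled; SVR X-standardized; dropout MLP X-and-y standardized),
   randomized hyperparameter search on a 1:1-augmented development set,
   **dynamic per-fold 1:1 augmentation CV** (validation folds stay purely
   original), 2:1-augmented final training, and a provenance-checked
   hold-out evaluation.
7. **`recommender`** — two-stage dose enumeration: sweep CHO over 71 levels
   (0.50–1.20 g/kg/h, 0.01 steps) under PRO = CHO/4 and under PRO = 0, take
   the best prediction of each stage (P₁, P₂), and recommend the 4:1 CPS
   regimen iff P₁ ≥ P₂.

## Worked example

```python
import cpsrec
from cpsrec import partitioning, modeling, recommender, augmentation
from cpsrec.cohort import OUTCOME

table = cpsrec.generate_cohort(n=231, seed=7)          # 231 x 47
split = partitioning.stratified_split(table, 0.20, seed=42)
cols  = list(cpsrec.SELECTED_FEATURES) + [OUTCOME]
dev, hold = table.loc[split.development_indices, cols], table.loc[split.holdout_indices, cols]
print(len(dev), len(hold))                             # 184 47

spec = modeling.ModelSpec("boosted-trees",
                          {"n_estimators": 80, "max_depth": 5, "learning_rate": 0.3})
aug = augmentation.MixupAugmenter().fit(dev)
pred = modeling.train_final(dev, aug, spec, augmentation_ratio=2.0, seed=1)
print(pred.n_training_rows_)                           # 552  (184 + 2x184)

m = modeling.evaluate_holdout(pred, hold)
print(round(m.mae, 1), round(m.rmse, 1), round(m.r2, 3))   # 482.2 630.7 0.552

rec = recommender.recommend(pred, hold.drop(columns=[OUTCOME]).iloc[0])
print(rec.strategy, rec.cho, rec.pro)                  # CPS-4:1 0.71 0.1775
```

The hold-out MAE/RMSE are in meters of rowing distance; an R² of 0.55 on the
synthetic cohort means the model explains just over half of the
between-trial variance.  The recommendation sweeps all 142 candidate
regimens (71 CPS + 71 CHO-only) and returns the dose with the highest
predicted distance, with ties broken toward the 4:1 CPS strategy and, within
a stage, toward the lowest dose.

A full run — generation, split, selection, augmenter comparison, both
modeling arms, hold-out evaluation, and per-individual recommendations —
is one call (or `cpsrec run-all --outdir runs/demo` from the shell):

```python
from cpsrec.pipeline import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(seed=42), "runs/demo")
```

## Command-line interface

`cpsrec` exposes subcommands `generate`, `split`, `select-features`,
`augment`, `evaluate-augmentation`, `recommend`, and `run-all`; every
command takes explicit seeds and writes CSV/JSON artifacts.  See
`cpsrec --help`.

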