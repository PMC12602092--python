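# finclock

**Epigenetic-clock construction for nonlethal fish age estimation from
fin-clip DNA methylation.**

Age data drive fisheries stock assessment, but the standard source — counts
of opaque zones in otolith cross-sections — requires killing the fish.
DNA methylation at certain CpG dinucleotides changes predictably with age,
so a regression model on methylation levels ("epigenetic clock") can
estimate age from a fin clip. `finclock` implements the full construction
procedure for count data from enzymatic-conversion reduced-representation
sequencing (per-site methylated/total read counts plus an untreated library
portion for genotyping), with reference ages from paired otolith readings:

1. **Ages** (`finclock.aging`) — fractional age from opaque-zone counts and
   capture date (assumed March 15 birth date, fixed 365-day year), reader
   agreement, the index of average percent error (iAPE) and intra-observer
   error.
2. **QC** (`finclock.qc`) — removal of ungenotyped and SNP-suspect sites
   (pooled untreated substitution fraction > 5%), of shallowly sequenced
   individuals, of low-presence sites, and of sites whose exact
   Clopper–Pearson 95% intervals are too wide (width ≥ 0.85) in too many
   individuals; percent methylation with per-cell exact intervals.
3. **Age screen** (`finclock.screen`) — per site, a Bayesian binomial GLMM

   `Meth_f ~ Binomial(Total_f, p_f)`, `logit(p_f) = β0 + β1·Age_f + u_f`,
   `u_f ~ N(0, σ²_Fish)`,

   with the fish random intercept integrated out by Gauss–Hermite
   quadrature. A site is age-correlated when the 95% credible interval for
   β1 excludes zero. Engines: fast Laplace approximation (default) and
   slice-sampling MCMC (4 chains × 4000 iterations, convergence gates
   n_eff > 2000 and R-hat < 1.01). Over-dispersed cells (CI width > 0.85)
   are masked and imputed as the median among fish of the same (or nearest)
   integer age.
4. **Environment removal** (`finclock.envfilter`) — PCA, one-way PERMANOVA
   on Euclidean distances (9999 permutations, exact enumeration on small
   designs), and discriminant analysis of principal components (DAPC) with
   cross-validated PC count; sites contributing most to the first
   discriminant between focal water bodies are removed iteratively until
   PERMANOVA no longer separates them.
5. **Clock** (`finclock.clock`) — 80/20 train/test partition, Pearson
   prefilter (top 1000 |r| with age), natural-log transform of age, and a
   random-subset elastic-net search: repeatedly sample 125 sites with
   replacement and cross-validate both the mixing parameter α and the
   penalty λ, keeping the subset with minimum cross-validated MAE in years.
   Predicted age = `exp(β0 + Σ coef_s · p_s)`.
6. **Evaluation** (`finclock.evaluate`) — R², MAE, MDAE, and the regression
   of relative error on age.

A synthetic-cohort generator (`finclock.synth`) with per-site ground truth
(age-linear, environment-linear, age-by-environment, SNP-confounded and
neutral site classes; negative-binomial depth; shared fish random
intercepts; missingness) makes every stage testable without sequencing
data.

## Worked example

```python
import numpy as np
from finclock import (SyntheticConfig, simulate_cohort, partition_train_test,
                      pearson_prefilter, subset_search, predict_age)
from finclock.aging import select_agreement_subset
from finclock.qc import percent_methylation
from finclock.screen import impute_missing_cells
from finclock.evaluate import evaluate

config = SyntheticConfig(n_fish=100,
                         n_sites_by_class={"age_linear": 80, "neutral": 120},
                         seed=5)
matrix, fish, truths = simulate_cohort(config)
fish = select_agreement_subset(fish)
ages = np.array([r.fractional_age for r in fish])
frame = impute_missing_cells(percent_methylation(matrix),
                             [r.integer_age for r in fish]).to_frame()

part = partition_train_test(frame.index, [r.integer_age for r in fish],
                            train_frac=0.8, seed=0)
age_of = dict(zip(frame.index, ages))
y_train = np.array([age_of[f] for f in part.train_ids])
top = pearson_prefilter(frame.loc[part.train_ids], y_train, top_k=100)
model = subset_search(frame.loc[part.train_ids, top], np.log(y_train),
                      subset_size=40, iterations=30, seed=0,
                      alpha_grid=(0.1, 0.5, 1.0), n_folds=5, n_lambda=50)
pred = predict_age(model, frame.loc[part.test_ids])
true = np.array([age_of[f] for f in part.test_ids])
print(evaluate(pred.to_numpy(), true))
```

prints (see `examples/05_train_clock.py` for the narrated version):

```
ClockEvaluation(r2=0.961..., mae_years=0.80..., mdae_years=0.82..., ...)
```

i.e. on this small 100-fish cohort the held-out predictions track
otolith-derived age with R² ≈ 0.96 and a mean absolute error of ≈ 0.8
years; larger cohorts and longer subset searches (the `examples/` scripts
and the pipeline defaults) do better. Each `examples/` script exercises one
capability and prints a short interpretation.

The same pipeline runs from the shell:

```bash
finclock simulate --out cohort/ --seed 1
finclock pipeline --meth cohort/meth.tsv --total cohort/total.tsv \
    --substitutions cohort/substitutions.tsv --fish cohort/fish.csv \
    --out results/ --seed 1
```

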