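# ccxpen — penalized conditional logistic regression for case-crossover studies

The case-crossover design studies acute events (for example severe
drug-induced skin reactions) using cases only: each subject's exposure in
the window just before the event (the *case period*) is compared with the
same subject's exposure in an earlier *reference period*. The two windows
form a 1:1 matched pair, analysed with conditional logistic regression
(CLR). When an exposure is rarely *discordant* between the two periods —
few subjects switch between exposed and unexposed — the maximum-likelihood
estimate is unstable or infinite (separation), and multivariable CLR
produces wildly implausible odds ratios for exactly those sparse exposures.

`ccxpen` implements the CLR likelihood for matched pairs together with the
penalized and bias-reduced estimators that tame this sparse-data problem,
plus the evaluation layer needed to compare them against an external
benchmark classification. It is aimed at pharmacoepidemiologists and
biostatisticians analysing case-crossover (or matched case-control) data
with many binary exposures.

## The model

For subject *n* with case-period exposures **x**₁ₙ and reference-period
exposures **x**₀ₙ, the conditional log-likelihood is

    ℓ(β) = Σₙ [ β·x₁ₙ − log( exp(β·x₁ₙ) + exp(β·x₀ₙ) ) ],

which depends only on the differences zₙ = x₁ₙ − x₀ₙ; exp(βⱼ) is the odds
ratio of exposure *j*. Estimators provided:

| method | objective |
|---|---|
| univariable / multivariable CLR | maximize ℓ(β) (Newton–Raphson; separation capped at \|β\|=15 and flagged) |
| lasso | maximize ℓ(β) − λ Σ\|βⱼ\|, λ by 10-fold cross-validated likelihood |
| elastic net | maximize ℓ(β) − λ₁ Σ\|βⱼ\| − λ₂ Σβⱼ², (λ₁, λ₂) by CV |
| bolasso / sublasso | CV-lasso on B bootstrap samples / 75 % subsamples; keep drugs selected in ≥ 75 % of resamples at their average estimate |
| random lasso | two-step bootstrap lasso over random drug subsets of sizes q₁, q₂ |
| Firth | maximize ℓ(β) + ½ log det I(β) (Jeffreys penalty; finite under separation) |

Estimated log odds ratios are reclassified into three risk classes with
fixed cutoffs (highly suspected > 2.4, suspected > 0.45, other
otherwise) and scored against a benchmark classification, both as
correct-count tables and as ROC/AUC for the binary discriminations
"highly suspected vs rest" and "highly or suspected vs rest".

A synthetic-data module generates matched-pair exposure tables from known
true log odds ratios and per-drug discordance probabilities, including a
351-subject × 30-drug layout (9/10/11 class split, discordance spanning
ultra-sparse to common) on which the whole pipeline is exercised.

## Worked example

```python
from ccxpen import (euroscar_like_spec, simulate_dataset, count_discordances,
                    fit_clr, cv_lasso, reclassify, score_classification, roc_curve)

data, benchmark = simulate_dataset(euroscar_like_spec(seed=42))
disc = count_discordances(data)
print("sparse drugs (min discordance <= 1):", int((disc.min_discordance <= 1).sum()))

mle = fit_clr(data, mode="multivariable")
print("multivariable CLR separated drugs:", int(mle.separation_flags.sum()),
      "| largest |log OR|:", round(float(abs(mle.coefficients).max()), 2))

cv, lasso = cv_lasso(data, K=10, seed=42)
print("lasso lambda:", round(lasso.tuning["lambda"], 3),
      "| nonzero coefficients:", int((lasso.coefficients != 0).sum()),
      "| largest |log OR|:", round(float(abs(lasso.coefficients).max()), 2))

for name, est in [("clr-multi", mle.coefficients), ("lasso", lasso.coefficients)]:
    scored = score_classification(reclassify(est), benchmark, data.drug_names)
    roc = roc_curve(est, benchmark, "highly_only", drug_names=data.drug_names)
    print(f"{name:9s} total correct {scored.total_correct}/30 | AUC (highly) {roc.auc:.3f}")
```

prints

```
sparse drugs (min discordance <= 1): 19
multivariable CLR separated drugs: 1 | largest |log OR|: 15.0
lasso lambda: 0.287 | nonzero coefficients: 24 | largest |log OR|: 4.58
clr-multi total correct 22/30 | AUC (highly) 0.910
lasso     total correct 21/30 | AUC (highly) 0.958
```

Nineteen of the 30 simulated drugs are sparse; one drives the
multivariable MLE to the divergence cap (log OR 15, odds ratio ~3×10⁶),
while the cross-validated lasso keeps every estimate plausible (≤ 4.6)
and discriminates truly high-risk drugs better (AUC 0.958 vs 0.910).
Averaged over replicates the lasso also matches or beats the MLE on
total correct reclassifications.

The same analyses run from the shell:

```bash
ccx simulate --seed 42 --out data.csv --benchmark-out bench.csv
ccx fit --method lasso --data data.csv --seed 42 --out fit_lasso.tsv
ccx evaluate --fits . --benchmark bench.csv --out report.json
ccx run --config run.yaml       # full multi-method comparison
```

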