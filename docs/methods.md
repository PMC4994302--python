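# Methods

## The matched-pair conditional likelihood

A case-crossover record is a 1:1 matched pair inside one subject: binary
exposures **x**₁ₙ (case period) and **x**₀ₙ (reference period) to each of
p drugs. Conditioning on the pair removes all time-invariant
subject-level effects and the intercept; the contribution of pair *n* is

    ℓₙ(β) = β·x₁ₙ − log(exp(β·x₁ₙ) + exp(β·x₀ₙ)) = log σ(β·zₙ),

with zₙ = x₁ₙ − x₀ₙ ∈ {−1,0,1}ᵖ and σ the logistic function. Pairs
concordant in every drug contribute the constant −log 2: all information
lives in discordant exposures. For one drug, the MLE is the classic
discordant-pair estimator log(n₁₀/n₀₁), infinite when either count is
zero (separation / monotone likelihood). This is the sparse-data problem
the package addresses: with 30 drugs and a few hundred subjects, several
drugs typically have min(n₁₀, n₀₁) ≤ 1, and the joint MLE for those drugs
is extreme or divergent.

Evaluation is overflow-safe (log-sum-exp orientation); score and
information have the closed forms ∇ℓ = Σ zₙ σ(−ηₙ) and
I(β) = Σ wₙ zₙzₙᵀ with ηₙ = β·zₙ, wₙ = σ(ηₙ)σ(−ηₙ).

## Estimators

**CLR (Newton–Raphson).** Step-halving on ℓ; convergence at max|score| <
1e−8 or max step < 1e−10, 50-iteration cap. Estimates are clipped at
|β| = 15 (odds ratio ≈ 3×10⁶, far beyond anything interpretable); a
coordinate pinned at the cap with outward-pointing score is flagged as
separated and the fit marked non-converged. Capping rather than failing
keeps diverged estimates reportable and classifiable, mirroring how such
estimates appear (implausibly large but finite) in practice. Drugs with
no discordant pair have constant likelihood and stay at 0, unflagged.
The tolerances are chosen so the deterministic closed-form checks hold to
four decimals. Exposures are never standardized: all covariates share the
0/1 scale and coefficients must remain log odds ratios for the
reclassification cutoffs to make sense.

**Lasso / elastic net.** Penalized objective ℓ(β) − λ₁Σ|βⱼ| − λ₂Σβⱼ².
The ridge term uses the squared norm, so λ₂ = 0 is exactly the lasso and
λ₁ = 0 exactly ridge regression. Optimization is cyclic coordinate
descent: per coordinate, a Newton step on the local quadratic (gradient
gⱼ, curvature hⱼ = Iⱼⱼ) with soft-thresholding,
βⱼ ← S(hⱼβⱼ + gⱼ, λ₁)/(hⱼ + 2λ₂), with a per-update trust cap of 2.0 so
the quadratic model cannot overshoot on saturated likelihoods, and the
same |β| ≤ 15 clip. Convergence when no coefficient moves more than 1e−7
in a full cycle; post-convergence, |βⱼ| < 1e−8 snaps to exactly 0 so
"selected" is well defined for the ensembles. The inner loop is
numba-compiled; with zₙ sparse the per-cycle cost is proportional to the
total number of discordant cells.

λ_max = maxⱼ|n₁₀ⱼ − n₀₁ⱼ|/2 is the largest score coordinate at β = 0; by
the KKT conditions the lasso solution is identically zero for λ ≥ λ_max.
The default path has 100 log-spaced points from λ_max down to λ_max/1000
(a standard path convention), fitted with warm starts.

**Cross-validation.** Subjects — each carrying its intact pair — are
randomly partitioned into K = 10 near-equal blocks. For each penalty, the
model is fit on K−1 blocks and the held-out block's conditional
log-likelihood at the trained coefficients is recorded; the K held-out
contributions are *summed* (the cross-validated likelihood in the
Verweij–van Houwelingen sense) and the penalty maximizing the sum is
selected, ties going to the heavier penalty (sparser model). No
one-standard-error rule. The elastic net scans λ₂ over a small default
grid {0, 0.25, 0.5, 1, 2, 4} jointly with the λ₁ path; the grid is a
pragmatic default covering "no ridge" to "ridge comparable to the
likelihood curvature of a moderately discordant drug", exposed as a
parameter.

**Ensembles.** bolasso draws B bootstrap samples of the N pairs (with
replacement); sublasso draws ⌊0.75·N⌋ distinct pairs (without
replacement); in both, the CV-tuned lasso is re-fit per resample — each
resample is treated as its own dataset, penalty re-tuned — and a drug is
kept only if nonzero in at least 75 % of resamples, at its coefficient
averaged over *all* B resamples (zeros included; a switch
`average_over='selected'` averages over selecting resamples only, off by
default). Resamples whose likelihood is constant are redrawn (cap 100).
Random lasso runs the bootstrap loop twice over random drug subsets:
step 1 uses uniform subsets of q₁ drugs and produces importance weights
wⱼ = |mean coefficient|; step 2 draws subsets of q₂ drugs without
replacement with probability ∝ wⱼ (zero-weight drugs excluded). (q₁, q₂)
are selected from {15, 20, 25, 30} by 5-fold outer cross-validation
scoring the held-out conditional likelihood of the resulting final
estimate vector, ties to the smallest pair; because that selection loop
multiplies the work by |grid|² × folds × 2, the number of resamples used
inside it is a separate knob (`q_select_resamples`). Defaults are
B = 1000 and the full q grid; the test suite and the acceptance script
run scaled-down ensembles (B = 25–200, q-selection at 12 resamples) as
their problem-size choice.

**Firth.** Maximizes ℓ(β) + ½ log det I(β). The modified score is
implemented in the standard hat-value form
U*ⱼ = Σₙ zₙⱼ(1 − μₙ + hₙ(½ − μₙ)), hₙ = wₙ zₙᵀI⁻¹zₙ — analytically
equivalent to differentiating the log-determinant, and cheaper and more
stable than numerical differentiation — with Newton steps on U* and
step-halving on the penalized likelihood. In the univariable case the
solution is exactly log((n₁₀+½)/(n₀₁+½)): the ½-count-corrected odds
ratio, finite even under separation. Drugs with no discordant pair make
I singular and carry no information; they are dropped from the design and
reported as 0 with a flag — the penalty alone should not manufacture an
estimate. The same applies to exactly collinear difference columns
(e.g. two drugs discordant only in the same single subject), detected by
pivoted QR: log det I is degenerate for every β in that case, so a
maximal independent column subset is kept. The penalty constant is fixed
at ½ (the Jeffreys prior).

## Evaluation

Log-OR estimates map to three risk classes by fixed cutoffs: highly
suspected if β̂ > 2.4, suspected if 0.45 < β̂ ≤ 2.4, other if β̂ ≤ 0.45.
Boundaries go to the lower class so the exact zeros produced by shrinkage
land in "other"; boundary hits are measure-zero for continuous fits.
Agreement with a benchmark classification is reported per class and in
total. Discrimination uses ROC curves for the two binarizations of the
benchmark; the AUC is the Mann–Whitney rank statistic with ties counted
½, which equals the trapezoidal area under the full threshold sweep and
is independent of the 0–4 display grid used for the curve points. A
subsampling sensitivity analysis refits any estimator on repeated 75 %
subsamples (fraction configurable) and summarizes the AUC distribution by
median and IQR.

## Synthetic data

Each (subject, drug) cell is drawn independently from a three-way
mixture: concordant-exposed (1,1) with probability cⱼ, concordant-
unexposed (0,0) with probability 1 − cⱼ − dⱼ, discordant with probability
dⱼ; conditional on discordance the pair is (1,0) with probability
σ(βⱼ) — exactly the within-pair law of the conditional logistic model, so
βⱼ is the estimand of every fitter. Realized discordance fractions and
discordance directions converge to their targets, and univariable CLR
recovers βⱼ consistently (all property-tested).

The bundled 351-subject × 30-drug layout emulates a severe-drug-reaction
study population: a 9/10/11 split into highly-suspected / suspected /
other drugs, with true log ORs drawn per seed uniformly within each
class's band — highly suspected in (2.6, 4.2), consistent with benchmark
odds ratios for major risks reaching the 50–90 range and with the class
labels being coherent with the 0.45/2.4 cutoffs; suspected in (0.6, 2.0);
other exactly 0. Per-class discordance probabilities span sparse (about
one discordant pair in total) to common (~70 discordant pairs). The
high-risk class is mostly well observed — a drug is recognized as a major
risk precisely because many cases were exposed to it shortly before the
event — while the barely-informative sparse exposures concentrate in the
suspected and unsuspected classes, which is where unpenalized maximum
likelihood produces its extreme estimates. Concordant-exposed
probabilities are drawn from (0.01, 0.08), giving realistic background
use. Subjects with no exposure anywhere are redrawn
(`require_any_exposure`), emulating the study inclusion criterion that
every subject took at least one of the drugs under study, so the table is
already conditioned the way a shipped post-exclusion dataset is.

What this generator does *not* emulate: cross-drug correlation (drugs are
independent by default; observed correlations in real exposure tables are
low but nonzero), multi-drug prescribing patterns, time trends within
windows, or misclassified exposure. Consequently the multivariable and
univariable fits are closer to each other here than in real data, and
passing tests demonstrate the estimators' behaviour under sparse
discordance — not robustness to confounded or correlated exposure.

## Numerical and design choices

- Divergence cap 15, score tolerance 1e−8 (CLR) / 1e−6 (Firth),
  coordinate-descent tolerance 1e−7, zero-snap 1e−8: chosen so
  deterministic closed-form checks hold to 1e−4 with headroom.
- Fold assignment, bootstrap draws and simulation are all driven by
  explicit integer seeds; the pipeline derives per-stage seeds from one
  master seed via a stable hash, so any stage can be re-run independently
  yet reproducibly.
- Constant exposure columns yield NaN correlations (0/0 estimator), not a
  fabricated 0.
- Degenerate inputs: datasets with no discordant pair anywhere raise for
  λ_max (the likelihood is constant); concordant-only drugs are fitted as
  0 without flags; K > N folds and invalid probabilities raise.

## Limitations

- Strictly 1:1 matching; matched sets beyond one case/one reference
  period are out of scope.
- No standard errors or post-selection inference for the penalized fits.
- The random-lasso q-selection at its full defaults (B = 1000, 16 grid
  points, 5 folds) is computationally heavy; practical runs reduce
  `q_select_resamples`.
- The three-class cutoffs are taken as given; comparing shrunken and
  unshrunken estimators on fixed cutoffs structurally favours neither but
  penalizes shrinkage near class boundaries, which is why ROC/AUC (cutoff
  free) is reported alongside.
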