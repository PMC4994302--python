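"""Resampling ensembles around the cross-validated lasso.

Three variable-selection ensembles share one scheme: fit the CV-tuned
lasso on B resamples of the matched pairs, record per-drug selection
frequency (fraction of resamples with a nonzero coefficient), and report
the average coefficient for drugs selected in at least a threshold
fraction (default 75 %) of resamples, zero otherwise.  The average is
taken over *all* B resamples, zeros included (a config switch
``average_over='selected'`` averages over selecting resamples only).

- bolasso:  resamples are N pairs drawn with replacement (bootstrap).
- sublasso: resamples are floor(0.75 N) distinct pairs drawn without
  replacement (subsampling).
- random lasso: a two-step bootstrap ensemble over random drug subsets;
  step 1 fits on uniform subsets of q1 drugs to build importance weights
  w_j = |mean coefficient|, step 2 fits on subsets of q2 drugs drawn
  without replacement proportionally to w_j.  (q1, q2) are chosen from a
  candidate set by an outer cross-validation scoring the held-out
  conditional likelihood of the resulting estimate vector.

The penalty is re-tuned by K-fold CV inside every resample, treating each
resample as its own dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .clr_core import cond_loglik
from .io_data import CaseCrossoverDataset
from .penalized import cv_lasso, make_folds

REDRAW_CAP = 100


@dataclass
class EnsembleResult:
    """Selection frequencies and thresholded average estimates."""

    method: str
    drug_names: list
    n_resamples: int
    selection_frequency: np.ndarray
    mean_estimate: np.ndarray
    final_estimate: np.ndarray
    threshold: float
    tuning: dict = field(default_factory=dict)
    seed: int = 0
    all_zero_warning: bool = False

    def __post_init__(self) -> None:
        self.selection_frequency = np.asarray(self.selection_frequency, dtype=float)
        self.mean_estimate = np.asarray(self.mean_estimate, dtype=float)
        self.final_estimate = np.asarray(self.final_estimate, dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "drug": self.drug_names,
                "selection_frequency": self.selection_frequency,
                "mean_estimate": self.mean_estimate,
                "final_estimate": self.final_estimate,
            }
        )


def finalize_estimates(
    coef_matrix: np.ndarray, threshold: float, average_over: str = "all"
):
    """Apply the frequency-threshold / averaging rule to B coefficient rows."""
    B = coef_matrix.shape[0]
    nonzero = coef_matrix != 0.0
    freq = nonzero.mean(axis=0)
    if average_over == "all":
        mean = coef_matrix.mean(axis=0)
    elif average_over == "selected":
        counts = nonzero.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(
                counts > 0, coef_matrix.sum(axis=0) / np.maximum(counts, 1), 0.0
            )
    else:
        raise ValueError("average_over must be 'all' or 'selected'")
    final = np.where(freq >= threshold, mean, 0.0)
    return freq, mean, final


def _draw_valid(data: CaseCrossoverDataset, rng, sampler) -> CaseCrossoverDataset:
    """Draw a resample whose likelihood is not constant; redraw if needed."""
    for _ in range(REDRAW_CAP):
        idx = sampler(rng)
        sub = data.subset_subjects(idx)
        if np.any(sub.case_exposure != sub.ref_exposure):
            return sub
    raise RuntimeError(
        f"no resample with a discordant pair found in {REDRAW_CAP} draws"
    )


def _resample_loop(
    data, B, sampler, K, seed, n_lambda, min_ratio, drug_subsets=None
) -> np.ndarray:
    """Coefficient matrix (B x p) of CV-lasso fits on resamples.

    ``drug_subsets`` (optional, B index arrays) restricts each fit to a
    subset of drugs; the rest are fixed at zero.
    """
    rng = np.random.default_rng(seed)
    p = data.n_drugs
    coefs = np.zeros((B, p))
    for b in range(B):
        sub = _draw_valid(data, rng, sampler)
        cols = None if drug_subsets is None else np.asarray(drug_subsets[b])
        z = sub.exposure_difference().astype(float)
        if cols is not None:
            z = z[:, cols]
        if not np.any(z != 0):
            continue  # subset carries no information; all-zero fit
        fold_seed = int(rng.integers(0, 2**31 - 1))
        _, fit = cv_lasso(
            z, K=min(K, z.shape[0]), seed=fold_seed,
            n_lambda=n_lambda, min_ratio=min_ratio,
        )
        if cols is None:
            coefs[b] = fit.coefficients
        else:
            coefs[b, cols] = fit.coefficients
    return coefs


def bolasso(
    data: CaseCrossoverDataset,
    B: int = 1000,
    threshold: float = 0.75,
    K: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
    average_over: str = "all",
) -> EnsembleResult:
    """Bootstrap lasso ensemble: B resamples of N pairs with replacement."""
    if B < 1:
        raise ValueError("B must be >= 1")
    n = data.n_subjects

    def sampler(rng):
        return rng.integers(0, n, size=n)

    coefs = _resample_loop(data, B, sampler, K, seed, n_lambda, min_ratio)
    freq, mean, final = finalize_estimates(coefs, threshold, average_over)
    return EnsembleResult(
        method="bolasso",
        drug_names=list(data.drug_names),
        n_resamples=B,
        selection_frequency=freq,
        mean_estimate=mean,
        final_estimate=final,
        threshold=threshold,
        seed=seed,
        tuning={"K": K},
    )


def sublasso(
    data: CaseCrossoverDataset,
    B: int = 1000,
    subsample_fraction: float = 0.75,
    threshold: float = 0.75,
    K: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
    average_over: str = "all",
) -> EnsembleResult:
    """Subsampling lasso ensemble: distinct pairs drawn without replacement."""
    if B < 1:
        raise ValueError("B must be >= 1")
    n = data.n_subjects
    m = int(np.floor(subsample_fraction * n))
    if m < K:
        raise ValueError(f"subsample size {m} smaller than K={K}")

    def sampler(rng):
        return np.sort(rng.choice(n, size=m, replace=False))

    coefs = _resample_loop(data, B, sampler, K, seed, n_lambda, min_ratio)
    freq, mean, final = finalize_estimates(coefs, threshold, average_over)
    return EnsembleResult(
        method="sublasso",
        drug_names=list(data.drug_names),
        n_resamples=B,
        selection_frequency=freq,
        mean_estimate=mean,
        final_estimate=final,
        threshold=threshold,
        seed=seed,
        tuning={"K": K, "subsample_fraction": subsample_fraction},
    )


def _random_lasso_once(
    data, B, q1, q2, threshold, K, seed, n_lambda, min_ratio, average_over
):
    """Two-step random lasso at fixed (q1, q2); returns (freq, mean, final, warn)."""
    n, p = data.n_subjects, data.n_drugs
    rng = np.random.default_rng(seed)

    def sampler(r):
        return r.integers(0, n, size=n)

    # step 1: uniform drug subsets of size q1 -> importance weights
    subsets1 = [rng.choice(p, size=min(q1, p), replace=False) for _ in range(B)]
    coefs1 = _resample_loop(
        data, B, sampler, K, int(rng.integers(0, 2**31 - 1)),
        n_lambda, min_ratio, drug_subsets=subsets1,
    )
    weights = np.abs(coefs1.mean(axis=0))
    if not np.any(weights > 0):
        zeros = np.zeros(p)
        return zeros, zeros, zeros, True
    # step 2: subsets of size q2 without replacement, probability ~ w_j
    positive = np.flatnonzero(weights > 0)
    probs = weights[positive] / weights[positive].sum()
    q2_eff = min(q2, len(positive))
    subsets2 = [
        positive[rng.choice(len(positive), size=q2_eff, replace=False, p=probs)]
        for _ in range(B)
    ]
    coefs2 = _resample_loop(
        data, B, sampler, K, int(rng.integers(0, 2**31 - 1)),
        n_lambda, min_ratio, drug_subsets=subsets2,
    )
    freq, mean, final = finalize_estimates(coefs2, threshold, average_over)
    return freq, mean, final, False


def random_lasso(
    data: CaseCrossoverDataset,
    B: int = 1000,
    q_candidates=(15, 20, 25, 30),
    threshold: float = 0.75,
    K: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
    average_over: str = "all",
    q_select_folds: int = 5,
    q_select_resamples: int | None = None,
) -> EnsembleResult:
    """Two-step random lasso with (q1, q2) chosen by outer cross-validation.

    Every (q1, q2) pair from the candidate set is scored by
    ``q_select_folds``-fold CV: the two-step ensemble is run on each
    training split (with ``q_select_resamples`` resamples, default B) and
    the held-out pairs' conditional log-likelihood at the resulting final
    estimate vector is summed.  Ties go to the smallest (q1, q2).  The
    winning pair is then run on the full data with B resamples.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    p = data.n_drugs
    qs = sorted(int(q) for q in q_candidates)
    if any(q < 1 or q > p for q in qs):
        raise ValueError(f"q candidates must lie in 1..{p}")
    b_sel = B if q_select_resamples is None else int(q_select_resamples)
    rng = np.random.default_rng(seed)
    z = data.exposure_difference().astype(float)

    if len(qs) == 1:
        best_q = (qs[0], qs[0])
        select_scores = None
    else:
        folds = make_folds(data, q_select_folds, int(rng.integers(0, 2**31 - 1)))
        combos = list(product(qs, qs))
        scores = np.zeros(len(combos))
        for k in range(q_select_folds):
            train = data.subset_subjects(np.flatnonzero(folds != k))
            z_test = z[folds == k]
            fold_seed = int(rng.integers(0, 2**31 - 1))
            for c, (q1, q2) in enumerate(combos):
                _, _, final, _ = _random_lasso_once(
                    train, b_sel, q1, q2, threshold, K,
                    fold_seed + c, n_lambda, min_ratio, average_over,
                )
                scores[c] += cond_loglik(final, z_test)
        best_q = combos[int(np.argmax(scores))]  # first max = smallest (q1,q2)
        select_scores = dict(zip(map(str, combos), scores.tolist()))

    freq, mean, final, warn = _random_lasso_once(
        data, B, best_q[0], best_q[1], threshold, K,
        int(rng.integers(0, 2**31 - 1)), n_lambda, min_ratio, average_over,
    )
    return EnsembleResult(
        method="random_lasso",
        drug_names=list(data.drug_names),
        n_resamples=B,
        selection_frequency=freq,
        mean_estimate=mean,
        final_estimate=final,
        threshold=threshold,
        seed=seed,
        all_zero_warning=warn,
        tuning={"q1": best_q[0], "q2": best_q[1], "K": K,
                "q_select_scores": select_scores},
    )
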