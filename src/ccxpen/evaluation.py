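"""Benchmark evaluation: three-class reclassification, ROC curves, AUC.

Estimated log odds ratios are mapped to the three benchmark risk classes
with fixed cutoffs: above 2.4 -> highly suspected, in (0.45, 2.4] ->
suspected, at or below 0.45 -> other.  Boundary values go to the lower
class so exact zeros from shrinkage land in "other".

Discrimination is summarized by ROC curves for two binarizations of the
benchmark (highly-suspected vs rest; highly-or-suspected vs rest).  The
AUC is the Mann-Whitney rank statistic with ties counted one half, which
equals the trapezoidal area under the full threshold sweep and does not
depend on any display grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_data import BENCHMARK_CLASSES, CaseCrossoverDataset, DrugBenchmark

DEFAULT_CUTOFFS = (0.45, 2.4)


@dataclass
class ClassificationResult:
    """3x3 benchmark-by-predicted confusion with per-class correct counts."""

    drug_names: list
    predicted_class: list
    benchmark_class: list
    confusion: np.ndarray
    correct_by_class: dict
    total_correct: int

    def to_dict(self) -> dict:
        return {
            "correct_by_class": dict(self.correct_by_class),
            "total_correct": int(self.total_correct),
            "confusion": {
                bc: {
                    pc: int(self.confusion[i, j])
                    for j, pc in enumerate(BENCHMARK_CLASSES)
                }
                for i, bc in enumerate(BENCHMARK_CLASSES)
            },
        }


@dataclass
class ROCResult:
    """ROC points on a threshold grid plus the rank-statistic AUC."""

    positives_definition: str
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "one_minus_specificity": self.one_minus_specificity,
            }
        )


def reclassify(estimates, cutoffs=DEFAULT_CUTOFFS) -> list:
    """Map log-OR estimates to the three risk classes via fixed cutoffs."""
    lo, hi = cutoffs
    estimates = np.asarray(estimates, dtype=float)
    if not np.all(np.isfinite(estimates)):
        raise ValueError("estimates must be finite (cap diverged values first)")
    out = []
    for b in estimates:
        if b > hi:
            out.append("highly_suspected")
        elif b > lo:
            out.append("suspected")
        else:
            out.append("other")
    return out


def score_classification(
    predicted, benchmark: DrugBenchmark, drug_names=None
) -> ClassificationResult:
    """Count per-class and total agreement with the benchmark classes."""
    if drug_names is None:
        drug_names = list(benchmark.drug_names)
    truth = benchmark.classes_for(drug_names)
    predicted = list(predicted)
    if len(predicted) != len(drug_names):
        raise ValueError("predicted classes and drug list have different lengths")
    bad = set(predicted) - set(BENCHMARK_CLASSES)
    if bad:
        raise ValueError(f"invalid predicted class(es): {sorted(bad)}")
    idx = {c: i for i, c in enumerate(BENCHMARK_CLASSES)}
    confusion = np.zeros((3, 3), dtype=np.int64)
    for t, q in zip(truth, predicted):
        confusion[idx[t], idx[q]] += 1
    correct = {c: int(confusion[i, i]) for c, i in idx.items()}
    return ClassificationResult(
        drug_names=list(drug_names),
        predicted_class=predicted,
        benchmark_class=truth,
        confusion=confusion,
        correct_by_class=correct,
        total_correct=int(np.trace(confusion)),
    )


def _binarize(benchmark: DrugBenchmark, drug_names, positives_definition: str):
    truth = benchmark.classes_for(drug_names)
    if positives_definition == "highly_only":
        pos = {"highly_suspected"}
    elif positives_definition == "highly_or_suspected":
        pos = {"highly_suspected", "suspected"}
    else:
        raise ValueError(
            "positives_definition must be 'highly_only' or 'highly_or_suspected'"
        )
    return np.array([t in pos for t in truth], dtype=bool)


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # average ranks handle ties
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_curve(
    estimates,
    benchmark: DrugBenchmark,
    positives_definition: str = "highly_only",
    thresholds=None,
    drug_names=None,
) -> ROCResult:
    """ROC over a threshold grid (default 0..4) with the rank AUC.

    A drug is called positive at threshold t when its estimate exceeds t.
    The AUC is computed from ranks over all estimates and is independent
    of the display grid.
    """
    estimates = np.asarray(estimates, dtype=float)
    if drug_names is None:
        drug_names = list(benchmark.drug_names)
    labels = _binarize(benchmark, drug_names, positives_definition)
    if thresholds is None:
        thresholds = np.linspace(0.0, 4.0, 41)
    thresholds = np.asarray(thresholds, dtype=float)
    calls = estimates[None, :] > thresholds[:, None]
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    sens = (calls & labels[None, :]).sum(axis=1) / n_pos
    fpr = (calls & ~labels[None, :]).sum(axis=1) / n_neg
    return ROCResult(
        positives_definition=positives_definition,
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=rank_auc(estimates, labels),
    )


def subsample_auc_sensitivity(
    data: CaseCrossoverDataset,
    benchmark: DrugBenchmark,
    fitter,
    n_subsamples: int = 100,
    fraction: float = 0.75,
    seed: int = 0,
) -> dict:
    """Stability of both AUCs under repeated subsampling of the pairs.

    ``fitter(dataset, seed) -> length-p estimate vector`` is refit on each
    subsample of floor(fraction * N) subjects; returns the per-subsample
    AUCs plus median/IQR summaries.
    """
    rng = np.random.default_rng(seed)
    n = data.n_subjects
    m = int(np.floor(fraction * n))
    if m < 1:
        raise ValueError("subsample size must be >= 1")
    auc_high = np.empty(n_subsamples)
    auc_high_susp = np.empty(n_subsamples)
    for s in range(n_subsamples):
        idx = (
            np.arange(n)
            if m == n
            else np.sort(rng.choice(n, size=m, replace=False))
        )
        sub = data.subset_subjects(idx)
        est = np.asarray(fitter(sub, int(rng.integers(0, 2**31 - 1))), dtype=float)
        auc_high[s] = rank_auc(
            est, _binarize(benchmark, sub.drug_names, "highly_only")
        )
        auc_high_susp[s] = rank_auc(
            est, _binarize(benchmark, sub.drug_names, "highly_or_suspected")
        )
    def summarize(a):
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        return {"median": float(med), "iqr": float(q3 - q1), "values": a.tolist()}

    return {
        "highly_only": summarize(auc_high),
        "highly_or_suspected": summarize(auc_high_susp),
    }
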