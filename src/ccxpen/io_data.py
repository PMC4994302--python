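"""Matched-pair exposure data: containers, I/O, filters and diagnostics.

A case-crossover study records, for each subject, binary exposure to each
of ``p`` drugs during two windows: the *case period* (just before the
event) and the *reference period* (an earlier comparison window).  The two
windows form a 1:1 matched pair within the subject, so the data are two
aligned N x p 0/1 matrices.

Two CSV dialects are supported.  The canonical *wide* dialect has one row
per subject and two columns per drug (``<drug>__case``, ``<drug>__ref``),
which makes the pair matching structural.  A *long* dialect
(``subject_id,period,drug,exposed``) is accepted for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BENCHMARK_CLASSES = ("highly_suspected", "suspected", "other")


class DataValidationError(ValueError):
    """Raised when an input table violates the matched-pair contract."""


@dataclass
class CaseCrossoverDataset:
    """Binary exposure matrices for N matched case/reference pairs.

    ``case_exposure[n, j]`` is subject ``n``'s exposure to drug ``j``
    during the case period; ``ref_exposure`` the same for the reference
    period.  Entries are strictly 0/1.
    """

    subject_ids: list
    drug_names: list
    case_exposure: np.ndarray
    ref_exposure: np.ndarray

    def __post_init__(self) -> None:
        self.case_exposure = np.asarray(self.case_exposure, dtype=np.int8)
        self.ref_exposure = np.asarray(self.ref_exposure, dtype=np.int8)
        self.subject_ids = list(self.subject_ids)
        self.drug_names = list(self.drug_names)
        n, p = self.case_exposure.shape
        if self.ref_exposure.shape != (n, p):
            raise DataValidationError(
                f"case/ref shape mismatch: {self.case_exposure.shape} vs "
                f"{self.ref_exposure.shape}"
            )
        if n < 1 or p < 1:
            raise DataValidationError("dataset must have N >= 1 and p >= 1")
        if len(self.subject_ids) != n:
            raise DataValidationError("subject_ids length != N")
        if len(self.drug_names) != p:
            raise DataValidationError("drug_names length != p")
        if len(set(self.subject_ids)) != n:
            raise DataValidationError("duplicate subject IDs")
        if len(set(self.drug_names)) != p:
            raise DataValidationError("duplicate drug names")
        for name, mat in (("case", self.case_exposure), ("ref", self.ref_exposure)):
            bad = ~np.isin(mat, (0, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise DataValidationError(
                    f"non-binary {name} exposure for subject "
                    f"{self.subject_ids[i]!r}, drug {self.drug_names[j]!r}"
                )

    @property
    def n_subjects(self) -> int:
        return self.case_exposure.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.case_exposure.shape[1]

    def exposure_difference(self) -> np.ndarray:
        """N x p matrix of x_case - x_ref, entries in {-1, 0, 1}.

        The conditional likelihood of a matched pair depends on the
        exposures only through this difference.
        """
        return (self.case_exposure.astype(np.int64)
                - self.ref_exposure.astype(np.int64))

    def subset_subjects(self, index: Sequence[int]) -> "CaseCrossoverDataset":
        """Dataset restricted to the given subject row indices.

        Repeated indices are allowed (bootstrap resampling); repeated
        subjects get suffixed IDs so uniqueness still holds.
        """
        index = np.asarray(index, dtype=np.intp)
        ids: list = []
        seen: dict = {}
        for i in index:
            sid = self.subject_ids[i]
            k = seen.get(sid, 0)
            seen[sid] = k + 1
            ids.append(sid if k == 0 else f"{sid}#{k}")
        return CaseCrossoverDataset(
            subject_ids=ids,
            drug_names=self.drug_names,
            case_exposure=self.case_exposure[index],
            ref_exposure=self.ref_exposure[index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CaseCrossoverDataset):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.drug_names == other.drug_names
            and np.array_equal(self.case_exposure, other.case_exposure)
            and np.array_equal(self.ref_exposure, other.ref_exposure)
        )


@dataclass
class DrugBenchmark:
    """Per-drug benchmark risk class, optionally with a benchmark log OR.

    The three admissible classes are ``highly_suspected``, ``suspected``
    and ``other``, mirroring the external (case-control) classification
    the case-crossover estimates are compared against.
    """

    drug_names: list
    benchmark_class: list
    benchmark_log_or: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.drug_names = list(self.drug_names)
        self.benchmark_class = list(self.benchmark_class)
        if len(self.drug_names) != len(self.benchmark_class):
            raise DataValidationError("drug_names and benchmark_class lengths differ")
        if len(set(self.drug_names)) != len(self.drug_names):
            raise DataValidationError("duplicate drug names in benchmark")
        bad = set(self.benchmark_class) - set(BENCHMARK_CLASSES)
        if bad:
            raise DataValidationError(f"invalid benchmark class(es): {sorted(bad)}")
        if self.benchmark_log_or is not None:
            self.benchmark_log_or = np.asarray(self.benchmark_log_or, dtype=float)
            if self.benchmark_log_or.shape != (len(self.drug_names),):
                raise DataValidationError("benchmark_log_or length != p")

    def classes_for(self, drug_names: Sequence[str]) -> list:
        """Benchmark classes aligned to the given drug order."""
        lookup = dict(zip(self.drug_names, self.benchmark_class))
        missing = [d for d in drug_names if d not in lookup]
        if missing:
            raise DataValidationError(f"drugs missing from benchmark: {missing}")
        return [lookup[d] for d in drug_names]


@dataclass
class DiscordanceSummary:
    """Per-drug 2x2 classification of the N matched pairs.

    n10 counts pairs exposed in the case period only, n01 in the reference
    period only; n11/n00 are the concordant counts.  Only discordant pairs
    carry information in the conditional likelihood, so
    ``min_discordance = min(n10, n01)`` is the key sparsity diagnostic.
    """

    drug_names: list
    n10: np.ndarray
    n01: np.ndarray
    n11: np.ndarray
    n00: np.ndarray
    min_discordance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("n10", "n01", "n11", "n00"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.min_discordance = np.minimum(self.n10, self.n01)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug_names,
                "n10": self.n10,
                "n01": self.n01,
                "n11": self.n11,
                "n00": self.n00,
                "min_discordance": self.min_discordance,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O


def _wide_columns(drug_names: Sequence[str]) -> list:
    cols = ["subject_id"]
    for d in drug_names:
        cols += [f"{d}__case", f"{d}__ref"]
    return cols


def save_dataset(data: CaseCrossoverDataset, path, format: str = "wide") -> None:
    """Write a dataset as CSV in the wide or long dialect."""
    path = Path(path)
    if format == "wide":
        frame = pd.DataFrame({"subject_id": data.subject_ids})
        for j, d in enumerate(data.drug_names):
            frame[f"{d}__case"] = data.case_exposure[:, j]
            frame[f"{d}__ref"] = data.ref_exposure[:, j]
        frame.to_csv(path, index=False)
    elif format == "long":
        rows = []
        for i, sid in enumerate(data.subject_ids):
            for j, d in enumerate(data.drug_names):
                rows.append((sid, "case", d, int(data.case_exposure[i, j])))
                rows.append((sid, "ref", d, int(data.ref_exposure[i, j])))
        pd.DataFrame(rows, columns=["subject_id", "period", "drug", "exposed"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_dataset(path, format: str = "wide") -> CaseCrossoverDataset:
    """Read a dataset CSV in the declared dialect and validate it."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if format == "wide":
        return _load_wide(frame)
    if format == "long":
        return _load_long(frame)
    raise ValueError(f"unknown format {format!r}")


def _parse_binary(values: pd.Series, what: str) -> np.ndarray:
    stripped = values.str.strip()
    bad = ~stripped.isin(["0", "1"])
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise DataValidationError(
            f"non-binary exposure value {values.iloc[i]!r} in {what}, row {i}"
        )
    return stripped.astype(np.int8).to_numpy()


def _load_wide(frame: pd.DataFrame) -> CaseCrossoverDataset:
    if "subject_id" not in frame.columns:
        raise DataValidationError("wide CSV must have a 'subject_id' column")
    drug_names: list = []
    for col in frame.columns:
        if col == "subject_id":
            continue
        if col.endswith("__case"):
            drug_names.append(col[: -len("__case")])
        elif col.endswith("__ref"):
            continue
        else:
            raise DataValidationError(
                f"malformed header: column {col!r} is neither <drug>__case "
                "nor <drug>__ref"
            )
    for d in drug_names:
        if f"{d}__ref" not in frame.columns:
            raise DataValidationError(f"malformed header: missing column '{d}__ref'")
    case = np.column_stack(
        [_parse_binary(frame[f"{d}__case"], f"column {d}__case") for d in drug_names]
    )
    ref = np.column_stack(
        [_parse_binary(frame[f"{d}__ref"], f"column {d}__ref") for d in drug_names]
    )
    return CaseCrossoverDataset(
        subject_ids=frame["subject_id"].tolist(),
        drug_names=drug_names,
        case_exposure=case,
        ref_exposure=ref,
    )


def _load_long(frame: pd.DataFrame) -> CaseCrossoverDataset:
    required = {"subject_id", "period", "drug", "exposed"}
    missing = required - set(frame.columns)
    if missing:
        raise DataValidationError(f"malformed header: missing column(s) {sorted(missing)}")
    bad_period = ~frame["period"].isin(["case", "ref"])
    if bad_period.any():
        val = frame.loc[bad_period, "period"].iloc[0]
        raise DataValidationError(f"invalid period value {val!r} (must be case/ref)")
    exposed = _parse_binary(frame["exposed"], "column exposed")
    # preserve first-appearance order of subjects and drugs
    subject_ids = list(dict.fromkeys(frame["subject_id"]))
    drug_names = list(dict.fromkeys(frame["drug"]))
    sidx = {s: i for i, s in enumerate(subject_ids)}
    didx = {d: j for j, d in enumerate(drug_names)}
    n, p = len(subject_ids), len(drug_names)
    case = np.zeros((n, p), dtype=np.int8)
    ref = np.zeros((n, p), dtype=np.int8)
    filled = {"case": np.zeros((n, p), dtype=bool), "ref": np.zeros((n, p), dtype=bool)}
    for (sid, period, drug), value in zip(
        frame[["subject_id", "period", "drug"]].itertuples(index=False), exposed
    ):
        i, j = sidx[sid], didx[drug]
        if filled[period][i, j]:
            raise DataValidationError(
                f"duplicate record for subject {sid!r}, drug {drug!r}, period {period}"
            )
        filled[period][i, j] = True
        (case if period == "case" else ref)[i, j] = value
    for period, mask in filled.items():
        if not mask.all():
            i, j = np.argwhere(~mask)[0]
            raise DataValidationError(
                f"missing {period}-period record for subject "
                f"{subject_ids[i]!r}, drug {drug_names[j]!r}"
            )
    return CaseCrossoverDataset(subject_ids, drug_names, case, ref)


def load_benchmark(path) -> DrugBenchmark:
    """Read a benchmark CSV with columns ``drug,class[,log_or]``."""
    frame = pd.read_csv(path, dtype={"drug": str, "class": str})
    if "drug" not in frame.columns or "class" not in frame.columns:
        raise DataValidationError("benchmark CSV must have 'drug' and 'class' columns")
    log_or = None
    if "log_or" in frame.columns and frame["log_or"].notna().any():
        log_or = frame["log_or"].to_numpy(dtype=float)
    return DrugBenchmark(
        drug_names=frame["drug"].tolist(),
        benchmark_class=frame["class"].tolist(),
        benchmark_log_or=log_or,
    )


def save_benchmark(benchmark: DrugBenchmark, path) -> None:
    frame = pd.DataFrame({"drug": benchmark.drug_names, "class": benchmark.benchmark_class})
    if benchmark.benchmark_log_or is not None:
        frame["log_or"] = benchmark.benchmark_log_or
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters and diagnostics


def apply_exclusion_filter(
    data: CaseCrossoverDataset,
) -> tuple[CaseCrossoverDataset, list]:
    """Drop subjects with no exposure to any drug in either period.

    Such subjects contribute a constant to the conditional likelihood and
    carry no information.  Returns the filtered dataset (original subject
    order preserved) and the list of excluded subject IDs.
    """
    any_exposure = (data.case_exposure.any(axis=1)) | (data.ref_exposure.any(axis=1))
    keep = np.flatnonzero(any_exposure)
    excluded = [data.subject_ids[i] for i in np.flatnonzero(~any_exposure)]
    if len(keep) == data.n_subjects:
        return data, []
    if len(keep) == 0:
        raise DataValidationError("all subjects excluded: no exposures anywhere")
    return data.subset_subjects(keep), excluded


def count_discordances(data: CaseCrossoverDataset) -> DiscordanceSummary:
    """Classify every (subject, drug) pair into the 2x2 discordance table."""
    case = data.case_exposure.astype(bool)
    ref = data.ref_exposure.astype(bool)
    return DiscordanceSummary(
        drug_names=data.drug_names,
        n10=(case & ~ref).sum(axis=0),
        n01=(~case & ref).sum(axis=0),
        n11=(case & ref).sum(axis=0),
        n00=(~case & ~ref).sum(axis=0),
    )


def pairwise_correlations(data: CaseCrossoverDataset, period: str = "case") -> np.ndarray:
    """Pearson correlations between drug columns within one period.

    For 0/1 columns Pearson and Spearman coincide.  Constant columns have
    an undefined correlation; those entries are NaN (the diagonal is kept
    at 1).
    """
    if period == "case":
        mat = data.case_exposure.astype(float)
    elif period == "ref":
        mat = data.ref_exposure.astype(float)
    else:
        raise ValueError(f"period must be 'case' or 'ref', got {period!r}")
    p = mat.shape[1]
    sd = mat.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr
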