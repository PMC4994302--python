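"""End-to-end method comparison: fit every estimator, reclassify, score.

Given a matched-pair dataset and a per-drug benchmark classification, run
a configurable set of estimators (univariable / multivariable CLR, lasso,
elastic net, bolasso, sublasso, random lasso, Firth), map each estimate
vector to the three risk classes, and emit a per-class correct-count
table and the two discrimination AUCs per method, plus per-method fit
files and a machine-readable report.

Seeding: one master seed in the config; each stage derives its own seed
from a stable hash of the stage name so stages can be re-run
independently yet reproducibly.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np

from . import __version__
from .clr_core import fit_clr
from .ensembles import bolasso, random_lasso, sublasso
from .evaluation import (
    DEFAULT_CUTOFFS,
    reclassify,
    roc_curve,
    score_classification,
)
from .firth import fit_firth
from .io_data import (
    CaseCrossoverDataset,
    DrugBenchmark,
    apply_exclusion_filter,
    count_discordances,
    load_benchmark,
    load_dataset,
    pairwise_correlations,
)
from .penalized import cv_elastic_net, cv_lasso
from .synthetic_data import euroscar_like_spec, simulate_dataset, spec_from_dict

log = logging.getLogger("ccxpen")

METHOD_NAMES = (
    "clr-uni",
    "clr-multi",
    "lasso",
    "enet",
    "bolasso",
    "sublasso",
    "randomlasso",
    "firth",
)

#: methods whose fits are per-drug rather than jointly adjusted
PER_DRUG_METHODS = ("clr-uni",)


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _fit_method(name, data, seed, settings):
    """Dispatch one estimator; returns (estimates, extra-metadata dict)."""
    K = settings.get("folds", 10)
    B = settings.get("resamples", 1000)
    threshold = settings.get("threshold", 0.75)
    n_lambda = settings.get("n_lambda", 100)
    if name == "clr-uni":
        fit = fit_clr(data, mode="univariable")
        return fit.coefficients, {"separated": fit.separation_flags.tolist()}
    if name == "clr-multi":
        fit = fit_clr(data, mode="multivariable")
        return fit.coefficients, {"separated": fit.separation_flags.tolist()}
    if name == "lasso":
        _, fit = cv_lasso(data, K=K, seed=seed, n_lambda=n_lambda)
        return fit.coefficients, {"tuning": fit.tuning}
    if name == "enet":
        _, fit = cv_elastic_net(
            data, K=K, seed=seed, n_lambda=n_lambda,
            lambda2_grid=settings.get("lambda2_grid", (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)),
        )
        return fit.coefficients, {"tuning": fit.tuning}
    if name == "bolasso":
        res = bolasso(data, B=B, threshold=threshold, K=K, seed=seed,
                      n_lambda=n_lambda)
        return res.final_estimate, {"selection_frequency": res.selection_frequency.tolist()}
    if name == "sublasso":
        res = sublasso(data, B=B, threshold=threshold, K=K, seed=seed,
                       n_lambda=n_lambda)
        return res.final_estimate, {"selection_frequency": res.selection_frequency.tolist()}
    if name == "randomlasso":
        res = random_lasso(
            data, B=B, threshold=threshold, K=K, seed=seed, n_lambda=n_lambda,
            q_candidates=settings.get("q_candidates", (15, 20, 25, 30)),
            q_select_resamples=settings.get("q_select_resamples"),
        )
        return res.final_estimate, {
            "selection_frequency": res.selection_frequency.tolist(),
            "q1": res.tuning["q1"], "q2": res.tuning["q2"],
        }
    if name == "firth":
        fit = fit_firth(data)
        return fit.coefficients, {"dropped": fit.tuning.get("dropped_drugs", [])}
    raise ValueError(f"unknown method {name!r}")


def _load_inputs(config):
    data_cfg = config["data"]
    if "path" in data_cfg:
        data = load_dataset(data_cfg["path"], format=data_cfg.get("format", "wide"))
    elif "spec" in data_cfg:
        spec_cfg = data_cfg["spec"]
        if spec_cfg == "euroscar_like":
            spec = euroscar_like_spec(seed=derive_seed(config.get("seed", 0), "simulate"))
        else:
            spec = spec_from_dict(spec_cfg)
        data, sim_benchmark = simulate_dataset(spec)
    else:
        raise ValueError("config['data'] must name a 'path' or a 'spec'")
    bench_cfg = config.get("benchmark")
    if bench_cfg is None:
        if "spec" not in data_cfg:
            raise ValueError("a benchmark file is required for file-based data")
        benchmark = sim_benchmark
    elif isinstance(bench_cfg, (str, Path)):
        benchmark = load_benchmark(bench_cfg)
    elif isinstance(bench_cfg, DrugBenchmark):
        benchmark = bench_cfg
    else:
        raise ValueError("config['benchmark'] must be a path or DrugBenchmark")
    return data, benchmark


def run_comparison(config: dict, data=None, benchmark=None) -> dict:
    """Run the full method comparison described by ``config``.

    ``data``/``benchmark`` may be passed directly (bypassing the config's
    data source).  Returns the report dict; when ``config['outdir']`` is
    set, also writes per-method fit TSVs, ``report.json``, table analogues
    and a MANIFEST.
    """
    methods = list(config.get("methods", METHOD_NAMES))
    unknown = [m for m in methods if m not in METHOD_NAMES]
    if unknown:
        raise ValueError(f"unknown method name(s): {unknown}")
    cutoffs = tuple(config.get("cutoffs", DEFAULT_CUTOFFS))
    master_seed = int(config.get("seed", 0))
    if config.get("fast"):
        config = {**config, "resamples": min(config.get("resamples", 100), 100),
                  "folds": min(config.get("folds", 5), 5)}

    if data is None or benchmark is None:
        loaded_data, loaded_bench = _load_inputs(config)
        data = data if data is not None else loaded_data
        benchmark = benchmark if benchmark is not None else loaded_bench

    outdir = Path(config["outdir"]) if "outdir" in config else None
    manifest: list = []
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)

    try:
        data, excluded = apply_exclusion_filter(data)
        disc = count_discordances(data)
        corr_case = pairwise_correlations(data, "case")
        corr_ref = pairwise_correlations(data, "ref")

        def max_offdiag(c):
            c = c.copy()
            np.fill_diagonal(c, np.nan)
            return float(np.nanmax(np.abs(c))) if np.isfinite(c).any() else float("nan")

        report = {
            "version": __version__,
            "seed": master_seed,
            "n_subjects": data.n_subjects,
            "n_drugs": data.n_drugs,
            "n_excluded": len(excluded),
            "excluded_ids": excluded,
            "cutoffs": list(cutoffs),
            "max_abs_correlation": {
                "case": max_offdiag(corr_case),
                "ref": max_offdiag(corr_ref),
            },
            "methods": {},
        }
        if outdir is not None:
            disc.to_tsv(outdir / "discordances.tsv")
            manifest.append("discordances.tsv")

        for name in methods:
            stage_seed = derive_seed(master_seed, name)
            log.info("fitting %s (seed %d)", name, stage_seed)
            try:
                estimates, meta = _fit_method(name, data, stage_seed, config)
            except Exception:
                log.exception("stage %r failed", name)
                raise RuntimeError(f"stage {name!r} failed") from None
            predicted = reclassify(estimates, cutoffs)
            scored = score_classification(predicted, benchmark, data.drug_names)
            roc_high = roc_curve(estimates, benchmark, "highly_only",
                                 drug_names=data.drug_names)
            roc_hs = roc_curve(estimates, benchmark, "highly_or_suspected",
                               drug_names=data.drug_names)
            entry = {
                "estimates": dict(zip(data.drug_names, map(float, estimates))),
                "classification": scored.to_dict(),
                "auc_highly_only": roc_high.auc,
                "auc_highly_or_suspected": roc_hs.auc,
                "seed": stage_seed,
                "per_drug_fits": name in PER_DRUG_METHODS,
                **meta,
            }
            report["methods"][name] = entry
            if outdir is not None:
                import pandas as pd

                frame = pd.DataFrame(
                    {
                        "drug": data.drug_names,
                        "log_or": np.asarray(estimates, dtype=float),
                        "or": np.exp(np.asarray(estimates, dtype=float)),
                        "predicted_class": predicted,
                    }
                )
                frame.to_csv(outdir / f"fit_{name}.tsv", sep="\t", index=False)
                manifest.append(f"fit_{name}.tsv")

        if outdir is not None:
            import pandas as pd

            rows = []
            for name in methods:
                c = report["methods"][name]["classification"]["correct_by_class"]
                rows.append(
                    (name, c["highly_suspected"], c["suspected"], c["other"],
                     report["methods"][name]["classification"]["total_correct"])
                )
            pd.DataFrame(
                rows, columns=["method", "highly_suspected", "suspected", "other", "total"]
            ).to_csv(outdir / "table_classification.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    (name,
                     report["methods"][name]["auc_highly_only"],
                     report["methods"][name]["auc_highly_or_suspected"])
                    for name in methods
                ],
                columns=["method", "auc_highly_only", "auc_highly_or_suspected"],
            ).to_csv(outdir / "table_auc.tsv", sep="\t", index=False)
            manifest += ["table_classification.tsv", "table_auc.tsv"]
            (outdir / "report.json").write_text(json.dumps(report, indent=2))
            manifest.append("report.json")
            (outdir / "MANIFEST").write_text(
                "\n".join(["complete"] + manifest) + "\n"
            )
        return report
    except Exception:
        if outdir is not None:
            (outdir / "MANIFEST").write_text(
                "\n".join(["incomplete"] + manifest) + "\n"
            )
        raise
    finally:
        if outdir is not None:
            log.removeHandler(handler)
            handler.close()
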