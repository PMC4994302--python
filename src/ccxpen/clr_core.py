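"""Conditional logistic likelihood for 1:1 matched pairs, and its MLE.

For a matched pair with case-period exposures x1 and reference-period
exposures x0, the conditional likelihood contribution is

    l_n(beta) = <beta, x1> - log(exp(<beta, x1>) + exp(<beta, x0>))
              = log sigmoid(<beta, z_n>),        z_n = x1 - x0.

Pairs concordant in every drug (z_n = 0) contribute the constant -log 2,
so all information lives in the discordant entries of z.  There is no
intercept: conditioning on the pair removes it.

Fitting is Newton-Raphson with step-halving.  Separation (monotone
likelihood, e.g. a drug exposed in case periods only) makes the MLE
infinite; estimates are capped at |beta| = 15 and flagged rather than
failed, since a capped value is still classifiable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_data import CaseCrossoverDataset

#: coefficients beyond this magnitude are treated as diverged (separation)
DIVERGENCE_BOUND = 15.0
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
MAX_ITER = 50


@dataclass
class ModelFit:
    """Per-method estimate vector with convergence diagnostics."""

    method: str
    drug_names: list
    coefficients: np.ndarray
    converged: bool
    n_iterations: int
    separation_flags: np.ndarray
    loglik_at_solution: float
    tuning: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.separation_flags = np.asarray(self.separation_flags, dtype=bool)
        if self.coefficients.shape != (len(self.drug_names),):
            raise ValueError("coefficient length != number of drugs")
        if self.separation_flags.shape != self.coefficients.shape:
            raise ValueError("separation_flags length != number of drugs")

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "drug": self.drug_names,
                "log_or": self.coefficients,
                "or": self.odds_ratios,
                "separated": self.separation_flags.astype(int),
            }
        )


def _as_diff(data) -> np.ndarray:
    if isinstance(data, CaseCrossoverDataset):
        return data.exposure_difference().astype(float)
    return np.asarray(data, dtype=float)


def _check_dim(beta: np.ndarray, z: np.ndarray) -> None:
    if beta.shape != (z.shape[1],):
        raise ValueError(f"beta has length {beta.shape}, expected ({z.shape[1]},)")


def cond_loglik(beta, data) -> float:
    """Conditional log-likelihood sum_n log sigmoid(<beta, z_n>).

    Overflow-safe via log1p/exp in the stable orientation.
    """
    z = _as_diff(data)
    beta = np.asarray(beta, dtype=float)
    _check_dim(beta, z)
    eta = z @ beta
    return float(-np.logaddexp(0.0, -eta).sum())


def cond_score(beta, data) -> np.ndarray:
    """Gradient of the conditional log-likelihood: sum_n z_n * sigmoid(-eta_n)."""
    z = _as_diff(data)
    beta = np.asarray(beta, dtype=float)
    _check_dim(beta, z)
    eta = z @ beta
    return z.T @ expit(-eta)


def cond_info(beta, data) -> np.ndarray:
    """Observed information -d^2 l / d beta^2 = Z' diag(w) Z, w = mu(1-mu)."""
    z = _as_diff(data)
    beta = np.asarray(beta, dtype=float)
    _check_dim(beta, z)
    eta = z @ beta
    w = expit(eta) * expit(-eta)
    return (z * w[:, None]).T @ z


def _newton(z: np.ndarray, beta0: np.ndarray | None = None):
    """Newton-Raphson with step-halving on the conditional log-likelihood.

    Returns (beta, converged, n_iter, separation_flags).  Coefficients are
    clipped to the divergence bound; a coordinate pinned at the bound with
    its score still pushing outward is flagged as separated.  Drugs with no
    discordant pair have constant likelihood and stay at zero, unflagged.
    """
    n, p = z.shape
    informative = np.abs(z).sum(axis=0) > 0
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = cond_loglik(beta, z)
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        score = cond_score(beta, z)
        info = cond_info(beta, z)
        # restrict the solve to informative coordinates; pad a singular
        # information matrix with a tiny ridge so steps stay defined
        idx = np.flatnonzero(informative)
        sub_info = info[np.ix_(idx, idx)]
        sub_info = sub_info + 1e-12 * np.eye(len(idx))
        try:
            step_sub = np.linalg.solve(sub_info, score[idx])
        except np.linalg.LinAlgError:
            step_sub = np.linalg.lstsq(sub_info, score[idx], rcond=None)[0]
        step = np.zeros(p)
        step[idx] = step_sub
        # step-halving on the likelihood
        scale = 1.0
        for _ in range(30):
            cand = np.clip(beta + scale * step, -DIVERGENCE_BOUND, DIVERGENCE_BOUND)
            ll_cand = cond_loglik(cand, z)
            if ll_cand >= ll - 1e-14:
                break
            scale *= 0.5
        delta = cand - beta
        beta, ll = cand, ll_cand
        score = cond_score(beta, z)
        at_cap = np.abs(beta) >= DIVERGENCE_BOUND - 1e-9
        active = informative & ~at_cap
        if (np.abs(score[active]).max(initial=0.0) < SCORE_TOL
                or np.abs(delta).max(initial=0.0) < STEP_TOL):
            break
    score = cond_score(beta, z)
    at_cap = np.abs(beta) >= DIVERGENCE_BOUND - 1e-9
    separated = at_cap & (score * np.sign(beta) > -SCORE_TOL)
    active = informative & ~separated
    converged = bool(np.abs(score[active]).max(initial=0.0) < 1e-6 and not separated.any())
    return beta, converged, n_iter, separated


def fit_clr(data: CaseCrossoverDataset, mode: str = "multivariable") -> ModelFit:
    """Unpenalized conditional-logistic maximum likelihood.

    ``multivariable`` fits all drugs jointly; ``univariable`` fits one
    single-drug model per drug and assembles the estimates into one vector
    (each drug's estimate then has the closed form log(n10/n01) whenever
    both discordance counts are positive).
    """
    z = data.exposure_difference().astype(float)
    p = z.shape[1]
    if mode == "multivariable":
        beta, converged, n_iter, separated = _newton(z)
        ll = cond_loglik(beta, z)
        return ModelFit(
            method="clr-multi",
            drug_names=list(data.drug_names),
            coefficients=beta,
            converged=converged,
            n_iterations=n_iter,
            separation_flags=separated,
            loglik_at_solution=ll,
        )
    if mode == "univariable":
        beta = np.zeros(p)
        separated = np.zeros(p, dtype=bool)
        converged = True
        total_iter = 0
        for j in range(p):
            bj, cj, it, sj = _newton(z[:, [j]])
            beta[j] = bj[0]
            separated[j] = sj[0]
            converged &= cj
            total_iter = max(total_iter, it)
        ll = float(sum(cond_loglik(beta[[j]], z[:, [j]]) for j in range(p)))
        return ModelFit(
            method="clr-uni",
            drug_names=list(data.drug_names),
            coefficients=beta,
            converged=converged,
            n_iterations=total_iter,
            separation_flags=separated,
            loglik_at_solution=ll,
        )
    raise ValueError(f"mode must be 'univariable' or 'multivariable', got {mode!r}")
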