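"""Firth bias-reduced conditional logistic regression.

Maximizes the penalized log-likelihood

    l*(beta) = l(beta) + 1/2 * log det I(beta),

where I is the observed information of the matched-pair conditional
likelihood.  The Jeffreys-prior penalty keeps estimates finite under
separation: in the univariable case the solution has the closed form
log((n10 + 1/2) / (n01 + 1/2)), the classic 1/2-count correction of the
discordant-pair odds ratio.

The modified score has the standard hat-value form

    U*_j(beta) = sum_n z_nj * (1 - mu_n + h_n (1/2 - mu_n)),

with mu_n = sigmoid(eta_n), w_n = mu_n (1 - mu_n) and hat value
h_n = w_n z_n' I^{-1} z_n.  Iteration is Newton-type steps on U* with
step-halving on l*.

Drugs with no discordant pair make I singular and carry no likelihood
information; they are excluded from the design and reported with estimate
0 and a flag, so the penalty alone never manufactures an estimate.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .clr_core import ModelFit, cond_loglik
from .io_data import CaseCrossoverDataset

MAX_ITER = 100
SCORE_TOL = 1e-6


def _as_diff(data) -> np.ndarray:
    if isinstance(data, CaseCrossoverDataset):
        return data.exposure_difference().astype(float)
    return np.asarray(data, dtype=float)


def firth_loglik(beta, data) -> float:
    """l(beta) + 1/2 log det I(beta) on the informative design."""
    z = _as_diff(data)
    beta = np.asarray(beta, dtype=float)
    eta = z @ beta
    w = expit(eta) * expit(-eta)
    info = (z * w[:, None]).T @ z
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return cond_loglik(beta, z) + 0.5 * logdet


def _modified_score_and_info(beta: np.ndarray, z: np.ndarray):
    eta = z @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (z * w[:, None]).T @ z
    try:
        zi = np.linalg.solve(info, z.T)  # p x n
    except np.linalg.LinAlgError:
        zi = np.linalg.pinv(info) @ z.T
    hat = w * np.einsum("np,pn->n", z, zi)
    score = z.T @ ((1.0 - mu) + hat * (0.5 - mu))
    return score, info


def fit_firth(data: CaseCrossoverDataset) -> ModelFit:
    """Multivariable Firth-penalized conditional logistic fit."""
    z_full = _as_diff(data)
    p = z_full.shape[1]
    informative = np.abs(z_full).sum(axis=0) > 0
    # exactly collinear difference columns (e.g. two drugs discordant in
    # the same single subject) make I singular for every beta; keep a
    # maximal independent subset via pivoted QR and flag the rest
    if informative.any():
        idx = np.flatnonzero(informative)
        from scipy.linalg import qr

        r = qr(z_full[:, idx], mode="r", pivoting=True)
        rmat, piv = r[0], r[1]
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * 1e-10 if diag.size else 0.0
        rank = int((diag > tol).sum())
        keep = np.zeros(p, dtype=bool)
        keep[idx[piv[:rank]]] = True
        informative = keep
    z = z_full[:, informative]
    beta_sub = np.zeros(z.shape[1])
    converged = False
    n_iter = 0
    if z.shape[1] > 0:
        ll = firth_loglik(beta_sub, z)
        for n_iter in range(1, MAX_ITER + 1):
            score, info = _modified_score_and_info(beta_sub, z)
            if np.abs(score).max() < SCORE_TOL:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
            # guard the first iterations against wild steps
            norm = np.abs(step).max()
            if norm > 5.0:
                step *= 5.0 / norm
            scale = 1.0
            for _ in range(30):
                cand = beta_sub + scale * step
                ll_cand = firth_loglik(cand, z)
                if ll_cand > ll - 1e-14:
                    break
                scale *= 0.5
            beta_sub, ll = cand, ll_cand
        else:
            n_iter = MAX_ITER
        score, _ = _modified_score_and_info(beta_sub, z)
        converged = bool(np.abs(score).max() < SCORE_TOL)
    else:
        converged = True

    beta = np.zeros(p)
    beta[informative] = beta_sub
    flags = ~informative  # dropped-from-design marker, not separation
    if not informative.any():
        flags = np.ones(p, dtype=bool)
    return ModelFit(
        method="firth",
        drug_names=list(data.drug_names),
        coefficients=beta,
        converged=converged,
        n_iterations=n_iter,
        separation_flags=flags,
        loglik_at_solution=cond_loglik(beta, z_full),
        tuning={"dropped_drugs": [
            d for d, f in zip(data.drug_names, ~informative) if f
        ]},
    )


def fit_firth_univariable(data: CaseCrossoverDataset) -> ModelFit:
    """Per-drug Firth fits assembled into one vector.

    Each drug's estimate matches the closed form
    log((n10 + 1/2)/(n01 + 1/2)).
    """
    z_full = _as_diff(data)
    p = z_full.shape[1]
    beta = np.zeros(p)
    flags = np.zeros(p, dtype=bool)
    converged = True
    for j in range(p):
        col = z_full[:, [j]]
        if not np.any(col != 0):
            flags[j] = True
            continue
        sub = fit_firth_column(col)
        beta[j] = sub
    return ModelFit(
        method="firth-uni",
        drug_names=list(data.drug_names),
        coefficients=beta,
        converged=converged,
        n_iterations=0,
        separation_flags=flags,
        loglik_at_solution=float(
            sum(cond_loglik(beta[[j]], z_full[:, [j]]) for j in range(p))
        ),
        tuning={},
    )


def fit_firth_column(col: np.ndarray) -> float:
    """One-dimensional Firth fit via the modified-score iteration."""
    beta = np.array([0.0])
    ll = firth_loglik(beta, col)
    for _ in range(MAX_ITER):
        score, info = _modified_score_and_info(beta, col)
        if abs(score[0]) < SCORE_TOL:
            break
        step = score / np.maximum(info[0], 1e-12)
        if abs(step[0]) > 5.0:
            step = np.array([np.sign(step[0]) * 5.0])
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_cand = firth_loglik(cand, col)
            if ll_cand > ll - 1e-14:
                break
            scale *= 0.5
        beta, ll = cand, ll_cand
    return float(beta[0])
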