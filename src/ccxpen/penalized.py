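"""L1/L2-penalized conditional logistic regression with cross-validated tuning.

The lasso maximizes  l(beta) - lambda * sum_j |beta_j|  over the
conditional log-likelihood of the matched pairs; the elastic net adds a
ridge term  - lambda2 * sum_j beta_j^2.  Estimation is cyclic coordinate
descent: each coordinate takes a Newton step on its local quadratic
approximation followed by soft-thresholding, with a per-update trust cap
so the quadratic model cannot overshoot on saturated likelihoods.

Tuning follows K-fold cross-validation over subjects (pairs stay intact):
for each candidate penalty the model is fit on K-1 blocks and the
held-out block's conditional log-likelihood is recorded; the K held-out
contributions are summed and the penalty maximizing this cross-validated
likelihood is selected (ties go to the heavier penalty, i.e. the sparser
model).  The default grid has 100 log-spaced points from lambda_max down
to lambda_max/1000, where lambda_max = max_j |n10_j - n01_j| / 2 is the
smallest penalty at which the lasso solution is exactly zero.

Exposures are binary on a common 0/1 scale and are deliberately not
standardized, so coefficients remain log odds ratios throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .clr_core import DIVERGENCE_BOUND, ModelFit, cond_loglik
from .io_data import CaseCrossoverDataset, count_discordances

#: post-convergence snap: coefficients below this magnitude count as zero
ZERO_SNAP = 1e-8
CD_TOL = 1e-7
CD_MAX_CYCLES = 5000


@dataclass
class PenaltyPath:
    """Lasso (or elastic-net) solution path over a decreasing penalty grid."""

    lambda_grid: np.ndarray
    coefficients_path: np.ndarray  # len(grid) x p
    loglik_path: np.ndarray
    lambda2: float = 0.0

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.coefficients_path = np.asarray(self.coefficients_path, dtype=float)
        self.loglik_path = np.asarray(self.loglik_path, dtype=float)
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    def to_frame(self, drug_names):
        import pandas as pd

        rows = []
        for lam, coefs in zip(self.lambda_grid, self.coefficients_path):
            for drug, c in zip(drug_names, coefs):
                rows.append((lam, drug, c))
        return pd.DataFrame(rows, columns=["lambda", "drug", "coefficient"])


@dataclass
class CVResult:
    """Cross-validation record: folds, the CV-likelihood curve, the winner."""

    fold_assignment: np.ndarray
    lambda_grid: np.ndarray
    cv_loglik: np.ndarray
    selected_lambda: float
    seed: int
    lambda2_grid: np.ndarray | None = None
    selected_lambda2: float = 0.0


@njit(cache=True)
def _cd_kernel(z, eta, beta, lam1, lam2, tol, max_cycles, bound):  # pragma: no cover
    n, p = z.shape
    for cycle in range(max_cycles):
        max_change = 0.0
        for j in range(p):
            g = 0.0
            h = 0.0
            for i in range(n):
                zij = z[i, j]
                if zij != 0.0:
                    mu = 1.0 / (1.0 + np.exp(-eta[i]))
                    g += zij * (1.0 - mu)
                    h += zij * zij * mu * (1.0 - mu)
            if h <= 1e-12 and lam2 == 0.0:
                # no curvature: either no discordant pair (g == 0) or a
                # fully saturated column; keep the coefficient in place
                if g <= lam1 and g >= -lam1:
                    continue
            b = beta[j]
            num = h * b + g
            denom = h + 2.0 * lam2
            if denom <= 1e-12:
                continue
            if num > lam1:
                new = (num - lam1) / denom
            elif num < -lam1:
                new = (num + lam1) / denom
            else:
                new = 0.0
            # trust cap: the local quadratic is only trustworthy nearby
            if new - b > 2.0:
                new = b + 2.0
            elif new - b < -2.0:
                new = b - 2.0
            if new > bound:
                new = bound
            elif new < -bound:
                new = -bound
            d = new - b
            if d != 0.0:
                beta[j] = new
                for i in range(n):
                    if z[i, j] != 0.0:
                        eta[i] += d * z[i, j]
                if abs(d) > max_change:
                    max_change = abs(d)
        if max_change < tol:
            return cycle + 1
    return max_cycles


def _as_diff(data) -> np.ndarray:
    if isinstance(data, CaseCrossoverDataset):
        return data.exposure_difference().astype(float)
    return np.asarray(data, dtype=float)


def penalized_objective(beta, z, lam1: float, lam2: float = 0.0) -> float:
    """l(beta) - lam1 * ||beta||_1 - lam2 * ||beta||_2^2."""
    beta = np.asarray(beta, dtype=float)
    return (
        cond_loglik(beta, z)
        - lam1 * np.abs(beta).sum()
        - lam2 * float(beta @ beta)
    )


def lambda_max(data) -> float:
    """Smallest penalty at which the lasso solution is exactly zero.

    Equals the largest absolute score coordinate at beta = 0, which for
    matched pairs is max_j |n10_j - n01_j| / 2.
    """
    if isinstance(data, CaseCrossoverDataset):
        disc = count_discordances(data)
        n10, n01 = disc.n10, disc.n01
        if int(n10.sum() + n01.sum()) == 0:
            raise ValueError("likelihood constant: no discordant pair for any drug")
        return float(np.abs(n10 - n01).max()) / 2.0
    z = np.asarray(data, dtype=float)
    if not np.any(z != 0):
        raise ValueError("likelihood constant: no discordant pair for any drug")
    return float(np.abs(z.sum(axis=0)).max()) / 2.0


def default_lambda_grid(
    lam_max: float, n_lambda: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced decreasing grid from lam_max down to lam_max * min_ratio."""
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_penalized(
    z: np.ndarray,
    lam1: float,
    lam2: float = 0.0,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    n, p = z.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    eta = z @ beta
    _cd_kernel(
        np.ascontiguousarray(z),
        eta,
        beta,
        float(lam1),
        float(lam2),
        CD_TOL,
        CD_MAX_CYCLES,
        DIVERGENCE_BOUND,
    )
    beta[np.abs(beta) < ZERO_SNAP] = 0.0
    return beta


def fit_lasso(data, lam: float, lam2: float = 0.0, beta0=None) -> np.ndarray:
    """Penalized-CLR coefficient vector at one penalty value."""
    if lam < 0 or lam2 < 0:
        raise ValueError("penalties must be non-negative")
    return _fit_penalized(_as_diff(data), lam, lam2, beta0)


def fit_path(data, lambda_grid, lam2: float = 0.0) -> PenaltyPath:
    """Warm-started solution path over a decreasing penalty grid."""
    z = _as_diff(data)
    grid = np.asarray(lambda_grid, dtype=float)
    coefs = np.zeros((len(grid), z.shape[1]))
    lls = np.zeros(len(grid))
    beta = None
    for i, lam in enumerate(grid):
        beta = _fit_penalized(z, lam, lam2, beta)
        coefs[i] = beta
        lls[i] = cond_loglik(beta, z)
    return PenaltyPath(grid, coefs, lls, lambda2=lam2)


def make_folds(data, K: int, seed: int) -> np.ndarray:
    """Random partition of subjects into K blocks of near-equal size.

    Each subject carries its intact case/reference pair into its block.
    Returns an array of fold indices in 0..K-1, one per subject.
    """
    n = data.n_subjects if isinstance(data, CaseCrossoverDataset) else int(data)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of subjects ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    for k, block in enumerate(np.array_split(order, K)):
        folds[block] = k
    return folds


def _cv_loglik_surface(z, folds, grid, lam2: float) -> np.ndarray:
    """Summed held-out conditional log-likelihood per grid point."""
    K = int(folds.max()) + 1
    cv = np.zeros(len(grid))
    for k in range(K):
        test = folds == k
        path = fit_path(z[~test], grid, lam2=lam2)
        etas = z[test] @ path.coefficients_path.T  # n_test x len(grid)
        cv += -np.logaddexp(0.0, -etas).sum(axis=0)
    return cv


def _final_fit(data, z, grid, sel_idx, cv, folds, seed, lam2, method, lambda2_grid=None):
    path = fit_path(z, grid, lam2=lam2)
    beta = path.coefficients_path[sel_idx]
    drug_names = (
        list(data.drug_names)
        if isinstance(data, CaseCrossoverDataset)
        else [f"x{j}" for j in range(z.shape[1])]
    )
    cvres = CVResult(
        fold_assignment=folds,
        lambda_grid=grid,
        cv_loglik=cv,
        selected_lambda=float(grid[sel_idx]),
        seed=seed,
        lambda2_grid=lambda2_grid,
        selected_lambda2=lam2,
    )
    fit = ModelFit(
        method=method,
        drug_names=drug_names,
        coefficients=beta,
        converged=True,
        n_iterations=0,
        separation_flags=np.zeros(z.shape[1], dtype=bool),
        loglik_at_solution=cond_loglik(beta, z),
        tuning={
            "lambda": float(grid[sel_idx]),
            "lambda2": lam2,
            "K": int(folds.max()) + 1,
            "seed": seed,
        },
    )
    return cvres, fit, path


def cv_lasso(
    data,
    K: int = 10,
    lambda_grid=None,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
):
    """Lasso tuned by K-fold cross-validated conditional likelihood.

    Returns ``(CVResult, ModelFit)``; the fit is refit on the full data at
    the selected penalty.  When several grid points tie, the largest
    penalty (sparsest model) wins.
    """
    z = _as_diff(data)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(lambda_max(z), n_lambda, min_ratio)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if grid.size > 1 and np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    folds = make_folds(
        data if isinstance(data, CaseCrossoverDataset) else z.shape[0], K, seed
    )
    cv = _cv_loglik_surface(z, folds, grid, 0.0)
    sel = int(np.argmax(cv))  # first max on a decreasing grid = largest lambda
    cvres, fit, _ = _final_fit(data, z, grid, sel, cv, folds, seed, 0.0, "lasso")
    return cvres, fit


def cv_elastic_net(
    data,
    K: int = 10,
    lambda1_grid=None,
    lambda2_grid=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
):
    """Elastic net tuned over a (lambda1, lambda2) grid by CV likelihood.

    The ridge term uses the squared L2 norm, so lambda2 = 0 recovers the
    lasso exactly and lambda1 = 0 is ridge regression.  The grid is
    scanned with lambda2 ascending and lambda1 descending; ties keep the
    first (sparsest / least ridged) candidate.
    """
    z = _as_diff(data)
    if lambda1_grid is None:
        lambda1_grid = default_lambda_grid(lambda_max(z), n_lambda, min_ratio)
    grid1 = np.asarray(lambda1_grid, dtype=float)
    grid2 = np.sort(np.asarray(list(lambda2_grid), dtype=float))
    if grid1.size == 0 or grid2.size == 0:
        raise ValueError("empty penalty grid")
    folds = make_folds(
        data if isinstance(data, CaseCrossoverDataset) else z.shape[0], K, seed
    )
    best = None
    for lam2 in grid2:
        cv = _cv_loglik_surface(z, folds, grid1, lam2)
        sel = int(np.argmax(cv))
        if best is None or cv[sel] > best[0] + 1e-12:
            best = (cv[sel], lam2, sel, cv)
    _, lam2, sel, cv = best
    cvres, fit, _ = _final_fit(
        data, z, grid1, sel, cv, folds, seed, lam2, "elastic_net", lambda2_grid=grid2
    )
    return cvres, fit
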