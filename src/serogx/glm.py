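"""Minimal weighted least-squares and logistic fitting core.

The permutation tests and the genome scan re-fit on the order of 10^5-10^6
small models, so fitting is done directly on numpy arrays: ordinary least
squares with Wald t-tests for continuous outcomes, Newton/IRLS with Wald
z-tests for binary outcomes, and a batched IRLS that fits one logistic model
per SNP sharing the covariate columns.  Estimates agree with statsmodels to
numerical precision (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

# linear predictor beyond which fitted probabilities are numerically 0/1;
# used both for overflow clipping and as a separation heuristic
_ETA_CAP = 30.0


class DegenerateDesignError(ValueError):
    """Design matrix is rank deficient (e.g. collinear interaction column)."""


@dataclass
class LinearFit:
    beta: np.ndarray
    se: np.ndarray
    df_resid: int
    n: int
    sigma2: float
    flags: tuple = ()

    def p_two_sided(self, j: int) -> float:
        t = self.beta[j] / self.se[j]
        return float(2.0 * stats.t.sf(abs(t), self.df_resid))

    def p_upper(self, j: int) -> float:
        """One-sided p for the alternative beta_j > 0."""
        t = self.beta[j] / self.se[j]
        return float(stats.t.sf(t, self.df_resid))


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    n: int
    converged: bool
    flags: tuple = ()
    n_iter: int = 0

    def p_two_sided(self, j: int) -> float:
        z = self.beta[j] / self.se[j]
        return float(2.0 * stats.norm.sf(abs(z)))

    def p_upper(self, j: int) -> float:
        z = self.beta[j] / self.se[j]
        return float(stats.norm.sf(z))


def fit_linear(X: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS with classical (homoskedastic) Wald standard errors.

    Raises :class:`DegenerateDesignError` if ``X`` is rank deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DegenerateDesignError(f"n={n} rows for p={p} columns")
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise DegenerateDesignError(f"design has rank {rank} < {p} columns")
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return LinearFit(beta=beta, se=se, df_resid=df, n=n, sigma2=sigma2)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Logistic regression by Newton/IRLS.

    Convergence is declared when the max absolute coefficient change falls
    below ``tol``.  Suspected complete/quasi-complete separation (diverging
    coefficients or saturated fitted probabilities) is reported via
    ``flags`` rather than by raising, so scans can record and move on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDesignError(f"design has rank < {p} columns")
    beta = np.zeros(p)
    flags: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CAP, _ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # guard against zero weights from saturated probabilities
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    if not converged and "singular_information" not in flags:
        flags.append("not_converged")
    eta = X @ beta
    if np.max(np.abs(eta)) >= _ETA_CAP or np.max(np.abs(beta)) > 25.0:
        flags.append("separation_suspected")
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CAP, _ETA_CAP)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        beta=beta, se=se, n=n, converged=converged, flags=tuple(flags), n_iter=it
    )


def logistic_irls_batch(
    Xs: np.ndarray,
    y: np.ndarray,
    row_weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``S`` logistic models sharing the outcome in one vectorized sweep.

    Parameters
    ----------
    Xs : (S, n, p) design tensor, one design per model (per SNP).
    y : (n,) binary outcome shared by all models.
    row_weights : optional (S, n) 0/1 mask; rows with weight 0 (e.g. missing
        genotype) drop out of the corresponding model.

    Returns ``(beta, se, converged, ok)`` with shapes (S, p), (S, p), (S,),
    (S,).  ``ok`` is False where the information matrix was singular or the
    coefficients diverged; those rows carry NaN estimates.
    """
    Xs = np.asarray(Xs, dtype=float)
    S, n, p = Xs.shape
    y = np.asarray(y, dtype=float)
    if row_weights is None:
        row_weights = np.ones((S, n))
    m = np.asarray(row_weights, dtype=float)

    beta = np.zeros((S, p))
    active = np.ones(S, dtype=bool)
    ok = np.ones(S, dtype=bool)
    converged = np.zeros(S, dtype=bool)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa = Xs[idx]
        ba = beta[idx]
        ma = m[idx]
        eta = np.clip(np.einsum("snp,sp->sn", Xa, ba), -_ETA_CAP, _ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12) * ma
        z = eta + (y[None, :] - mu) / np.maximum(mu * (1.0 - mu), 1e-12)
        XtW = Xa.transpose(0, 2, 1) * w[:, None, :]
        A = XtW @ Xa
        b = np.einsum("spn,sn->sp", XtW, z)
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0]
            bad = ~np.isfinite(new).all(axis=1)
        except np.linalg.LinAlgError:
            # fall back to per-model solve to isolate singular designs
            new = np.empty_like(ba)
            bad = np.zeros(idx.size, dtype=bool)
            for k in range(idx.size):
                try:
                    new[k] = np.linalg.solve(A[k], b[k])
                except np.linalg.LinAlgError:
                    bad[k] = True
                    new[k] = np.nan
        diverged = np.nanmax(np.abs(new), axis=1) > 1e3
        bad |= diverged
        step = np.max(np.abs(new - ba), axis=1)
        beta[idx] = new
        done = step < tol
        converged[idx[done & ~bad]] = True
        ok[idx[bad]] = False
        active[idx[done | bad]] = False

    # standard errors from the final information matrix
    se = np.full((S, p), np.nan)
    eta = np.clip(np.einsum("snp,sp->sn", Xs, beta), -_ETA_CAP, _ETA_CAP)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12) * m
    A = (Xs.transpose(0, 2, 1) * w[:, None, :]) @ Xs
    for s in range(S):
        if not ok[s]:
            beta[s] = np.nan
            continue
        try:
            se[s] = np.sqrt(np.diag(np.linalg.inv(A[s])))
        except np.linalg.LinAlgError:
            ok[s] = False
            beta[s] = np.nan
    return beta, se, converged, ok
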