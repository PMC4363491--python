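"""Serology assay cleaning.

Order of operations, fixed: outlier-plate exclusion -> failed-assay (zero)
removal -> log2 transform -> residualization against plate (random
intercept) and storage years (fixed effect).

The residualizer is a one-random-intercept linear mixed model fitted by
REML.  Because there is a single variance ratio lambda = sigma_u^2 /
sigma_e^2, the REML criterion is profiled down to a 1-D function of lambda
using the closed-form blockwise inverse of V = I + lambda * Z Z', and
minimized by bounded scalar search on log(lambda).  BLUPs then have the
classical shrinkage form u_j = lambda * n_j / (1 + lambda * n_j) * (mean
within-plate residual).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import ANALYTES

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# outlier plates

@dataclass
class OutlierPlateReport:
    flagged: list
    stats: pd.DataFrame  # plate, analyte, n, ks_stat, p
    threshold: float
    skipped: list = field(default_factory=list)


def detect_outlier_plates(
    assays: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
) -> OutlierPlateReport:
    """Flag plates whose assay distributions differ from all other plates.

    Per plate and analyte, a two-sample Kolmogorov-Smirnov test of that
    plate's log2 values against the pooled remainder; a plate is flagged if
    any analyte passes the Bonferroni-corrected level
    ``alpha / (n_plates * n_analytes)``.  Plates with fewer than 3
    observations for an analyte are skipped (never flagged on it).
    """
    merged = assays.merge(
        subjects[["subject_id", "plate"]], on="subject_id", how="left")
    plates = np.sort(merged["plate"].unique())
    if plates.size < 2:
        return OutlierPlateReport([], pd.DataFrame(
            columns=["plate", "analyte", "n", "ks_stat", "p"]), np.nan)
    thresh = alpha / (plates.size * len(ANALYTES))
    rows = []
    skipped = []
    for a in ANALYTES:
        raw = merged[a].to_numpy(dtype=float)
        vals = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
        for p in plates:
            on = vals[(merged["plate"] == p).to_numpy() & ~np.isnan(vals)]
            off = vals[(merged["plate"] != p).to_numpy() & ~np.isnan(vals)]
            if on.size < 3:
                log.warning(
                    "plate %s has %d observations for %s; skipped", p, on.size, a)
                skipped.append((p, a))
                continue
            ks = stats.ks_2samp(on, off)
            rows.append(
                {"plate": p, "analyte": a, "n": on.size,
                 "ks_stat": ks.statistic, "p": ks.pvalue})
    st = pd.DataFrame(rows)
    flagged = sorted(st.loc[st["p"] < thresh, "plate"].unique().tolist())
    return OutlierPlateReport(flagged, st, thresh, skipped)


# ---------------------------------------------------------------------------
# failed assays and log2

def drop_failed_assays(assays: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Mark zero-valued raw ratios as missing and log2-transform the rest.

    Returns ``(log2_df, n_zero)`` where ``log2_df`` carries NaN wherever the
    raw value was 0 (failed assay) or missing, and ``n_zero`` counts
    removals per analyte.
    """
    out = assays[["subject_id"]].copy()
    n_zero = {}
    for a in ANALYTES:
        raw = assays[a].to_numpy(dtype=float)
        zero = raw == 0
        n_zero[a] = int(zero.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(raw)
        vals[zero | np.isnan(raw)] = np.nan
        out[a] = vals
        if n_zero[a]:
            log.info("%s: removed %d zero-valued assays", a, n_zero[a])
    return out, n_zero


# ---------------------------------------------------------------------------
# REML residualization

@dataclass
class MixedFit:
    analyte: str
    beta: np.ndarray          # (intercept, storage slope)
    sigma2_u: float
    sigma2_e: float
    lam: float                # sigma2_u / sigma2_e
    blups: dict               # plate -> BLUP of the plate intercept
    neg2_reml: float
    n: int
    method: str = "reml"      # or "fixed_dummies" fallback


def reml_criterion(
    lam: float, y: np.ndarray, X: np.ndarray,
    plate_codes: np.ndarray, plate_sizes: np.ndarray,
) -> float:
    """-2 x profiled REML log-likelihood (up to an additive constant) of the
    random-intercept model at variance ratio ``lam``."""
    crit, _, _ = _reml_pieces(lam, y, X, plate_codes, plate_sizes)
    return crit


def _reml_pieces(lam, y, X, codes, sizes):
    n, p = X.shape
    q = sizes.size
    c = lam / (1.0 + lam * sizes)                     # (q,)
    SX = np.zeros((q, p))
    for k in range(p):
        SX[:, k] = np.bincount(codes, weights=X[:, k], minlength=q)
    Sy = np.bincount(codes, weights=y, minlength=q)
    XtVX = X.T @ X - (SX * c[:, None]).T @ SX
    XtVy = X.T @ y - SX.T @ (c * Sy)
    yTVy = y @ y - c @ (Sy * Sy)
    beta = np.linalg.solve(XtVX, XtVy)
    quad = yTVy - XtVy @ beta
    df = n - p
    sigma2 = max(quad / df, 1e-300)
    sign, logdet = np.linalg.slogdet(XtVX)
    crit = df * np.log(sigma2) + np.sum(np.log1p(lam * sizes)) + logdet
    return crit, beta, sigma2


def residualize(
    log2_df: pd.DataFrame,
    subjects: pd.DataFrame,
    analyte: str,
) -> tuple[pd.Series, MixedFit]:
    """Residuals of ``log2(analyte)`` after removing the storage-year drift
    and the plate random intercept (BLUP).

    Returns a Series indexed like ``log2_df`` (NaN where the input was
    missing) and the fitted :class:`MixedFit`.  With fewer than 3 distinct
    plates the model falls back to fixed-effect plate dummies.
    """
    merged = log2_df[["subject_id", analyte]].merge(
        subjects[["subject_id", "plate", "storage_years"]],
        on="subject_id", how="left")
    okm = merged[analyte].notna().to_numpy()
    y = merged.loc[okm, analyte].to_numpy(dtype=float)
    storage = merged.loc[okm, "storage_years"].to_numpy(dtype=float)
    plate = merged.loc[okm, "plate"].to_numpy()
    uplates, codes = np.unique(plate, return_counts=False), None
    codes = np.searchsorted(uplates, plate)
    sizes = np.bincount(codes, minlength=uplates.size).astype(float)

    if uplates.size < 2 or np.sum(sizes >= 2) < 2:
        raise ValueError(
            f"{analyte}: need >= 2 plates with >= 2 observations each")

    X = np.column_stack([np.ones_like(y), storage])

    if uplates.size < 3:
        log.warning(
            "%s: only %d plates; falling back to fixed-effect plate dummies",
            analyte, uplates.size)
        dummies = np.zeros((y.size, uplates.size - 1))
        for k in range(1, uplates.size):
            dummies[codes == k, k - 1] = 1.0
        Xd = np.column_stack([X, dummies])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        fit = MixedFit(
            analyte=analyte, beta=beta[:2], sigma2_u=float("nan"),
            sigma2_e=float(resid @ resid / (y.size - Xd.shape[1])),
            lam=float("nan"),
            blups={p: float(b) for p, b in zip(uplates[1:], beta[2:])},
            neg2_reml=float("nan"), n=y.size, method="fixed_dummies")
    else:
        res = optimize.minimize_scalar(
            lambda t: reml_criterion(np.exp(t), y, X, codes, sizes),
            bounds=(-16.0, 10.0), method="bounded",
            options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError(
                f"{analyte}: REML variance-ratio optimization did not converge")
        lam = float(np.exp(res.x))
        crit, beta, sigma2 = _reml_pieces(lam, y, X, codes, sizes)
        r = y - X @ beta
        c = lam / (1.0 + lam * sizes)
        u = c * np.bincount(codes, weights=r, minlength=sizes.size)
        resid = r - u[codes]
        fit = MixedFit(
            analyte=analyte, beta=beta, sigma2_u=lam * sigma2,
            sigma2_e=sigma2, lam=lam,
            blups={p: float(b) for p, b in zip(uplates, u)},
            neg2_reml=float(crit), n=y.size)

    out = pd.Series(np.nan, index=merged.index, name=analyte)
    out[okm] = resid
    return out, fit


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class CleaningResult:
    subjects: pd.DataFrame       # subjects retained after plate exclusion
    residuals: pd.DataFrame      # subject_id + one residual column per analyte
    outlier_report: OutlierPlateReport
    n_zero: dict
    fits: dict                   # analyte -> MixedFit
    n_input: int
    n_excluded_plate: int

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for a in ANALYTES:
            f = self.fits[a]
            rows.append({
                "analyte": a,
                "n_fitted": f.n,
                "n_zero_removed": self.n_zero[a],
                "storage_slope": f.beta[1],
                "sigma2_plate": f.sigma2_u,
                "sigma2_resid": f.sigma2_e,
                "method": f.method,
            })
        return pd.DataFrame(rows)


def clean_serology(
    subjects: pd.DataFrame,
    assays: pd.DataFrame,
    alpha: float = 0.05,
    exclude_flagged_plates: bool = True,
) -> CleaningResult:
    """Run the full cleaning cascade and residualize every analyte."""
    n_input = len(subjects)
    report = detect_outlier_plates(assays, subjects, alpha=alpha)
    subj = subjects
    if exclude_flagged_plates and report.flagged:
        keep = ~subj["plate"].isin(report.flagged)
        log.info("excluding plates %s (%d subjects)",
                 report.flagged, int((~keep).sum()))
        subj = subj[keep].reset_index(drop=True)
    asy = assays[assays["subject_id"].isin(subj["subject_id"])].reset_index(drop=True)
    log2_df, n_zero = drop_failed_assays(asy)
    residuals = log2_df[["subject_id"]].copy()
    fits = {}
    for a in ANALYTES:
        res, fit = residualize(log2_df, subj, a)
        residuals[a] = res.to_numpy()
        fits[a] = fit
    return CleaningResult(
        subjects=subj, residuals=residuals, outlier_report=report,
        n_zero=n_zero, fits=fits, n_input=n_input,
        n_excluded_plate=n_input - len(subj))
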