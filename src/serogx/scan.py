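"""Genotype QC cascade and genotype x serology interaction scan.

QC follows the standard array-era cascade, in this exact order: (1) SNPs
with >5% missingness out; (2) subjects with >2% missingness out (computed
after step 1); (3) SNPs with >2% missingness out (after the subject
removal); (4) SNPs out of Hardy-Weinberg equilibrium at p < 1e-6 out;
finally SNPs with minor allele frequency < 0.05 out.  Order matters and is
part of the contract.

The scan fits, per SNP, a logistic model

    phenotype ~ genotype + serology + genotype:serology + age + sex

by IRLS and Wald-tests the interaction coefficient.  Genotypes are additive
minor-allele dosages; missing dosages are handled complete-case per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomat import GenotypeMatrix
from .glm import (
    DegenerateDesignError,
    LinearFit,
    fit_linear,
    fit_logistic,
    logistic_irls_batch,
)

GENOME_WIDE_ALPHA = 8.3e-9   # 5e-8 split across the 6 serology variables
SUGGESTIVE_ALPHA = 1e-5


# ---------------------------------------------------------------------------
# Hardy-Weinberg

def hwe_chisq_p(n_hom_ref: np.ndarray, n_het: np.ndarray,
                n_hom_alt: np.ndarray) -> np.ndarray:
    """1-df chi-square HWE p-value from genotype counts (vectorized).

    Expected counts are n*p^2, 2npq, n*q^2 at the sample allele frequency.
    Monomorphic SNPs return p = 1.
    """
    n0 = np.asarray(n_hom_ref, dtype=float)
    n1 = np.asarray(n_het, dtype=float)
    n2 = np.asarray(n_hom_alt, dtype=float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n0 + n1) / (2 * n)
        q = 1.0 - p
        e0 = n * p * p
        e1 = 2 * n * p * q
        e2 = n * q * q
        chi2 = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1
                + (n2 - e2) ** 2 / e2)
    out = stats.chi2.sf(chi2, df=1)
    mono = (p == 0) | (q == 0) | (n == 0)
    out = np.where(mono, 1.0, out)
    return out


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE test: sum of probabilities of heterozygote counts as or
    less likely than observed, conditional on allele counts."""
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    # heterozygote count shares the parity of the rare-allele count
    het_vals = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logprob = np.zeros(het_vals.size)
    for i, h in enumerate(het_vals):
        a = (n_rare - h) // 2          # rare homozygotes
        b = n - a - h                  # common homozygotes
        logprob[i] = (
            _lgamma(n + 1) - _lgamma(a + 1) - _lgamma(h + 1) - _lgamma(b + 1)
            + h * np.log(2.0)
            + _lgamma(n_rare + 1) + _lgamma(2 * n - n_rare + 1)
            - _lgamma(2 * n + 1)
        )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    p_obs = prob[het_vals == n_het][0]
    return float(np.sum(prob[prob <= p_obs * (1 + 1e-12)]))


def _lgamma(x):
    from scipy.special import gammaln
    return gammaln(x)


# ---------------------------------------------------------------------------
# QC cascade

@dataclass
class QCReport:
    steps: list = field(default_factory=list)  # (step name, n removed)
    removed_snps: dict = field(default_factory=dict)   # step -> list of ids
    removed_subjects: list = field(default_factory=list)
    n_snps_in: int = 0
    n_snps_out: int = 0
    n_subjects_in: int = 0
    n_subjects_out: int = 0

    def removal_step(self, snp_id: str) -> str | None:
        for step, ids in self.removed_snps.items():
            if snp_id in ids:
                return step
        return None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed"])


def qc_genotypes(
    gm: GenotypeMatrix,
    snp_missing_max: float = 0.05,
    subject_missing_max: float = 0.02,
    snp_missing_max_2: float = 0.02,
    hwe_alpha: float = 1e-6,
    maf_min: float = 0.05,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the five-step QC cascade in order; returns the filtered matrix
    and a step-by-step accounting report.  Raises if any step empties the
    SNP set, naming the step."""
    if gm.n_snps == 0 or gm.n_subjects == 0:
        raise ValueError("empty genotype matrix")
    rep = QCReport(n_snps_in=gm.n_snps, n_subjects_in=gm.n_subjects)

    def _snp_ids(g, mask):
        return g.snps.loc[~mask, "snp_id"].tolist()

    # 1. SNP missingness > 5%
    keep = gm.snp_missingness() <= snp_missing_max
    rep.removed_snps["snp_missingness_5pct"] = _snp_ids(gm, keep)
    rep.steps.append(("snp_missingness_5pct", int((~keep).sum())))
    gm = gm.subset(snp_mask=keep)
    if gm.n_snps == 0:
        raise ValueError("QC step 'snp_missingness_5pct' removed all SNPs")

    # 2. subject missingness > 2%
    keep_subj = gm.subject_missingness() <= subject_missing_max
    rep.removed_subjects = gm.subject_ids[~keep_subj].tolist()
    rep.steps.append(("subject_missingness_2pct", int((~keep_subj).sum())))
    gm = gm.subset(subject_mask=keep_subj)
    if gm.n_subjects == 0:
        raise ValueError(
            "QC step 'subject_missingness_2pct' removed all subjects")

    # 3. SNP missingness > 2% after subject removal
    keep = gm.snp_missingness() <= snp_missing_max_2
    rep.removed_snps["snp_missingness_2pct"] = _snp_ids(gm, keep)
    rep.steps.append(("snp_missingness_2pct", int((~keep).sum())))
    gm = gm.subset(snp_mask=keep)
    if gm.n_snps == 0:
        raise ValueError("QC step 'snp_missingness_2pct' removed all SNPs")

    # 4. HWE
    d = gm.dosages
    n0 = np.nansum(d == 0, axis=0)
    n1 = np.nansum(d == 1, axis=0)
    n2 = np.nansum(d == 2, axis=0)
    if hwe_method == "chisq":
        hwe_p = hwe_chisq_p(n0, n1, n2)
    elif hwe_method == "exact":
        hwe_p = np.array([
            hwe_exact_p(int(a), int(b), int(c))
            for a, b, c in zip(n0, n1, n2)])
    else:
        raise ValueError(f"unknown hwe_method {hwe_method!r}")
    keep = hwe_p >= hwe_alpha
    rep.removed_snps["hwe"] = _snp_ids(gm, keep)
    rep.steps.append(("hwe", int((~keep).sum())))
    gm = gm.subset(snp_mask=keep)
    if gm.n_snps == 0:
        raise ValueError("QC step 'hwe' removed all SNPs")

    # 5. MAF
    keep = gm.maf() >= maf_min
    rep.removed_snps["maf"] = _snp_ids(gm, keep)
    rep.steps.append(("maf", int((~keep).sum())))
    gm = gm.subset(snp_mask=keep)
    if gm.n_snps == 0:
        raise ValueError("QC step 'maf' removed all SNPs")

    rep.n_snps_out = gm.n_snps
    rep.n_subjects_out = gm.n_subjects
    return gm, rep


# ---------------------------------------------------------------------------
# interaction models

@dataclass
class InteractionResult:
    snp_id: str
    beta_main: float
    beta_int: float
    se_int: float
    p_int: float
    n_used: int
    serology: str = ""
    phenotype: str = ""
    converged: bool = True
    flags: tuple = ()


def fit_interaction_model(
    phenotype: np.ndarray,
    dosage: np.ndarray,
    serology: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
    snp_id: str = "",
    serology_name: str = "",
    phenotype_name: str = "",
    min_n: int = 50,
) -> InteractionResult:
    """Single-SNP logistic interaction fit with Wald test on the product
    term.  Complete-case over all five inputs; a rank-deficient design
    (e.g. serology constant, making genotype:serology collinear with
    genotype) raises :class:`DegenerateDesignError`."""
    arrs = [np.asarray(v, dtype=float) for v in
            (phenotype, dosage, serology, age, male)]
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    y, g, s, a_, m_ = (a[ok] for a in arrs)
    if y.size < min_n:
        raise ValueError(f"only {y.size} complete-case rows (< {min_n})")
    X = np.column_stack([np.ones(y.size), g, s, g * s, a_, m_])
    fit = fit_logistic(X, y)
    return InteractionResult(
        snp_id=snp_id, beta_main=float(fit.beta[1]),
        beta_int=float(fit.beta[3]), se_int=float(fit.se[3]),
        p_int=fit.p_two_sided(3), n_used=int(y.size),
        serology=serology_name, phenotype=phenotype_name,
        converged=fit.converged, flags=fit.flags)


def interaction_scan_batch(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    serology: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP interaction fits.

    ``dosages`` is (n, S) with NaN for missing calls; rows with missing
    phenotype/serology/age must be pre-filtered.  Returns arrays
    ``(beta_main, beta_int, se_int, n_used, ok)`` of length S; per-SNP
    missing genotypes are zero-weighted (complete-case per SNP).
    """
    n, S = dosages.shape
    y = np.asarray(phenotype, dtype=float)
    base = np.column_stack(
        [np.ones(n), np.zeros(n), serology, np.zeros(n), age, male])
    beta_main = np.full(S, np.nan)
    beta_int = np.full(S, np.nan)
    se_int = np.full(S, np.nan)
    n_used = np.zeros(S, dtype=int)
    all_ok = np.zeros(S, dtype=bool)
    for start in range(0, S, chunk):
        stop = min(start + chunk, S)
        d = dosages[:, start:stop]
        miss = np.isnan(d)
        dz = np.where(miss, 0.0, d)
        k = stop - start
        Xs = np.broadcast_to(base, (k, n, 6)).copy()
        Xs[:, :, 1] = dz.T
        Xs[:, :, 3] = dz.T * serology[None, :]
        w = (~miss.T).astype(float)
        b, se, conv, ok = logistic_irls_batch(Xs, y, row_weights=w)
        ok = ok & conv
        beta_main[start:stop] = b[:, 1]
        beta_int[start:stop] = b[:, 3]
        se_int[start:stop] = se[:, 3]
        n_used[start:stop] = w.sum(axis=1).astype(int)
        all_ok[start:stop] = ok
    return beta_main, beta_int, se_int, n_used, all_ok


def genomic_inflation(z: np.ndarray) -> float:
    """Lambda: median observed Wald chi-square over its null median."""
    chi2 = np.asarray(z, dtype=float) ** 2
    chi2 = chi2[~np.isnan(chi2)]
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


def scan_genome(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    serology: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
    serology_name: str = "",
    phenotype_name: str = "",
    suggestive_alpha: float = SUGGESTIVE_ALPHA,
    genome_wide_alpha: float = GENOME_WIDE_ALPHA,
) -> tuple[pd.DataFrame, float]:
    """Genome-wide interaction scan.

    Returns ``(results, lambda_gc)``.  ``results`` has one row per SNP with
    ``beta_main, beta_int, se_int, p_int, n_used, flag, tier``, sorted by
    interaction p; per-SNP failures are flagged, never fatal.  ``lambda_gc``
    is the genomic-inflation factor of the interaction Wald statistics.
    """
    cov = np.column_stack([
        np.asarray(phenotype, dtype=float),
        np.asarray(serology, dtype=float),
        np.asarray(age, dtype=float),
        np.asarray(male, dtype=float)])
    rows_ok = ~np.isnan(cov).any(axis=1)
    y, s, a_, m_ = (cov[rows_ok, j] for j in range(4))
    d = gm.dosages[rows_ok]
    bm, bi, se, n_used, ok = interaction_scan_batch(d, y, s, a_, m_)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = bi / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    res = pd.DataFrame({
        "snp_id": gm.snps["snp_id"],
        "chrom": gm.snps["chrom"],
        "pos": gm.snps["pos"],
        "beta_main": bm,
        "beta_int": bi,
        "se_int": se,
        "p_int": p,
        "n_used": n_used,
        "flag": np.where(ok, "ok", "failed"),
    })
    tier = np.full(len(res), "-", dtype=object)
    tier[(p < suggestive_alpha) & ok] = "suggestive"
    tier[(p < genome_wide_alpha) & ok] = "genome-wide"
    res["tier"] = tier
    res["serology"] = serology_name
    res["phenotype"] = phenotype_name
    lam = genomic_inflation(z[ok])
    return res.sort_values("p_int", na_position="last").reset_index(drop=True), lam


def replicate_snp(
    gm: GenotypeMatrix,
    snp_id: str,
    phenotype: np.ndarray,
    serology: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
    expected_direction: int = 1,
    qc_report: QCReport | None = None,
) -> dict:
    """One-sided replication test of a previously reported interaction.

    ``expected_direction`` is the pre-declared sign of the interaction
    (+1/-1); the one-sided p is the Wald tail in that direction.  If the
    SNP is absent and a QC report is supplied, the error names the filter
    that removed it.
    """
    try:
        j = gm.snp_index(snp_id)
    except KeyError:
        step = qc_report.removal_step(snp_id) if qc_report else None
        if step:
            raise KeyError(
                f"SNP {snp_id!r} was removed by QC step {step!r}") from None
        raise
    r = fit_interaction_model(
        phenotype, gm.dosages[:, j], serology, age, male, snp_id=snp_id)
    z = r.beta_int / r.se_int
    p_one = float(stats.norm.sf(expected_direction * z))
    return {
        "snp_id": snp_id, "beta_int": r.beta_int, "se_int": r.se_int,
        "p_one_sided": p_one, "p_two_sided": r.p_int, "n_used": r.n_used,
        "expected_direction": expected_direction,
        "direction_matches": np.sign(r.beta_int) == expected_direction,
    }


def qt_association(
    feature: np.ndarray,
    dosage: np.ndarray,
    affection: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
) -> dict:
    """Quantitative-trait association of a continuous serology feature with
    dosage, controlling for affection status, age and sex (cases and
    controls pooled).  Two-sided Wald p on the dosage coefficient."""
    arrs = [np.asarray(v, dtype=float) for v in
            (feature, dosage, affection, age, male)]
    ok = ~np.any([np.isnan(a) for a in arrs], axis=0)
    yv, g, aff, a_, m_ = (a[ok] for a in arrs)
    X = np.column_stack([np.ones(yv.size), g, aff, a_, m_])
    fit: LinearFit = fit_linear(X, yv)
    return {
        "beta": float(fit.beta[1]), "se": float(fit.se[1]),
        "p": fit.p_two_sided(1), "n_used": int(yv.size),
    }
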