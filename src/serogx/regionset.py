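"""SNP-set interaction enrichment under LD via phenotype permutation.

Whether a pre-specified SNP set (e.g. disease-associated SNPs in the HLA
region) carries more nominally significant genotype x serology interactions
than expected cannot be judged against a binomial null: the SNPs are in LD
and their tests correlated.  The null is built by permuting the phenotype
labels within sex strata while leaving genotypes, serology and age attached
to subjects -- LD structure and any genotype-exposure dependence survive the
shuffle, only the genotype/exposure-phenotype link is broken.  Duplicating a
SNP in the set shifts the observed count and the whole permutation
distribution together, which is exactly the LD-robustness the scheme buys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomat import GenotypeMatrix
from .scan import interaction_scan_batch


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete
    pairs; NaN for monomorphic SNPs or fewer than 10 complete pairs."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 10:
        raise ValueError(f"only {a.size} complete pairs (< 10)")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class RegionEnrichment:
    snp_set: list
    observed_hits: int
    n_tested: int
    alpha: float
    n_perm: int
    perm_hits: np.ndarray
    p_empirical: float
    p_corrected: float
    seed: int

    @property
    def hit_fraction(self) -> float:
        return self.observed_hits / self.n_tested

    def summary(self) -> str:
        return (f"{self.observed_hits}/{self.n_tested} "
                f"({100 * self.hit_fraction:.0f}%) nominally significant "
                f"interactions; permutation p = {self.p_empirical:.4g}")


def _hit_count(dosages, y, serology, age, male, alpha):
    _, bi, se, _, ok = interaction_scan_batch(dosages, y, serology, age, male)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(bi / se))
    return int(np.sum((p < alpha) & ok))


def region_enrichment_test(
    gm: GenotypeMatrix,
    snp_set: list,
    phenotype: np.ndarray,
    serology: np.ndarray,
    age: np.ndarray,
    male: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    correction_factor: int = 1,
) -> RegionEnrichment:
    """Count nominally significant interaction tests in ``snp_set`` and
    compare to the within-sex phenotype-permutation null.

    Empirical p is k/N with ties counted; ``p_corrected`` multiplies by
    ``correction_factor`` (e.g. 6 when six serology variables were
    screened), capped at 1.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm = {n_perm} must be >= 100")
    present = set(gm.snps["snp_id"])
    idx = [gm.snp_index(s) for s in snp_set if s in present]
    if not idx:
        raise ValueError("SNP set is empty after intersecting with the matrix")
    cov = np.column_stack([
        np.asarray(phenotype, dtype=float),
        np.asarray(serology, dtype=float),
        np.asarray(age, dtype=float),
        np.asarray(male, dtype=float)])
    rows_ok = ~np.isnan(cov).any(axis=1)
    y, s, a_, m_ = (cov[rows_ok, j] for j in range(4))
    d = gm.dosages[np.ix_(rows_ok, idx)]

    observed = _hit_count(d, y, s, a_, m_, alpha)

    rng = np.random.default_rng(seed)
    male_idx = np.flatnonzero(m_ == 1.0)
    female_idx = np.flatnonzero(m_ == 0.0)
    perm_hits = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        yp = y.copy()
        yp[male_idx] = y[male_idx[rng.permutation(male_idx.size)]]
        yp[female_idx] = y[female_idx[rng.permutation(female_idx.size)]]
        perm_hits[b] = _hit_count(d, yp, s, a_, m_, alpha)

    k = int(np.sum(perm_hits >= observed))
    p = k / n_perm
    return RegionEnrichment(
        snp_set=[gm.snps["snp_id"].iloc[i] for i in idx],
        observed_hits=observed, n_tested=len(idx), alpha=alpha,
        n_perm=n_perm, perm_hits=perm_hits, p_empirical=float(p),
        p_corrected=float(min(1.0, p * correction_factor)), seed=seed)
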