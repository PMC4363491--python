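"""Genotype QC cascade, HWE tests, and the interaction scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serogx.genomat import GenotypeMatrix
from serogx.glm import DegenerateDesignError
from serogx.scan import (
    fit_interaction_model,
    genomic_inflation,
    hwe_chisq_p,
    hwe_exact_p,
    qc_genotypes,
    qt_association,
    replicate_snp,
    scan_genome,
)
from serogx.simulate import (
    CausalSNP,
    GenoSimConfig,
    assign_disease_by_interaction,
    generate_genotypes,
)


def qc_fixture():
    """30 subjects x 60 SNPs constructed so the cascade removes exactly:
    2 SNPs (>5% missing), 1 subject (>2% missing), 1 further SNP (>2%
    missing), 1 SNP out of HWE, 1 SNP with MAF < 5% -> 55 SNPs, 29 subjects.
    """
    n, m = 30, 60
    base = np.array([0] * 11 + [1] * 15 + [2] * 4, dtype=float)  # good HWE
    rng = np.random.default_rng(0)
    d = np.column_stack([rng.permutation(base) for _ in range(m)])
    # SNPs 0,1: two missing calls each -> step 1
    d[2, 0] = d[3, 0] = np.nan
    d[2, 1] = d[3, 1] = np.nan
    # subject 29: missing at SNPs 10,11 -> 2/58 > 2% -> step 2
    d[29, 10] = d[29, 11] = np.nan
    # SNP 12: one missing call in a retained subject -> 1/29 > 2% -> step 3
    d[5, 12] = np.nan
    # SNP 13: all heterozygote -> HWE chi-square = n -> step 4
    d[:, 13] = 1.0
    # SNP 14: single heterozygote -> MAF 1/58 < 5% -> step 5
    d[:, 14] = 0.0
    d[7, 14] = 1.0
    snps = pd.DataFrame({
        "snp_id": [f"snp{i:06d}" for i in range(m)],
        "chrom": 1, "pos": 10_000 + 5_000 * np.arange(m),
        "allele1": "A", "allele2": "G"})
    ids = np.array([f"S{i:02d}" for i in range(n)])
    return GenotypeMatrix(d, ids, snps)


class TestHWE:
    def test_perfect_hwe_chi_square_zero(self):
        assert hwe_chisq_p(25, 50, 25) == pytest.approx(1.0)
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    def test_chisq_matches_expected_count_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            c = rng.integers(1, 200, size=3)
            n = c.sum()
            p = (2 * c[0] + c[1]) / (2 * n)
            exp = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
            chi2 = (((c - exp) ** 2) / exp).sum()
            oracle = stats.chi2.sf(chi2, 1)
            ours = hwe_chisq_p(c[0], c[1], c[2])
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_exact_test_probabilities_sum_to_one(self):
        # p-value of the most probable configuration is large, of an extreme
        # configuration small; both bounded by construction
        assert 0 < hwe_exact_p(40, 5, 40) < 1e-6
        assert hwe_exact_p(0, 0, 50) == 1.0

    def test_monomorphic_snp_passes(self):
        assert hwe_chisq_p(100, 0, 0) == 1.0


class TestQCCascade:
    def test_constructed_fixture_counts(self):
        gm = qc_fixture()
        out, rep = qc_genotypes(gm)
        assert out.n_snps == 55
        assert out.n_subjects == 29
        assert dict(rep.steps) == {
            "snp_missingness_5pct": 2,
            "subject_missingness_2pct": 1,
            "snp_missingness_2pct": 1,
            "hwe": 1,
            "maf": 1,
        }
        assert rep.removed_snps["hwe"] == ["snp000013"]
        assert rep.removed_snps["maf"] == ["snp000014"]
        assert rep.removed_subjects == ["S29"]

    def test_step_order_matters(self):
        """SNPs 10/11 exceed the 2% missingness filter on the raw matrix but
        survive because their missing calls sit in the subject removed at
        step 2 -- reordering steps would drop them."""
        gm = qc_fixture()
        raw_missing = gm.snp_missingness()
        assert raw_missing[10] > 0.02 and raw_missing[11] > 0.02
        out, _ = qc_genotypes(gm)
        kept = set(out.snps["snp_id"])
        assert {"snp000010", "snp000011"} <= kept

    def test_all_heterozygote_snp_has_max_maf(self):
        gm = qc_fixture()
        assert gm.maf()[13] == pytest.approx(0.5)

    def test_emptying_step_is_named(self):
        gm = qc_fixture()
        gm.dosages[:, :] = np.nan
        with pytest.raises(ValueError, match="snp_missingness_5pct"):
            qc_genotypes(gm)


@pytest.fixture(scope="module")
def spiked_scan():
    """4000 subjects, 60 SNPs, one spiked interaction (log-OR 0.8)."""
    n = 4000
    cfg = GenoSimConfig(
        n_snps=60, missing_rate=0.01, seed=21,
        causal_snps=(CausalSNP(17, "CRP", 0.1, 0.8),),
        baseline_log_odds=-0.3)
    gm = generate_genotypes(cfg, n)
    rng = np.random.default_rng(22)
    sero = pd.DataFrame({"CRP": rng.normal(0, 1, n)})
    y = assign_disease_by_interaction(gm, sero, cfg)
    age = rng.normal(50, 12, n)
    male = (rng.random(n) < 0.5).astype(float)
    return gm, y, sero["CRP"].to_numpy(), age, male


class TestInteractionModel:
    def test_spiked_interaction_recovered(self, spiked_scan):
        gm, y, sero, age, male = spiked_scan
        r = fit_interaction_model(y, gm.dosages[:, 17], sero, age, male)
        assert r.converged
        assert r.beta_int == pytest.approx(0.8, abs=2 * r.se_int)

    def test_constant_serology_is_degenerate(self, spiked_scan):
        gm, y, _, age, male = spiked_scan
        with pytest.raises(DegenerateDesignError):
            fit_interaction_model(
                y, gm.dosages[:, 3], np.ones_like(y), age, male)

    def test_allele_flip_negates_betas_keeps_p(self, spiked_scan):
        gm, y, sero, age, male = spiked_scan
        g = gm.dosages[:, 17]
        r1 = fit_interaction_model(y, g, sero, age, male)
        r2 = fit_interaction_model(y, 2.0 - g, sero, age, male)
        assert r2.beta_int == pytest.approx(-r1.beta_int, abs=1e-6)
        assert r2.beta_main == pytest.approx(-r1.beta_main, abs=1e-6)
        assert r2.p_int == pytest.approx(r1.p_int, abs=1e-8)

    def test_wald_close_to_likelihood_ratio(self, spiked_scan):
        """Wald and likelihood-ratio interaction tests agree asymptotically
        at n=4000: a null SNP's p-values coincide closely, and the spiked
        SNP's chi-square statistics agree to within the usual higher-order
        divergence of the two tests in the far tail."""
        sm = pytest.importorskip("statsmodels.api")
        gm, y, sero, age, male = spiked_scan

        def both(j):
            g = gm.dosages[:, j]
            ok = ~np.isnan(g)
            X = np.column_stack([np.ones(ok.sum()), g[ok], sero[ok],
                                 g[ok] * sero[ok], age[ok], male[ok]])
            full = sm.Logit(y[ok], X).fit(disp=0)
            red = sm.Logit(y[ok], X[:, [0, 1, 2, 4, 5]]).fit(disp=0)
            lrt_chi2 = 2 * (full.llf - red.llf)
            r = fit_interaction_model(y, g, sero, age, male)
            return (r.beta_int / r.se_int) ** 2, lrt_chi2, r.p_int

        wald_null, lrt_null, p_null = both(3)  # null SNP
        assert p_null == pytest.approx(stats.chi2.sf(lrt_null, 1), abs=0.02)
        wald_alt, lrt_alt, _ = both(17)        # spiked SNP
        assert wald_alt == pytest.approx(lrt_alt, rel=0.2)

    def test_min_rows_enforced(self):
        with pytest.raises(ValueError, match="complete-case"):
            fit_interaction_model(
                np.zeros(30), np.zeros(30), np.zeros(30),
                np.zeros(30), np.zeros(30))


class TestScanGenome:
    def test_spiked_snp_is_top_hit(self, spiked_scan):
        gm, y, sero, age, male = spiked_scan
        res, lam = scan_genome(gm, y, sero, age, male)
        assert res.iloc[0]["snp_id"] == "snp000017"
        assert res.iloc[0]["p_int"] < 1e-8

    def test_null_scan_calibrated(self):
        n = 900
        cfg = GenoSimConfig(n_snps=3000, missing_rate=0.01, seed=31)
        gm = generate_genotypes(cfg, n)
        rng = np.random.default_rng(32)
        y = (rng.random(n) < 0.5).astype(float)
        sero = rng.normal(0, 1, n)
        age = rng.normal(50, 12, n)
        male = (rng.random(n) < 0.5).astype(float)
        res, lam = scan_genome(gm, y, sero, age, male)
        assert 0.9 < lam < 1.1
        assert (res["flag"] == "ok").mean() > 0.99
        ps = res.loc[res["flag"] == "ok", "p_int"]
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestReplication:
    def test_qc_removed_snp_names_filter(self):
        gm = qc_fixture()
        out, rep = qc_genotypes(gm)
        n = out.n_subjects
        args = (np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        with pytest.raises(KeyError, match="maf"):
            replicate_snp(out, "snp000014", *args, qc_report=rep)

    def test_one_sided_beats_two_sided_in_declared_direction(self, spiked_scan):
        gm, y, sero, age, male = spiked_scan
        r = replicate_snp(gm, "snp000017", y, sero, age, male,
                          expected_direction=1)
        assert r["direction_matches"]
        assert r["p_one_sided"] == pytest.approx(r["p_two_sided"] / 2, rel=1e-6)
        r_wrong = replicate_snp(gm, "snp000017", y, sero, age, male,
                                expected_direction=-1)
        assert r_wrong["p_one_sided"] > 0.5


class TestQuantitativeTrait:
    def test_matches_ols_normal_equations_oracle(self):
        rng = np.random.default_rng(41)
        n = 30
        g = rng.integers(0, 3, n).astype(float)
        aff = (rng.random(n) < 0.5).astype(float)
        age = rng.normal(50, 10, n)
        male = (rng.random(n) < 0.5).astype(float)
        y = 0.2 * g + 0.5 * aff + rng.normal(size=n)
        r = qt_association(y, g, aff, age, male)
        X = np.column_stack([np.ones(n), g, aff, age, male])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 5)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert r["beta"] == pytest.approx(beta[1], abs=1e-8)
        assert r["se"] == pytest.approx(se, abs=1e-8)

    def test_spiked_additive_effect_recovered(self):
        n = 1100
        cfg = GenoSimConfig(n_snps=5, maf_range=(0.3, 0.3),
                            missing_rate=0.0, seed=42)
        gm = generate_genotypes(cfg, n)
        rng = np.random.default_rng(43)
        g = gm.dosages[:, 2]
        aff = (rng.random(n) < 0.6).astype(float)
        y = 0.15 * g + 0.3 * aff + rng.normal(0, 1, n)
        r = qt_association(y, g, aff, rng.normal(50, 10, n),
                           (rng.random(n) < 0.5).astype(float))
        assert r["beta"] == pytest.approx(0.15, abs=2 * r["se"])
        assert r["p"] < 0.05


def test_genomic_inflation_of_standard_normals():
    rng = np.random.default_rng(5)
    assert genomic_inflation(rng.standard_normal(200000)) == pytest.approx(
        1.0, abs=0.02)
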