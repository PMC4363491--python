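"""Synthetic cohort and genotype generator.

Generates case-parent-control cohorts with the statistical structure the
downstream analysis assumes, so every stage of the pipeline is testable with
no external data:

* plate-level random intercepts on the log2 assay scale, plus per-year
  storage drift and age/sex effects on every analyte;
* two-component (seronegative/seropositive) log2 mixtures for the three
  bimodal antibody analytes and single near-normal components for the rest;
* group effects versus controls -- additive log2 shifts for continuous
  analytes, seroprevalence log-odds shifts for the bimodal ones, so the
  configured effect sizes live on the same scale the downstream models fit;
* LD-blocked genotypes in Hardy-Weinberg equilibrium via a latent Gaussian
  copula per haplotype, with optional spiked genotype x serology effects on
  disease status.

All randomness flows from the config seeds; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import ANALYTES, BIMODAL_ANALYTES, CONTROL, GROUPS, STATUSES
from .genomat import GenotypeMatrix

# ---------------------------------------------------------------------------
# cohort configuration

#: per-group plasma sample counts of the emulated study population
DEFAULT_GROUP_SIZES = {
    "SZ": 580,
    "SZ_father": 262,
    "SZ_mother": 266,
    "BP": 489,
    "BP_father": 314,
    "BP_mother": 314,
    CONTROL: 362,
}

# age at blood draw (mean, sd) per group; parents older than probands,
# truncated below at 18.  The source cohort reports no age summaries, so
# these are modelling assumptions chosen to make the age covariate
# informative (see docs/methods.md).
DEFAULT_AGE_DIST = {
    "SZ": (42.0, 13.0),
    "BP": (43.0, 13.0),
    "SZ_mother": (60.0, 12.0),
    "SZ_father": (61.0, 12.0),
    "BP_mother": (60.0, 12.0),
    "BP_father": (61.0, 12.0),
    CONTROL: (50.0, 15.0),
}

# per-analyte log2 age slope per year; all positive except HHV6
DEFAULT_AGE_SLOPES = {
    "TOXO": 0.012, "HSV1": 0.012, "CMV": 0.012,
    "HHV6": -0.012, "GLIADIN": 0.008, "CRP": 0.015,
}

# male minus female shift on the log2 scale; lower in males, most strongly
# for HHV6 and CMV
DEFAULT_SEX_SHIFTS = {
    "TOXO": -0.05, "HSV1": -0.05, "CMV": -0.15,
    "HHV6": -0.30, "GLIADIN": -0.05, "CRP": -0.05,
}

# group effects vs controls.  Continuous analytes (HHV6, GLIADIN, CRP):
# additive shift in log2-residual units.  Bimodal analytes (TOXO, HSV1,
# CMV): shift of the seroprevalence log-odds.  Values are the published
# effect estimates of the emulated study, so a faithful re-analysis should
# recover them.
DEFAULT_GROUP_SHIFTS = {
    "TOXO":    {"SZ": -0.02, "SZ_mother": 0.30, "SZ_father": 0.09,
                "BP": 0.04, "BP_mother": 0.10, "BP_father": 0.04},
    "HSV1":    {"SZ": -0.20, "SZ_mother": 0.23, "SZ_father": 0.43,
                "BP": 0.24, "BP_mother": 0.48, "BP_father": 0.41},
    "CMV":     {"SZ": -0.01, "SZ_mother": 0.19, "SZ_father": 0.65,
                "BP": 0.26, "BP_mother": 0.19, "BP_father": 0.48},
    "HHV6":    {"SZ": 0.12, "SZ_mother": 0.17, "SZ_father": 0.20,
                "BP": 0.19, "BP_mother": 0.06, "BP_father": 0.12},
    "GLIADIN": {"SZ": 0.07, "SZ_mother": -0.10, "SZ_father": 0.02,
                "BP": 0.04, "BP_mother": 0.07, "BP_father": 0.04},
    "CRP":     {"SZ": 1.04, "SZ_mother": 0.25, "SZ_father": 0.05,
                "BP": 0.42, "BP_mother": 0.44, "BP_father": 0.20},
}

# (seroprevalence, mu_neg, sd_neg, mu_pos, sd_pos) on the log2 scale.
# Prevalences are set so that the logistic standard errors of the group
# comparisons match the emulated study's reported precision; components are
# well separated so valley thresholding misclassifies ~2% of subjects.
DEFAULT_MIXTURE_PARAMS = {
    "TOXO": (0.13, -1.8, 0.65, 1.6, 0.75),
    "HSV1": (0.75, -2.2, 0.70, 1.5, 0.80),
    "CMV":  (0.78, -2.2, 0.70, 1.5, 0.80),
}

# single-component (mean, sd) for the near-normal analytes; sds chosen so
# the linear-model standard errors match the reported precision
DEFAULT_CONTINUOUS_PARAMS = {
    "HHV6": (0.0, 1.35),
    "GLIADIN": (0.0, 1.20),
    "CRP": (0.0, 1.80),
}


@dataclass
class CohortConfig:
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_plates: int = 32
    # raw ratios are standardized to 1.0 per plate upstream, so residual
    # plate effects are small relative to the assay scales
    plate_sd: float = 0.06
    storage_slope: float = 0.05
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    sex_shifts: dict = field(default_factory=lambda: dict(DEFAULT_SEX_SHIFTS))
    group_shifts: dict = field(
        default_factory=lambda: {a: dict(g) for a, g in DEFAULT_GROUP_SHIFTS.items()}
    )
    mixture_params: dict = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE_PARAMS)
    )
    continuous_params: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS_PARAMS)
    )
    age_dist: dict = field(default_factory=lambda: dict(DEFAULT_AGE_DIST))
    zero_rate: float = 0.005
    # recruitment window and assay reference year drive storage_years
    draw_year_range: tuple = (1996, 2011)
    reference_year: int = 2012
    # optional technical-failure plate: a large location shift on one plate
    outlier_plate: int | None = None
    outlier_shift: float = 0.0
    # extra subjects confined to the outlier plate, emulating records that
    # enter the raw accounting but are lost to the plate exclusion
    n_failed_records: int = 0
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "CohortConfig":
        """The study conditions: 2587 subjects, 32 plates, no failed plate."""
        return cls(seed=seed)

    @classmethod
    def with_failed_plate(cls, seed: int = 0) -> "CohortConfig":
        """Study conditions plus a failed 32nd plate carrying 73 extra
        records, so the raw table holds 2660 records and the analyzed set
        returns to 2587 once the plate is excluded."""
        return cls(seed=seed, outlier_plate=32, outlier_shift=3.0,
                   n_failed_records=73)

    @classmethod
    def null(cls, seed: int = 0, group_size: int = 100,
             n_plates: int = 8) -> "CohortConfig":
        """All effects zero and single-component Gaussians everywhere; used
        for type-I error calibration."""
        zero = {a: 0.0 for a in ANALYTES}
        return cls(
            group_sizes={s: group_size for s in STATUSES},
            n_plates=n_plates,
            plate_sd=0.0,
            storage_slope=0.0,
            age_slopes=dict(zero),
            sex_shifts=dict(zero),
            group_shifts={a: {g: 0.0 for g in GROUPS} for a in ANALYTES},
            mixture_params={},
            continuous_params={a: (0.0, 1.0) for a in ANALYTES},
            zero_rate=0.0,
            seed=seed,
        )

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in STATUSES:
                raise ValueError(f"group_sizes: unknown status label {g!r}")
            if n < 0:
                raise ValueError(f"group_sizes[{g!r}] = {n} must be >= 0")
        if self.n_plates < 1:
            raise ValueError(f"n_plates = {self.n_plates} must be >= 1")
        if self.plate_sd < 0:
            raise ValueError(f"plate_sd = {self.plate_sd} must be >= 0")
        if not 0 <= self.zero_rate < 1:
            raise ValueError(f"zero_rate = {self.zero_rate} must be in [0,1)")
        for a, p in self.mixture_params.items():
            prev, mu_n, sd_n, mu_p, sd_p = p
            if not 0 < prev < 1:
                raise ValueError(
                    f"mixture_params[{a!r}]: seroprevalence {prev} not in (0,1)")
            if sd_n <= 0 or sd_p <= 0:
                raise ValueError(f"mixture_params[{a!r}]: sds must be > 0")
            if mu_p <= mu_n:
                raise ValueError(
                    f"mixture_params[{a!r}]: positive mean {mu_p} must exceed "
                    f"negative mean {mu_n}")
        for a, (mu, sd) in self.continuous_params.items():
            if sd <= 0:
                raise ValueError(f"continuous_params[{a!r}]: sd must be > 0")
        if self.n_failed_records and self.outlier_plate is None:
            raise ValueError(
                "n_failed_records requires outlier_plate to be set")


def generate_cohort(
    config: CohortConfig, return_truth: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate subject records and raw assay panels.

    Returns ``(subjects, assays)`` -- and the latent truth table (plate
    effects removed, per-analyte latent seropositivity) when
    ``return_truth`` is set.  The raw assay value for analyte *a* of subject
    *i* is ``2 ** latent`` where the latent log2 value sums the component
    draw, group/age/sex effects, the plate random intercept and the storage
    drift; a small fraction of values is then zeroed to emulate failed
    assays.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    statuses: list[str] = []
    for g, n in config.group_sizes.items():
        statuses.extend([g] * n)
    n_regular = len(statuses)

    # technical-failure records drawn proportionally across groups
    if config.n_failed_records:
        labels = list(config.group_sizes)
        probs = np.array([config.group_sizes[g] for g in labels], dtype=float)
        probs /= probs.sum()
        extra = rng.choice(labels, size=config.n_failed_records, p=probs)
        statuses.extend(extra.tolist())
    n = len(statuses)
    status = np.array(statuses)

    sex = np.empty(n, dtype=object)
    mother = np.char.endswith(status.astype(str), "_mother")
    father = np.char.endswith(status.astype(str), "_father")
    other = ~(mother | father)
    sex[mother] = "female"
    sex[father] = "male"
    sex[other] = rng.choice(["male", "female"], size=int(other.sum()))

    age = np.empty(n)
    for g in np.unique(status):
        mask = status == g
        mu, sd = config.age_dist.get(g, (45.0, 15.0))
        age[mask] = np.maximum(rng.normal(mu, sd, mask.sum()), 18.0)
    age = np.round(age, 1)

    lo, hi = config.draw_year_range
    draw_year = rng.integers(lo, hi + 1, size=n)
    storage = (config.reference_year - draw_year).astype(float)

    # plates: uniform assignment; when failed records exist they sit on the
    # outlier plate and regular subjects avoid it (the failed plate is a
    # distinct physical batch)
    plates = np.arange(1, config.n_plates + 1)
    if config.n_failed_records:
        usable = plates[plates != config.outlier_plate]
        plate = np.empty(n, dtype=int)
        plate[:n_regular] = rng.choice(usable, size=n_regular)
        plate[n_regular:] = config.outlier_plate
    else:
        plate = rng.choice(plates, size=n)

    male = (sex == "male").astype(float)
    age_c = age - 45.0
    storage_c = storage - storage.mean()

    assay = {}
    truth = {}
    for a in ANALYTES:
        # each analyte is assayed in its own pass over the plates, so plate
        # intercepts are independent across analytes
        plate_eff = rng.normal(0.0, config.plate_sd, config.n_plates)
        if config.outlier_plate is not None:
            plate_eff[config.outlier_plate - 1] += config.outlier_shift
        base = (
            config.age_slopes.get(a, 0.0) * age_c
            + config.sex_shifts.get(a, 0.0) * male
            + config.storage_slope * storage_c
            + plate_eff[plate - 1]
        )
        if a in config.mixture_params:
            prev, mu_n, sd_n, mu_p, sd_p = config.mixture_params[a]
            logit = special.logit(prev) * np.ones(n)
            shifts = config.group_shifts.get(a, {})
            for g, s in shifts.items():
                logit[status == g] += s
            pos = rng.random(n) < special.expit(logit)
            comp = np.where(
                pos,
                rng.normal(mu_p, sd_p, n),
                rng.normal(mu_n, sd_n, n),
            )
            latent = comp + base
            truth[f"seropositive_{a}"] = pos.astype(int)
        else:
            mu, sd = config.continuous_params.get(a, (0.0, 1.0))
            shift = np.zeros(n)
            for g, s in config.group_shifts.get(a, {}).items():
                shift[status == g] = s
            latent = mu + shift + rng.normal(0.0, sd, n) + base
        raw = np.power(2.0, latent)
        if config.zero_rate > 0:
            raw[rng.random(n) < config.zero_rate] = 0.0
        assay[a] = raw
        truth[f"latent_{a}"] = latent

    ids = np.array([f"S{i:04d}" for i in range(1, n + 1)])
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "status": status,
            "sex": sex,
            "age_at_draw": age,
            "plate": plate,
            "storage_years": storage,
        }
    )
    assays = pd.DataFrame({"subject_id": ids, **assay})
    if return_truth:
        return subjects, assays, pd.DataFrame({"subject_id": ids, **truth})
    return subjects, assays


# ---------------------------------------------------------------------------
# genotypes

@dataclass(frozen=True)
class CausalSNP:
    """A spiked genotype (x serology) effect on disease status."""
    snp_index: int
    analyte: str
    main: float = 0.0        # log-OR per minor allele
    interaction: float = 0.0  # log-OR per (allele x serology unit)


@dataclass
class GenoSimConfig:
    n_snps: int
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.0
    missing_rate: float = 0.01
    causal_snps: tuple = ()
    baseline_log_odds: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError(f"n_snps = {self.n_snps} must be >= 1")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError(
                f"maf_range = {self.maf_range} must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError(f"ld_rho = {self.ld_rho} must be in [0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(
                f"missing_rate = {self.missing_rate} must be in [0,1)")
        if self.ld_block_size < 1:
            raise ValueError(f"ld_block_size = {self.ld_block_size} must be >= 1")


_BASES = np.array(list("ACGT"))


def generate_genotypes(config: GenoSimConfig, subjects) -> GenotypeMatrix:
    """LD-blocked genotypes in HWE before missingness.

    Each haplotype is an independent latent AR(1) Gaussian within an LD
    block (adjacent-SNP correlation ``ld_rho``), thresholded at the normal
    quantile of the allele frequency.  Dosage is the sum of the two
    haplotypes, so HWE holds per SNP by construction.
    """
    config.validate()
    if isinstance(subjects, int):
        n = subjects
        ids = np.array([f"S{i:04d}" for i in range(1, n + 1)])
    else:
        if len(subjects) == 0:
            raise ValueError("subjects is empty")
        n = len(subjects)
        ids = subjects["subject_id"].to_numpy()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf)

    rho = config.ld_rho
    hap = np.empty((2 * n, m))
    bsize = config.ld_block_size
    prev_col = None
    for j in range(m):
        eps = rng.standard_normal(2 * n)
        if j % bsize == 0 or rho == 0.0:
            col = eps
        else:
            col = rho * prev_col + np.sqrt(1.0 - rho * rho) * eps
        hap[:, j] = col
        prev_col = col
    alleles = (hap < thresh[None, :]).astype(np.int8)
    dos = (alleles[0::2] + alleles[1::2]).astype(float)

    if config.missing_rate > 0:
        dos[rng.random((n, m)) < config.missing_rate] = np.nan

    block = np.arange(m) // bsize
    chrom = (block % 22) + 1
    # positions increase within chromosome, 5 kb spacing
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 10_000 + 5_000 * np.arange(idx.size)
    a1 = rng.integers(0, 4, size=m)
    a2 = (a1 + rng.integers(1, 4, size=m)) % 4
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele1": _BASES[a1],
            "allele2": _BASES[a2],
        }
    )
    return GenotypeMatrix(dos, ids, snps)


def assign_disease_by_interaction(
    gm: GenotypeMatrix,
    serology: pd.DataFrame,
    config: GenoSimConfig,
) -> np.ndarray:
    """Draw binary case/control labels from a logistic model with spiked
    genotype main effects and genotype x serology interactions.

    ``serology`` holds one column per analyte referenced by
    ``config.causal_snps`` (residual scale or 0/1 serostatus), row-aligned
    with ``gm``.  Missing dosages contribute their SNP's mean dosage, so the
    linear predictor is defined for every subject.
    """
    config.validate()
    n = gm.n_subjects
    if len(serology) != n:
        raise ValueError(
            f"serology has {len(serology)} rows for {n} subjects")
    eta = np.full(n, config.baseline_log_odds, dtype=float)
    for c in config.causal_snps:
        if not 0 <= c.snp_index < gm.n_snps:
            raise ValueError(f"causal SNP index {c.snp_index} out of range")
        if c.analyte not in serology.columns:
            raise KeyError(
                f"analyte {c.analyte!r} not in serology columns "
                f"{list(serology.columns)}")
        g = gm.dosages[:, c.snp_index].copy()
        g[np.isnan(g)] = np.nanmean(g)
        s = serology[c.analyte].to_numpy(dtype=float)
        eta += c.main * g + c.interaction * g * s
    rng = np.random.default_rng(config.seed + 1)
    return (rng.random(n) < special.expit(eta)).astype(int)
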