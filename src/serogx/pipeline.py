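"""End-to-end orchestration: clean -> binarize -> compare -> enrich ->
scan -> region-enrich, with per-stage TSV reports and JSON provenance
sidecars.  Re-running with the same config and seeds reproduces every
report byte for byte."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ANALYTES, CONTROL, __version__
from .cleaning import clean_serology
from .compare import build_analysis_dataset, build_table
from .enrich import enrichment_test
from .io import read_ped_map, read_serology_table, read_snp_set
from .mixture import STUDY_PINNING, decide_all
from .regionset import region_enrichment_test
from .scan import qc_genotypes, scan_genome

log = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the global seed
_SEED_OFFSETS = {"enrich": 101, "region": 202}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    serology_path: str
    out_dir: str
    genotype_prefix: str | None = None
    stages: tuple = ("clean", "binarize", "compare", "enrich")
    alpha: float = 0.05
    n_perm_enrich: int = 3000
    n_perm_region: int = 5000
    suggestive_alpha: float = 1e-5
    scan_phenotype: str = "SZ"       # case group scanned against controls
    scan_serology: str = "HSV1"
    snp_set_path: str | None = None
    pin_analytes: bool = True        # pin the study's binary/continuous split
    seed: int = 0

    def validate(self) -> None:
        known = ("clean", "binarize", "compare", "enrich", "scan",
                 "region-enrich")
        for s in self.stages:
            if s not in known:
                raise ValueError(f"unknown stage {s!r}")
        order = {s: i for i, s in enumerate(known)}
        idx = [order[s] for s in self.stages]
        if idx != sorted(idx):
            raise ValueError("stages must appear in pipeline order")
        needs_geno = {"scan", "region-enrich"} & set(self.stages)
        if needs_geno and not self.genotype_prefix:
            raise ValueError(f"stages {needs_geno} require genotype_prefix")
        if "region-enrich" in self.stages and not self.snp_set_path:
            raise ValueError("region-enrich requires snp_set_path")


def _write(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    provenance = {"version": __version__, "n_rows": len(df), **provenance}
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; each writes a TSV report plus a
    provenance sidecar into ``out_dir``.  A stage failure halts the run
    with the failing stage named; earlier outputs are retained."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    subjects, assays = read_serology_table(config.serology_path)
    results["n_records_input"] = len(subjects)

    def _stage(name):
        return name in config.stages

    cleaning = None
    if _stage("clean"):
        try:
            cleaning = clean_serology(subjects, assays, alpha=config.alpha)
        except Exception as e:           # noqa: BLE001 - named stage failure
            raise StageError("clean", e) from e
        _write(cleaning.report_frame(), out / "cleaning_report.tsv",
               {"stage": "clean", "input": str(config.serology_path),
                "flagged_plates": cleaning.outlier_report.flagged,
                "n_input": cleaning.n_input,
                "n_excluded_plate": cleaning.n_excluded_plate})
        _write(cleaning.residuals, out / "residuals.tsv",
               {"stage": "clean", "input": str(config.serology_path)})
        results["cleaning"] = cleaning

    decisions = None
    if _stage("binarize"):
        if cleaning is None:
            raise StageError("binarize", ValueError("clean stage disabled"))
        try:
            pin = STUDY_PINNING if config.pin_analytes else None
            decisions = decide_all(cleaning.residuals, pinned=pin,
                                   keep_curve=True)
        except Exception as e:
            raise StageError("binarize", e) from e
        rows, curves = [], []
        for a in ANALYTES:
            d = decisions[a]
            rows.append({
                "analyte": a, "is_bimodal": d.is_bimodal,
                "threshold": d.threshold if d.is_bimodal else "",
                "peak_low": d.peaks[0] if d.peaks else "",
                "peak_high": d.peaks[1] if d.peaks else "",
                "bandwidth": d.bandwidth})
            if d.grid is not None:
                curves.append(pd.DataFrame(
                    {"analyte": a, "x": d.grid, "density": d.density}))
        _write(pd.DataFrame(rows), out / "binarize_report.tsv",
               {"stage": "binarize", "pinned": config.pin_analytes})
        if curves:
            _write(pd.concat(curves, ignore_index=True),
                   out / "density_curves.tsv", {"stage": "binarize"})
        results["decisions"] = decisions

    dataset = None
    if decisions is not None:
        dataset = build_analysis_dataset(
            cleaning.subjects, cleaning.residuals, decisions)
        results["dataset"] = dataset

    if _stage("compare"):
        if dataset is None:
            raise StageError("compare", ValueError("binarize stage disabled"))
        try:
            table = build_table(dataset)
        except Exception as e:
            raise StageError("compare", e) from e
        _write(table, out / "comparison_table.tsv", {"stage": "compare"})
        results["table"] = table

    if _stage("enrich"):
        if dataset is None:
            raise StageError("enrich", ValueError("binarize stage disabled"))
        seed = config.seed + _SEED_OFFSETS["enrich"]
        try:
            enr = enrichment_test(
                dataset, alpha=config.alpha, n_perm=config.n_perm_enrich,
                seed=seed)
        except Exception as e:
            raise StageError("enrich", e) from e
        qs = np.percentile(enr.perm_n_sig, [50, 95, 99])
        qd = np.percentile(enr.perm_n_dir, [50, 95, 99])
        _write(pd.DataFrame([{
            "observed_n_sig": enr.observed_n_sig,
            "observed_n_dir": enr.observed_n_dir,
            "p_sig": enr.p_sig, "p_dir": enr.p_dir,
            "n_perm": enr.n_perm, "alpha": enr.alpha,
            "perm_n_sig_q50": qs[0], "perm_n_sig_q95": qs[1],
            "perm_n_sig_q99": qs[2],
            "perm_n_dir_q50": qd[0], "perm_n_dir_q95": qd[1],
            "perm_n_dir_q99": qd[2],
        }]), out / "enrichment.tsv",
            {"stage": "enrich", "seed": seed,
             "n_excluded": enr.n_excluded})
        results["enrichment"] = enr

    gm_qc = None
    qc_rep = None
    if _stage("scan") or _stage("region-enrich"):
        gm, fam = read_ped_map(config.genotype_prefix)
        # scan is case-control: selected case group plus controls only
        merged = cleaning.subjects if cleaning else subjects
        order = {s: i for i, s in enumerate(gm.subject_ids)}
        keep_status = merged[
            merged["status"].isin([config.scan_phenotype, CONTROL])]
        keep_ids = [s for s in keep_status["subject_id"] if s in order]
        mask = np.isin(gm.subject_ids, keep_ids)
        gm_cc = gm.subset(subject_mask=mask)
        gm_qc, qc_rep = qc_genotypes(gm_cc)
        _write(qc_rep.frame(), out / "genotype_qc.tsv",
               {"stage": "scan", "input": str(config.genotype_prefix),
                "n_snps_in": qc_rep.n_snps_in,
                "n_snps_out": qc_rep.n_snps_out,
                "n_subjects_in": qc_rep.n_subjects_in,
                "n_subjects_out": qc_rep.n_subjects_out})
        # align covariates to the QC'd matrix
        meta = merged.set_index("subject_id").loc[gm_qc.subject_ids]
        pheno = (meta["status"] == config.scan_phenotype).to_numpy(float)
        male = (meta["sex"] == "male").to_numpy(float)
        age = meta["age_at_draw"].to_numpy(float)
        feat = dataset.frame.set_index("subject_id")[config.scan_serology] \
            .reindex(gm_qc.subject_ids).to_numpy(float) if dataset is not None \
            else None
        if feat is None:
            raise StageError(
                "scan", ValueError("scan requires the binarize stage"))
        results["qc_report"] = qc_rep

    if _stage("scan"):
        try:
            res, lam = scan_genome(
                gm_qc, pheno, feat, age, male,
                serology_name=config.scan_serology,
                phenotype_name=config.scan_phenotype,
                suggestive_alpha=config.suggestive_alpha)
        except Exception as e:
            raise StageError("scan", e) from e
        _write(res, out / "scan_results.tsv",
               {"stage": "scan", "lambda_gc": lam,
                "phenotype": config.scan_phenotype,
                "serology": config.scan_serology})
        results["scan"] = res
        results["lambda_gc"] = lam

    if _stage("region-enrich"):
        seed = config.seed + _SEED_OFFSETS["region"]
        try:
            snp_set = read_snp_set(config.snp_set_path)
            reg = region_enrichment_test(
                gm_qc, snp_set, pheno, feat, age, male,
                alpha=config.alpha, n_perm=config.n_perm_region, seed=seed,
                correction_factor=len(ANALYTES))
        except Exception as e:
            raise StageError("region-enrich", e) from e
        _write(pd.DataFrame([{
            "n_snps": reg.n_tested, "observed_hits": reg.observed_hits,
            "hit_fraction": reg.hit_fraction,
            "p_empirical": reg.p_empirical, "p_corrected": reg.p_corrected,
            "n_perm": reg.n_perm, "alpha": reg.alpha,
        }]), out / "region_enrichment.tsv",
            {"stage": "region-enrich", "seed": seed,
             "snp_set": str(config.snp_set_path)})
        results["region"] = reg

    return results
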