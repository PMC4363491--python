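"""Readers and writers for the package's text formats.

* the tab-separated serology table (subject covariates + 6 raw assay ratios);
  a raw value of ``0`` means a failed assay, an empty field means missing;
* PLINK PED/MAP text genotypes (additive minor-allele dosages on read);
* one-ID-per-line SNP set files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ANALYTES, SEXES, STATUSES
from .genomat import GenotypeMatrix

SEROLOGY_COLUMNS = (
    "subject_id", "status", "sex", "age_at_draw", "plate", "storage_years",
) + ANALYTES


class TableFormatError(ValueError):
    pass


def write_serology_table(subjects: pd.DataFrame, assays: pd.DataFrame, path) -> None:
    df = subjects.merge(assays, on="subject_id", how="left")
    df = df[list(SEROLOGY_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_serology_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse and validate the serology table.

    Returns ``(subjects, assays)``.  Assay fields distinguish ``0`` (failed
    assay, kept as raw value 0.0) from an empty field (missing, NaN).
    Malformed rows are reported with their 1-based line number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(SEROLOGY_COLUMNS):
            raise TableFormatError(
                f"bad header: expected {list(SEROLOGY_COLUMNS)}, got {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(SEROLOGY_COLUMNS):
                raise TableFormatError(
                    f"line {lineno}: expected {len(SEROLOGY_COLUMNS)} fields, "
                    f"got {len(parts)}")
            rec = dict(zip(SEROLOGY_COLUMNS, parts))
            if rec["status"] not in STATUSES:
                raise TableFormatError(
                    f"line {lineno}: unknown status {rec['status']!r}")
            if rec["sex"] not in SEXES:
                raise TableFormatError(
                    f"line {lineno}: unknown sex {rec['sex']!r}")
            try:
                rec["age_at_draw"] = float(rec["age_at_draw"])
                rec["plate"] = int(rec["plate"])
                rec["storage_years"] = float(rec["storage_years"])
                for a in ANALYTES:
                    v = rec[a]
                    rec[a] = np.nan if v == "" else float(v)
                    if rec[a] < 0:
                        raise ValueError(f"negative assay ratio {rec[a]}")
            except ValueError as e:
                raise TableFormatError(f"line {lineno}: {e}") from None
            if rec["age_at_draw"] <= 0:
                raise TableFormatError(
                    f"line {lineno}: age_at_draw must be > 0")
            rows.append(rec)
    df = pd.DataFrame(rows, columns=list(SEROLOGY_COLUMNS))
    dup = df["subject_id"].duplicated()
    if dup.any():
        raise TableFormatError(
            f"duplicate subject IDs: {sorted(df.loc[dup, 'subject_id'])}")
    subjects = df[list(SEROLOGY_COLUMNS[:6])].copy()
    assays = df[["subject_id", *ANALYTES]].copy()
    return subjects, assays


# ---------------------------------------------------------------------------
# PLINK PED/MAP text

_SEX_TO_PED = {"male": "1", "female": "2"}


def write_ped_map(
    gm: GenotypeMatrix,
    prefix: str,
    sex: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
) -> None:
    """Write ``prefix.ped`` and ``prefix.map``.

    ``phenotype`` uses PED case/control coding on write: 1=control, 2=case,
    -9=missing.  ``allele1`` (the counted allele) and ``allele2`` come from
    the SNP metadata; missing calls are written as ``0 0``.
    """
    snps = gm.snps
    with open(f"{prefix}.map", "w") as fh:
        for r in snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    a1 = snps["allele1"].to_numpy()
    a2 = snps["allele2"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(gm.subject_ids):
            sx = _SEX_TO_PED.get(sex[i], "0") if sex is not None else "0"
            if phenotype is None:
                ph = "-9"
            else:
                ph = "-9" if phenotype[i] < 0 else str(int(phenotype[i]) + 1)
            fields = [str(sid), str(sid), "0", "0", sx, ph]
            row = gm.dosages[i]
            for j in range(gm.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write("\t".join(fields) + "\n")


def read_ped_map(prefix: str) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read ``prefix.ped`` + ``prefix.map`` into additive dosages.

    The counted allele per SNP is the empirically minor one (ties broken
    toward the lexicographically smaller allele).  Returns the matrix and a
    per-subject frame with PED sex/phenotype fields decoded.
    """
    snps = pd.read_csv(
        f"{prefix}.map", sep="\t", header=None,
        names=["chrom", "snp_id", "cm", "pos"],
    )
    m = len(snps)
    ids, sexes, phenos = [], [], []
    geno_rows = []
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise TableFormatError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            ids.append(parts[1])
            sexes.append({"1": "male", "2": "female"}.get(parts[4], "unknown"))
            phenos.append(parts[5])
            geno_rows.append(parts[6:])
    alleles = np.array(geno_rows).reshape(len(ids), m, 2)

    n = len(ids)
    dosages = np.full((n, m), np.nan)
    a1_out = np.empty(m, dtype=object)
    a2_out = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        valid = col[:, 0] != "0"
        vals, counts = np.unique(col[valid], return_counts=True)
        if vals.size == 0:
            a1_out[j], a2_out[j] = "0", "0"
            continue
        if vals.size == 1:
            minor, major = vals[0], vals[0]
        else:
            order = np.lexsort((vals, counts))  # by count, then allele name
            minor, major = vals[order[0]], vals[order[-1]]
        a1_out[j], a2_out[j] = minor, major
        dosages[valid, j] = (col[valid] == minor).sum(axis=1)
    snps_out = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "allele1": a1_out,
            "allele2": a2_out,
        }
    )
    pheno_num = pd.Series(phenos).map({"1": 0, "2": 1}).to_numpy(dtype=float)
    fam = pd.DataFrame(
        {"subject_id": ids, "sex": sexes, "phenotype": pheno_num})
    return GenotypeMatrix(dosages, np.array(ids), snps_out), fam


def read_snp_set(path) -> list[str]:
    """One SNP ID per line; blank lines and ``#`` comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s.split()[0])
    return out
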