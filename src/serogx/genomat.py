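"""Additively coded genotype matrix with SNP metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosages.

    ``dosages`` is a float array of shape (n_subjects, n_snps) with values in
    {0, 1, 2} and NaN for missing calls.  ``snps`` carries one row per SNP:
    ``snp_id``, ``chrom``, ``pos``, ``allele1`` (the counted allele) and
    ``allele2``.
    """

    dosages: np.ndarray
    subject_ids: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        if self.dosages.shape != (len(self.subject_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP IDs")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snps["snp_id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in matrix")
        return int(hits[0])

    def maf(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele over non-missing calls,
        folded to the minor side."""
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def snp_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def subject_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def subset(
        self,
        subject_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        d = self.dosages
        ids = self.subject_ids
        snps = self.snps
        if subject_mask is not None:
            d = d[subject_mask]
            ids = ids[subject_mask]
        if snp_mask is not None:
            d = d[:, snp_mask]
            snps = snps.loc[snp_mask].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), ids.copy(), snps.copy())
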