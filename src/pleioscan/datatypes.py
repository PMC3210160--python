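"""Core in-memory containers shared across the toolkit.

Genotypes live in a :class:`GenotypeDataset`: an ``n_samples x n_snps``
dosage matrix counting copies of the designated minor allele (0/1/2,
``NaN`` for missing), plus per-SNP and per-sample metadata tables.
Phenotypes and covariates are plain :class:`pandas.DataFrame` objects
with a ``sample_id`` column; the required trait-table columns are
documented where each producer/consumer lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every SNP metadata table must carry.
SNP_COLUMNS = ["snp_id", "chrom", "pos", "minor_allele", "major_allele"]


@dataclass
class GenotypeDataset:
    """Genotypes for ``n`` samples at ``m`` biallelic SNPs.

    Parameters
    ----------
    dosages
        Float array of shape ``(n, m)``; entry ``(i, j)`` counts copies of
        the designated minor allele of SNP ``j`` in sample ``i`` (0, 1 or 2).
        ``NaN`` marks a missing genotype.
    snps
        Metadata with at least :data:`SNP_COLUMNS`; optional extra columns
        (``block_id``, QC flags, ...) are preserved by subsetting.
    samples
        One row per sample with a ``sample_id`` column; a ``subpop`` column,
        when present, records simulated subpopulation labels.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x SNPs) array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n} dosage rows"
            )
        if len(self.snps) != m:
            raise ValueError(
                f"SNP table has {len(self.snps)} rows for {m} dosage columns"
            )
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"SNP table lacks required columns: {missing_cols}")
        if self.snps["snp_id"].duplicated().any():
            dupes = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dupes))}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps["snp_id"])

    def snp_index(self, snp_id: str) -> int:
        """Column index of ``snp_id``; raises ``KeyError`` naming the SNP."""
        hits = np.flatnonzero((self.snps["snp_id"] == snp_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"unknown SNP id: {snp_id!r}")
        return int(hits[0])

    def dosage(self, snp_id: str) -> np.ndarray:
        """Dosage vector (length ``n_samples``) for one SNP."""
        return self.dosages[:, self.snp_index(snp_id)]

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per SNP over non-missing calls.

        The frequency of the *designated* minor allele; may exceed 0.5 for
        simulated subpopulation data or after subsetting.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to SNP columns where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            dosages=self.dosages[:, mask],
            snps=self.snps.loc[mask].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            dosages=self.dosages[mask, :],
            snps=self.snps.copy(),
            samples=self.samples.loc[mask].reset_index(drop=True),
        )
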