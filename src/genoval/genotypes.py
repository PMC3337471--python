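"""Genotype dosage matrix container.

Dosages are real-valued allele counts in [0, 2] (integer after gene drop,
possibly fractional after probability-based imputation); missing cells are
NaN. Rows follow ``animal_ids``, columns ``snp_ids``; ``chrom`` carries a
per-SNP chromosome label used only by the sex-chromosome exclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class GenotypeMatrix:
    animal_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    _row: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNP"
            )
        if self.chrom is None:
            self.chrom = np.full(len(self.snp_ids), "1", dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
            if len(self.chrom) != len(self.snp_ids):
                raise DataError("chrom labels do not match SNP count")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"dosage out of [0, 2]: animal {self.animal_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}, value {self.dosages[i, j]}"
            )
        self._row = {tok: i for i, tok in enumerate(self.animal_ids)}
        if len(self._row) != self.n_animals:
            raise DataError("duplicate animal ids in genotype matrix")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def row_positions(self, tokens) -> np.ndarray:
        try:
            return np.asarray([self._row[str(t)] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"animal {exc.args[0]!r} not genotyped") from None

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing dosages."""
        return np.isnan(self.dosages).mean(axis=0)

    def subset_animals(self, tokens) -> "GenotypeMatrix":
        rows = self.row_positions(tokens)
        return GenotypeMatrix(
            self.animal_ids[rows], self.snp_ids, self.dosages[rows], self.chrom
        )

    def subset_snps(self, keep) -> "GenotypeMatrix":
        """Subset columns by boolean mask or positional index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool and keep.shape != (self.n_snp,):
            raise DataError("boolean SNP mask has wrong length")
        return GenotypeMatrix(
            self.animal_ids,
            self.snp_ids[keep],
            self.dosages[:, keep],
            self.chrom[keep],
        )
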