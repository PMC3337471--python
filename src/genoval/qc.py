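"""Two-stage SNP quality control and Mendelian dosage imputation.

Stage 1 (raw-chip editing) drops sex-chromosome SNP, SNP with more than 10%
missing genotypes, and SNP with minor allele frequency below 0.001. Stage 2
(pre-analysis editing, applied after imputation) drops SNP with MAF below
0.02 or a Hardy-Weinberg Pearson chi-squared statistic above 300. All
inequalities are strict. Each dropped SNP gets exactly one drop reason with
precedence chrom > missing > maf > chi2.

Imputation fills each missing cell with the sum of the two parental
transmitted-allele probabilities (a real dosage in [0, 2]): a parent with
observed dosage g transmits the counted allele with probability g/2; an
unknown or un-genotyped parent falls back to the population allele
frequency. The pass is single and non-iterative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError, DataError
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree


@dataclass
class QcThresholds:
    maf_min_stage1: float = 0.001
    missing_max: float = 0.10
    exclude_chroms: tuple = ("X", "Y")
    maf_min_stage2: float = 0.02
    chi2_max: float = 300.0

    def __post_init__(self) -> None:
        for v in (self.maf_min_stage1, self.maf_min_stage2):
            if not 0.0 <= v < 0.5:
                raise ConfigurationError("MAF thresholds must lie in [0, 0.5)")
        if not 0.0 <= self.missing_max <= 1.0:
            raise ConfigurationError("missing_max must lie in [0, 1]")
        if self.chi2_max <= 0.0:
            raise ConfigurationError("chi2_max must be > 0")


@dataclass
class QcReport:
    table: pd.DataFrame  # snp_id, maf, missing_fraction, chi2, drop_reason
    stage: int
    n_input: int = field(default=0)
    n_retained: int = field(default=0)

    def __post_init__(self) -> None:
        self.n_input = len(self.table)
        self.n_retained = int((self.table["drop_reason"] == "none").sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP over non-missing dosages.

    SNP with every entry missing get NaN (flagged undefined; such SNP are
    auto-dropped by the filters).
    """
    D = geno.dosages
    observed = ~np.isnan(D)
    counts = observed.sum(axis=0)
    sums = np.where(observed, D, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    return freq


def minor_allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    freq = allele_frequency(geno)
    return np.minimum(freq, 1.0 - freq)


def hwe_chi2(geno: GenotypeMatrix) -> np.ndarray:
    """Pearson chi-squared for deviation from expected genotype proportions.

    Real-valued dosages are rounded half-up to genotype classes {0, 1, 2}
    for counting. Monomorphic SNP get statistic 0 (no deviation possible).
    """
    D = geno.dosages
    classes = np.floor(D + 0.5)  # half-up; NaN stays NaN
    n0 = np.nansum(classes == 0, axis=0).astype(float)
    n1 = np.nansum(classes == 1, axis=0).astype(float)
    n2 = np.nansum(classes == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2.0 * n2) / (2.0 * n)
    chi2 = np.zeros(geno.n_snp)
    ok = (n > 0) & (p > 0.0) & (p < 1.0)
    q = 1.0 - p[ok]
    exp = np.stack(
        [n[ok] * q * q, 2.0 * n[ok] * p[ok] * q, n[ok] * p[ok] * p[ok]]
    )
    obs = np.stack([n0[ok], n1[ok], n2[ok]])
    chi2[ok] = np.sum((obs - exp) ** 2 / exp, axis=0)
    return chi2


def filter_snps(
    geno: GenotypeMatrix, thr: QcThresholds | None = None, stage: int = 1
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply one filtering stage, returning the retained matrix and a report."""
    thr = thr or QcThresholds()
    if stage not in (1, 2):
        raise ConfigurationError("stage must be 1 or 2")
    maf = minor_allele_frequency(geno)
    miss = geno.missing_fraction()
    chi2 = hwe_chi2(geno) if stage == 2 else np.full(geno.n_snp, np.nan)

    reason = np.full(geno.n_snp, "none", dtype=object)
    if stage == 1:
        # precedence: chrom > missing > maf
        sel = np.isin(geno.chrom, thr.exclude_chroms)
        reason[sel & (reason == "none")] = "chrom"
        sel = (miss > thr.missing_max) | np.isnan(maf)
        reason[sel & (reason == "none")] = "missing"
        sel = maf < thr.maf_min_stage1
        reason[sel & (reason == "none")] = "maf"
    else:
        sel = np.isnan(maf) | (maf < thr.maf_min_stage2)
        reason[sel & (reason == "none")] = "maf"
        sel = chi2 > thr.chi2_max
        reason[sel & (reason == "none")] = "chi2"

    report = QcReport(
        pd.DataFrame(
            {
                "snp_id": geno.snp_ids,
                "maf": maf,
                "missing_fraction": miss,
                "chi2": chi2,
                "drop_reason": reason,
            }
        ),
        stage=stage,
    )
    keep = reason == "none"
    if not keep.any():
        err = DataError(f"stage-{stage} filtering removed every SNP")
        err.report = report
        raise err
    return geno.subset_snps(keep), report


def impute_dosages(
    geno: GenotypeMatrix, ped: Pedigree, freq: np.ndarray | None = None
) -> GenotypeMatrix:
    """Fill missing dosages from parental allele probabilities.

    Always resolvable: animals absent from the pedigree, or with unknown or
    un-genotyped parents, fall back to 2x the population frequency for the
    affected transmission. Previously observed entries are left untouched.
    """
    if freq is None:
        freq = allele_frequency(geno)
    freq = np.asarray(freq, dtype=float)
    if np.isnan(freq).any():
        raise DataError("allele frequency undefined for some SNP; filter first")
    D = geno.dosages
    missing = np.isnan(D)
    if not missing.any():
        return geno

    # transmitted-allele probability per genotyped animal/SNP
    T = np.where(missing, freq, D / 2.0)

    n = geno.n_animals
    sire_row = np.full(n, -1, dtype=np.int64)
    dam_row = np.full(n, -1, dtype=np.int64)
    row_of = {tok: i for i, tok in enumerate(geno.animal_ids)}
    for i, tok in enumerate(geno.animal_ids):
        stok = str(tok)
        if stok not in ped:
            continue
        p = ped.positions([stok])[0]
        for par, out in ((ped.sire[p], sire_row), (ped.dam[p], dam_row)):
            if par >= 0:
                out[i] = row_of.get(ped.ids[par], -1)

    freq_row = np.broadcast_to(freq, D.shape)
    t_sire = np.where((sire_row >= 0)[:, None], T[np.maximum(sire_row, 0)], freq_row)
    t_dam = np.where((dam_row >= 0)[:, None], T[np.maximum(dam_row, 0)], freq_row)
    sap = np.clip(t_sire + t_dam, 0.0, 2.0)

    out = np.where(missing, sap, D)
    return GenotypeMatrix(geno.animal_ids, geno.snp_ids, out, geno.chrom)


class SnpFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper over :func:`filter_snps` (one stage).

    ``fit`` computes the per-SNP statistics into ``report_``; ``transform``
    drops the flagged columns.
    """

    def __init__(self, stage: int = 1, thresholds: QcThresholds | None = None):
        self.stage = stage
        self.thresholds = thresholds

    def fit(self, X: GenotypeMatrix, y=None):
        _, self.report_ = filter_snps(X, self.thresholds, self.stage)
        self.keep_snp_ids_ = self.report_.table.loc[
            self.report_.table["drop_reason"] == "none", "snp_id"
        ].to_numpy(dtype=object)
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        keep = np.isin(X.snp_ids, self.keep_snp_ids_)
        return X.subset_snps(keep)


class MendelianImputer(BaseEstimator, TransformerMixin):
    """Estimator wrapper over :func:`impute_dosages`."""

    def __init__(self, pedigree: Pedigree | None = None):
        self.pedigree = pedigree

    def fit(self, X: GenotypeMatrix, y=None):
        self.allele_freq_ = allele_frequency(X)
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if self.pedigree is None:
            raise ConfigurationError("MendelianImputer requires a pedigree")
        return impute_dosages(X, self.pedigree, self.allele_freq_)
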