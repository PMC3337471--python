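"""Synthetic closed nucleus population generator.

Emulates the data structure a pig genetic-improvement nucleus line
produces: a multigenerational pedigree with heavy sire reuse and
overlapping generations, biallelic SNP dosages obtained by gene drop down
that pedigree (unlinked loci, founder frequencies bounded away from zero as
on a post-QC chip), five traits with heritabilities spanning 0.07-0.62 on
the corrected scale, and pedigree-BLUP pEBV with PEV-derived accuracies
showing the wide spread typical of such programs (few animals above 0.9).

One global seed in :class:`SimConfig` drives every operation through named
substreams, so partial reruns of any stage reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ConfigurationError, DataError
from .genotypes import GenotypeMatrix
from .models import PedigreeBlup, VarianceComponents
from .pedigree import UNKNOWN, Pedigree
from .relmat import a_inverse
from .traits import DEFAULT_H2, DEFAULT_TRAIT_NAMES, DEFAULT_VAR_A, TraitTable


@dataclass
class SimConfig:
    # pedigree structure
    n_founders: int = 60
    n_generations: int = 4
    sires_per_generation: int = 7
    dams_per_sire: int = 9
    litter_size: int = 6
    # genome
    n_snp: int = 1000
    n_qtl_per_trait: int = 100
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_sex_chrom_snp: int = 0  # labelled X; exercises the exclusion filter only
    missing_rate: float = 0.005
    # traits
    trait_names: tuple = DEFAULT_TRAIT_NAMES
    heritabilities: tuple = tuple(DEFAULT_H2)
    additive_variances: tuple = tuple(DEFAULT_VAR_A)
    # genotyping strategy: probability an animal is genotyped, by role
    geno_prob_sire: float = 0.65
    geno_prob_dam: float = 0.45
    geno_prob_other: float = 0.55
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_founders,
            self.sires_per_generation,
            self.dams_per_sire,
            self.litter_size,
            self.n_snp,
        )
        if any(v <= 0 for v in counts) or self.n_generations < 0:
            raise ConfigurationError("population/genome counts must be positive")
        if self.n_qtl_per_trait < 0 or self.n_qtl_per_trait > self.n_snp:
            raise ConfigurationError("n_qtl_per_trait must lie in [0, n_snp]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ConfigurationError("founder MAF range must satisfy 0 < lo <= hi <= 0.5")
        if len(self.heritabilities) != len(self.trait_names) or len(
            self.additive_variances
        ) != len(self.trait_names):
            raise ConfigurationError("per-trait vectors must match trait_names")
        for h2 in self.heritabilities:
            if not 0.0 < h2 < 1.0:
                raise ConfigurationError("heritabilities must lie in (0, 1)")
        for va in self.additive_variances:
            if va <= 0.0:
                raise ConfigurationError("additive variances must be positive")

    def h2_series(self) -> pd.Series:
        return pd.Series(self.heritabilities, index=list(self.trait_names))

    def var_a_series(self) -> pd.Series:
        return pd.Series(self.additive_variances, index=list(self.trait_names))


@dataclass
class TrueValues:
    """Simulation ground truth: per-animal TBV and per-trait QTL effects."""

    tbv: pd.DataFrame  # animals x traits
    qtl_effects: pd.DataFrame  # snp x traits (zero off-QTL)


@dataclass
class StudyPopulation:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # all animals, missing mask applied
    traits: TraitTable  # phenotypes + pEBV + accuracy
    truth: TrueValues
    genotyped_ids: np.ndarray
    config: SimConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Overlapping-generation nucleus pedigree with heavy sire reuse.

    Each generation draws a small sire team (from the previous two
    generations' males) and mates each sire to several dams; every litter
    alternates sexes. Every non-founder has both parents recorded.
    """
    rng = substream(cfg.rng_seed, "pedigree")
    ids: list = []
    sire: list = []
    dam: list = []
    gen: list = []
    sex: list = []

    def add(s: int, d: int, g: int, x: str) -> int:
        ids.append(str(len(ids) + 1))
        sire.append(s)
        dam.append(d)
        gen.append(g)
        sex.append(x)
        return len(ids) - 1

    for i in range(cfg.n_founders):
        add(UNKNOWN, UNKNOWN, 0, "M" if i % 2 == 0 else "F")

    for g in range(1, cfg.n_generations + 1):
        pool = [
            i for i in range(len(ids)) if gen[i] >= g - 2 and gen[i] <= g - 1
        ]
        males = np.asarray([i for i in pool if sex[i] == "M"], dtype=np.int64)
        females = np.asarray([i for i in pool if sex[i] == "F"], dtype=np.int64)
        if males.size == 0 or females.size == 0:
            raise ConfigurationError("breeding pool exhausted; enlarge founders")
        k = cfg.sires_per_generation
        sires = rng.choice(males, size=k, replace=males.size < k)
        need = k * cfg.dams_per_sire
        dams = rng.choice(females, size=need, replace=females.size < need)
        for si, s in enumerate(sires):
            for d in dams[si * cfg.dams_per_sire : (si + 1) * cfg.dams_per_sire]:
                for c in range(cfg.litter_size):
                    add(int(s), int(d), g, "M" if c % 2 == 0 else "F")

    return Pedigree(
        np.asarray(ids, dtype=object),
        np.asarray(sire, dtype=np.int64),
        np.asarray(dam, dtype=np.int64),
        np.asarray(gen, dtype=np.int64),
        np.asarray(sex, dtype=object),
    )


# ---------------------------------------------------------------------------
# genotypes


def _gene_drop(ped: Pedigree, cfg: SimConfig):
    """Drop founder alleles down the pedigree; returns (dosages, freqs)."""
    rng = substream(cfg.rng_seed, "genotypes")
    n, m = ped.n, cfg.n_snp
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    hap = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for k, p in enumerate((s, d)):
            if p < 0:
                hap[i, k] = rng.random(m) < freqs
            else:
                if p >= i:
                    raise DataError("pedigree ordering violation in gene drop")
                pick = rng.integers(0, 2, size=m)
                hap[i, k] = hap[p, pick, np.arange(m)]
    dosages = hap.sum(axis=1)
    return dosages, freqs


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop dosages for every pedigree animal, with random missingness."""
    dosages, _ = _gene_drop(ped, cfg)
    D = dosages.astype(np.float64)
    if cfg.missing_rate > 0.0:
        rng = substream(cfg.rng_seed, "missing")
        D[rng.random(D.shape) < cfg.missing_rate] = np.nan
    chrom = np.full(cfg.n_snp, "1", dtype=object)
    if cfg.n_sex_chrom_snp > 0:
        chrom[-cfg.n_sex_chrom_snp :] = "X"
    snp_ids = np.asarray([f"snp{j + 1}" for j in range(cfg.n_snp)], dtype=object)
    return GenotypeMatrix(ped.ids, snp_ids, D, chrom)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    ped: Pedigree, geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[TraitTable, TrueValues]:
    """True breeding values from sampled QTL, plus corrected-scale phenotypes.

    QTL effects are rescaled so the TBV variance across animals matches the
    configured additive variance exactly; phenotype = TBV + residual with
    variance sigma2_A (1 - h²)/h². Missing dosages (if the matrix was
    masked) are mean-filled for the TBV sum, a negligible distortion at the
    sub-percent missing rates simulated here.
    """
    rng = substream(cfg.rng_seed, "phenotypes")
    D = geno.dosages
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        D = np.where(np.isnan(D), col_mean, D)

    n, m = D.shape
    traits = list(cfg.trait_names)
    tbv = pd.DataFrame(0.0, index=pd.Index(geno.animal_ids, name="animal"), columns=traits)
    qtl = pd.DataFrame(0.0, index=pd.Index(geno.snp_ids, name="snp_id"), columns=traits)
    pheno = pd.DataFrame(index=tbv.index, columns=traits, dtype=float)

    for t, h2, var_a in zip(traits, cfg.heritabilities, cfg.additive_variances):
        if not 0.0 < h2 < 1.0:
            raise ConfigurationError("h2 must lie in the open interval (0, 1)")
        if cfg.n_qtl_per_trait > 0:
            loci = rng.choice(m, size=cfg.n_qtl_per_trait, replace=False)
            eff = rng.normal(size=cfg.n_qtl_per_trait)
            raw = D[:, loci] @ eff
            sd = raw.std()
            if sd <= 0.0:
                raise DataError("all sampled QTL monomorphic; increase n_snp")
            eff *= np.sqrt(var_a) / sd
            g = D[:, loci] @ eff
            g -= g.mean()
            qtl.iloc[loci, qtl.columns.get_loc(t)] = eff
        else:
            g = np.zeros(n)
        var_res = var_a * (1.0 - h2) / h2
        pheno[t] = g + rng.normal(scale=np.sqrt(var_res), size=n)
        tbv[t] = g

    table = TraitTable(pheno, cfg.h2_series(), cfg.var_a_series())
    return table, TrueValues(tbv, qtl)


# ---------------------------------------------------------------------------
# production-style pEBV


def attach_pebv(
    ped: Pedigree,
    traits: TraitTable,
    vc: dict | None = None,
    a_inv=None,
) -> TraitTable:
    """Single-trait pedigree BLUP per trait; adds pEBV and accuracy columns.

    Accuracy is the reliability 1 - PEV/sigma2_A from the solved mixed-model
    equations, clipped to [0, 1]. All phenotyped animals contribute (the
    production-run analogue: the full pedigree and all records, no genomics).
    """
    if a_inv is None:
        a_inv = a_inverse(ped)
    pebv = pd.DataFrame(index=pd.Index(ped.ids, name="animal"), dtype=float)
    acc = pd.DataFrame(index=pebv.index, dtype=float)
    for t in traits.trait_names:
        if vc is not None and t in vc:
            comps = vc[t]
        else:
            comps = VarianceComponents.from_h2(
                float(traits.h2[t]), float(traits.var_a[t])
            )
        y = traits.phenotypes[t].dropna()
        if y.empty:
            raise DataError(f"no phenotyped animals for trait {t}")
        model = PedigreeBlup(comps.var_a, comps.var_e, compute_pev=True).fit(
            ped, y, a_inv=a_inv
        )
        pebv[t] = model.ebv_.reindex(pebv.index)
        acc[t] = model.reliability_.reindex(pebv.index)
    return traits.with_pebv(pebv, acc)


# ---------------------------------------------------------------------------
# genotyping strategy + orchestration


def select_genotyped(ped: Pedigree, cfg: SimConfig) -> np.ndarray:
    """Sample the genotyped subset with role-dependent probabilities.

    Sires (reused breeding males) are genotyped most often, dams less, and
    other animals — including the youngest, progeny-less generation — at an
    intermediate rate, reproducing the overlap structure in which most
    animals have a genotyped sire and many have genotyped offspring.
    """
    rng = substream(cfg.rng_seed, "genotyping")
    counts = ped.offspring_counts()
    prob = np.full(ped.n, cfg.geno_prob_other)
    prob[(counts > 0) & (ped.sex == "M")] = cfg.geno_prob_sire
    prob[(counts > 0) & (ped.sex == "F")] = cfg.geno_prob_dam
    picked = rng.random(ped.n) < prob
    if picked.sum() < 10:
        raise ConfigurationError("genotyped subset too small; raise probabilities")
    return ped.ids[picked]


def simulate_population(cfg: SimConfig) -> StudyPopulation:
    """Full synthetic study population: pedigree, genotypes, traits, truth."""
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    traits, truth = simulate_phenotypes(ped, geno, cfg)
    a_inv = a_inverse(ped)
    traits = attach_pebv(ped, traits, a_inv=a_inv)
    genotyped = select_genotyped(ped, cfg)
    return StudyPopulation(ped, geno, traits, truth, genotyped, cfg)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, rng_seed=int(seed))
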