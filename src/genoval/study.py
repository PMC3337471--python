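"""End-to-end synthetic validation study driver.

Wires the pipeline the way the production evaluation is organised:
simulate a nucleus population -> two-stage SNP QC with probability-based
imputation in between -> relationship matrices -> fit the four predictors
on each training split -> relatedness-stratified accuracy reports for the
k-fold design (XVal) and the young-animal design (YoungVal).

Phenotype records used by the predictors are restricted to genotyped
animals (the distributed-data situation); the production-style pEBV used
as the validation stand-in for true merit come from all records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import subseed
from .errors import ConfigurationError
from .genotypes import GenotypeMatrix
from .models import (
    BayesBConfig,
    VarianceComponents,
    bayesb,
    deregress,
    pedigree_blup,
    ssgblup,
)
from .qc import allele_frequency, filter_snps, impute_dosages
from .relmat import RelationshipMatrix, a_inverse, a_matrix, g_matrix, h_inverse
from .simulate import SimConfig, StudyPopulation, simulate_population
from .validation import (
    DEFAULT_G_COUNT_BINS,
    assign_folds,
    bin_g_counts,
    g_threshold_counts,
    relatedness_category,
    select_top_accuracy,
    stratified_accuracy,
    young_animal_split,
)

ALL_METHODS = ("BLUP", "SStep", "BayesB_ph", "BayesB_ebv")


def _desk_bayesb() -> BayesBConfig:
    # desk-scale chain: long enough for stable posterior means at the
    # simulated marker counts, short enough for many folds x traits
    return BayesBConfig(chain_length=1500, burn_in=300, thin=5)


@dataclass
class StudyConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    k_folds: int = 6
    folds_to_run: tuple | None = (1,)  # None = all k rounds
    n_top: int = 75
    youngval_n_top: int = 30
    min_youngval_accuracy: float = 0.6
    g_threshold: float = 0.45
    g_bin_edges: tuple = DEFAULT_G_COUNT_BINS
    blend: float = 0.05
    methods: tuple = ALL_METHODS
    bayesb: BayesBConfig = field(default_factory=_desk_bayesb)
    deregress_c: float = 0.5
    r2_floor: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")


@dataclass
class PreparedStudy:
    population: StudyPopulation
    genotypes: GenotypeMatrix  # genotyped subset, imputed + stage-2 filtered
    freqs: np.ndarray
    a_inv: RelationshipMatrix
    g: RelationshipMatrix
    h_inv: RelationshipMatrix
    qc_reports: tuple


def prepare_study(cfg: StudyConfig, seed: int) -> PreparedStudy:
    """Simulate and run every split-independent stage once."""
    pop = simulate_population(replace(cfg.sim, rng_seed=int(seed)))
    raw = pop.genotypes.subset_animals(pop.genotyped_ids)
    stage1, rep1 = filter_snps(raw, stage=1)
    imputed = impute_dosages(stage1, pop.pedigree)
    filtered, rep2 = filter_snps(imputed, stage=2)
    freqs = allele_frequency(filtered)
    a_inv = a_inverse(pop.pedigree)
    g = g_matrix(filtered, freqs)
    a22 = a_matrix(pop.pedigree, subset=g.ids)
    h_inv = h_inverse(a_inv, g, a22, cfg.blend)
    return PreparedStudy(pop, filtered, freqs, a_inv, g, h_inv, (rep1, rep2))


def fit_split(
    prep: PreparedStudy,
    cfg: StudyConfig,
    training_ids,
    trait: str,
    seed: int,
    label: str,
) -> dict:
    """Fit every requested method on one training split for one trait.

    Returns method -> gEBV Series covering at least the genotyped animals
    (BLUP/SStep cover the whole pedigree).
    """
    pop = prep.population
    traits = pop.traits
    vc = VarianceComponents.from_h2(float(traits.h2[trait]), float(traits.var_a[trait]))
    train = [str(t) for t in training_ids]
    y = traits.phenotypes[trait].reindex(train).dropna()
    out: dict = {}
    for method in cfg.methods:
        if method == "BLUP":
            res = pedigree_blup(y, prep.a_inv, vc, compute_pev=False)
        elif method == "SStep":
            res = ssgblup(y, prep.h_inv, vc, compute_pev=False)
        elif method == "BayesB_ph":
            bb = replace(
                cfg.bayesb,
                rng_seed=subseed(seed, f"bayesb_ph:{label}:{trait}"),
            )
            res = bayesb(prep.genotypes, y, bb, vc, method="BayesB_ph")
        elif method == "BayesB_ebv":
            dr = deregress(
                traits.pebv[trait].reindex(train),
                traits.accuracy[trait].reindex(train),
                float(traits.h2[trait]),
                c=cfg.deregress_c,
                r2_floor=cfg.r2_floor,
            )
            bb = replace(
                cfg.bayesb,
                rng_seed=subseed(seed, f"bayesb_ebv:{label}:{trait}"),
            )
            res = bayesb(
                prep.genotypes,
                dr["debv"],
                bb,
                vc,
                weights=dr["weight"],
                method="BayesB_ebv",
            )
        out[method] = res.frame["estimate"]
    return out


def run_xval(prep: PreparedStudy, cfg: StudyConfig, seed: int):
    """k-fold cross-validation with relatedness-stratified accuracies.

    Returns (report, gbins): tidy frames of per (trait, method, stratum)
    and per (trait, method, g-count bin) accuracies. The top-``n_top``
    pEBV-accuracy subset per fold and trait is used throughout.
    """
    pop = prep.population
    genotyped = [str(t) for t in prep.genotypes.animal_ids]
    folds = assign_folds(genotyped, cfg.k_folds, seed)
    rounds = range(1, cfg.k_folds + 1) if cfg.folds_to_run is None else cfg.folds_to_run
    report_rows = []
    gbin_rows = []
    for fold in rounds:
        val = folds.index[folds == fold].to_numpy(dtype=object)
        train = folds.index[folds != fold].to_numpy(dtype=object)
        for trait in pop.traits.trait_names:
            preds = fit_split(prep, cfg, train, trait, seed, f"xval{fold}")
            top = select_top_accuracy(val, pop.traits, trait, cfg.n_top)
            strata = relatedness_category(pop.pedigree, train, top)
            strata["ALL"] = top  # the high-accuracy validation subset
            strata["FOLD"] = val  # the entire fold, selection-free
            rep = stratified_accuracy(
                preds, pop.traits, trait, strata, truth=pop.truth.tbv[trait]
            )
            rep.insert(0, "fold", fold)
            report_rows.append(rep)

            counts = g_threshold_counts(prep.g, train, top, cfg.g_threshold)
            bins = bin_g_counts(counts, cfg.g_bin_edges)
            bin_strata = {
                int(b): bins.index[bins == b].to_numpy(dtype=object)
                for b in sorted(bins.unique())
            }
            brep = stratified_accuracy(
                preds, pop.traits, trait, bin_strata, truth=pop.truth.tbv[trait]
            )
            brep = brep.rename(columns={"stratum": "g_bin"})
            brep.insert(0, "fold", fold)
            gbin_rows.append(brep)
    return pd.concat(report_rows, ignore_index=True), pd.concat(
        gbin_rows, ignore_index=True
    )


def run_youngval(prep: PreparedStudy, cfg: StudyConfig, seed: int) -> pd.DataFrame:
    """Young-animal validation: progeny-less genotyped animals held out."""
    pop = prep.population
    training, validation, subsets, excluded = young_animal_split(
        pop.pedigree,
        pop.traits,
        prep.genotypes.animal_ids,
        cfg.youngval_n_top,
        cfg.min_youngval_accuracy,
    )
    rows = []
    for trait in pop.traits.trait_names:
        preds = fit_split(prep, cfg, training, trait, seed, "youngval")
        rep = stratified_accuracy(
            preds,
            pop.traits,
            trait,
            {"ALL": subsets[trait]},
            truth=pop.truth.tbv[trait],
        )
        rep["excluded"] = excluded[trait]
        rows.append(rep)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "design", "YoungVal")
    return out


def run_study(cfg: StudyConfig, seed: int) -> dict:
    """One full synthetic study at one seed."""
    prep = prepare_study(cfg, seed)
    xval, gbins = run_xval(prep, cfg, seed)
    young = run_youngval(prep, cfg, seed)
    return {
        "prepared": prep,
        "xval": xval,
        "gbins": gbins,
        "youngval": young,
    }
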