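"""Cross-validation design and relatedness-stratified accuracy evaluation.

Accuracy is the product-moment correlation between gEBV and high-accuracy
pedigree EBV (the available stand-in for true breeding value in real data);
on synthetic data a parallel correlation with the simulated TBV is also
reported. Validation animals are stratified by which relatives sit in the
training set — at least one parent (P), at least one offspring (O), both
kinds (PO), or neither (N); P optionally splits into one-parent (1P) and
two-parent (2P) — and, alternatively, by the count of genomic relationship
coefficients with training animals exceeding a threshold (default 0.45,
strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import ConfigurationError, DataError
from .pedigree import Pedigree
from .relmat import RelationshipMatrix
from .traits import TraitTable

#: default bin edges for counts of large genomic coefficients: the label of
#: bin b covers counts in [edges[b], edges[b+1])
DEFAULT_G_COUNT_BINS = (0, 1, 2, 6, 11)


def assign_folds(ids, k: int = 6, seed: int = 0) -> pd.Series:
    """Balanced random fold assignment: fold sizes differ by at most one."""
    ids = np.asarray(list(ids), dtype=object)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > len(ids):
        raise ConfigurationError(f"k={k} exceeds the {len(ids)} available animals")
    rng = substream(seed, "folds")
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=np.int64)
    folds[perm] = np.arange(len(ids)) % k + 1
    return pd.Series(folds, index=pd.Index(ids, name="animal"), name="fold")


def select_top_accuracy(
    validation_ids, traits: TraitTable, trait: str, n_top: int = 75
) -> np.ndarray:
    """Top-n validation animals by pEBV accuracy, ties broken by id order."""
    if traits.accuracy is None:
        raise DataError("trait table has no pEBV accuracies")
    ids = [str(t) for t in validation_ids]
    acc = traits.accuracy[trait].reindex(ids)
    order = sorted(ids, key=lambda a: (-(acc[a] if pd.notna(acc[a]) else -np.inf), a))
    return np.asarray(order[: min(n_top, len(order))], dtype=object)


def relatedness_category(
    ped: Pedigree, training_ids, validation_ids, split_parents: bool = False
) -> dict:
    """Partition validation animals by genotyped relatives in training.

    Only parent and offspring links count (grandparents do not). With
    ``split_parents`` the parent-only stratum separates into one-parent (1P)
    and two-parent (2P).
    """
    train = {str(t) for t in training_ids}
    val = [str(t) for t in validation_ids]
    overlap = train & set(val)
    if overlap:
        raise DataError(
            f"training and validation overlap ({sorted(overlap)[:5]} ...)"
        )
    pos = ped.positions(val)
    # offspring links: training animals whose parent is the validation animal
    train_pos = ped.positions(sorted(train & {str(t) for t in ped.ids}))
    parents_of_train = set(ped.sire[train_pos][ped.sire[train_pos] >= 0]) | set(
        ped.dam[train_pos][ped.dam[train_pos] >= 0]
    )
    labels = ["1P", "2P", "O", "PO", "N"] if split_parents else ["P", "O", "PO", "N"]
    strata: dict = {lab: [] for lab in labels}
    for tok, p in zip(val, pos):
        n_par = sum(
            1
            for q in (ped.sire[p], ped.dam[p])
            if q >= 0 and str(ped.ids[q]) in train
        )
        has_off = p in parents_of_train
        if n_par and has_off:
            lab = "PO"
        elif n_par:
            lab = ("1P" if n_par == 1 else "2P") if split_parents else "P"
        elif has_off:
            lab = "O"
        else:
            lab = "N"
        strata[lab].append(tok)
    return {lab: np.asarray(v, dtype=object) for lab, v in strata.items()}


def g_threshold_counts(
    g: RelationshipMatrix, training_ids, validation_ids, threshold: float = 0.45
) -> pd.Series:
    """Per-validation-animal count of training coefficients strictly above
    ``threshold`` — how many training animals it is highly related to."""
    rows = g.positions([str(t) for t in validation_ids])
    cols = g.positions([str(t) for t in training_ids])
    counts = (g.values[np.ix_(rows, cols)] > threshold).sum(axis=1)
    return pd.Series(
        counts, index=pd.Index([str(t) for t in validation_ids], name="animal"),
        name="g_count",
    )


def bin_g_counts(counts: pd.Series, edges=DEFAULT_G_COUNT_BINS) -> pd.Series:
    """Map counts to bin indices; bin b covers [edges[b], edges[b+1])."""
    edges = np.asarray(edges)
    return pd.Series(
        np.searchsorted(edges, counts.to_numpy(), side="right") - 1,
        index=counts.index,
        name="g_bin",
    )


def young_animal_split(
    ped: Pedigree,
    traits: TraitTable,
    genotyped_ids,
    n_top: int = 30,
    min_mean_accuracy: float = 0.6,
):
    """Young-animal validation design.

    Validation: genotyped animals with no offspring link anywhere in the
    pedigree (the selection candidates); training: all other genotyped
    animals. The per-trait evaluation subset is the ``n_top`` validation
    animals with the highest pEBV accuracy; traits whose subset mean
    accuracy falls below ``min_mean_accuracy`` are flagged as excluded
    (too little signal in the stand-in for TBV), mirroring the exclusion of
    low-information progeny-mean traits.
    """
    ids = [str(t) for t in genotyped_ids]
    counts = ped.offspring_counts()
    pos = ped.positions(ids)
    is_young = counts[pos] == 0
    validation = np.asarray(ids, dtype=object)[is_young]
    training = np.asarray(ids, dtype=object)[~is_young]
    if training.size == 0:
        raise DataError("no training animals: nobody in the pedigree has progeny")
    if validation.size == 0:
        raise DataError("no young (progeny-less) genotyped animals")
    subsets: dict = {}
    excluded: dict = {}
    for t in traits.trait_names:
        top = select_top_accuracy(validation, traits, t, n_top)
        subsets[t] = top
        mean_acc = float(traits.accuracy[t].reindex(top).mean())
        excluded[t] = mean_acc < min_mean_accuracy
    return training, validation, subsets, excluded


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _slope(x: np.ndarray, y: np.ndarray) -> float:
    """Regression slope of y on x (dispersion/unbiasedness diagnostic)."""
    if len(x) < 3 or np.var(x) == 0:
        return np.nan
    return float(np.cov(x, y)[0, 1] / np.var(x, ddof=1))


def stratified_accuracy(
    predictions: dict,
    traits: TraitTable,
    trait: str,
    strata: dict,
    truth: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-method, per-stratum validation accuracy report.

    ``predictions`` maps method name to a gEBV Series (indexed by animal).
    Accuracy is corr(gEBV, pEBV) over the stratum members; strata with
    fewer than two animals are reported with NaN accuracy. When a ``truth``
    series (simulated TBV) is supplied, corr(gEBV, TBV) is reported too.
    """
    if traits.pebv is None or traits.accuracy is None:
        raise DataError("trait table has no pEBV; run the pedigree evaluation")
    rows = []
    for method, gebv in predictions.items():
        for label, members in strata.items():
            members = [str(t) for t in members]
            g = gebv.reindex(members).to_numpy(dtype=float)
            p = traits.pebv[trait].reindex(members).to_numpy(dtype=float)
            ok = ~(np.isnan(g) | np.isnan(p))
            rows.append(
                {
                    "trait": trait,
                    "method": method,
                    "stratum": label,
                    "n": int(ok.sum()),
                    "accuracy": _corr(g[ok], p[ok]),
                    "mean_reliability": float(
                        traits.accuracy[trait].reindex(members).mean()
                    ),
                    "accuracy_tbv": (
                        _corr(
                            g[ok],
                            truth.reindex(members).to_numpy(dtype=float)[ok],
                        )
                        if truth is not None
                        else np.nan
                    ),
                    # regression of TBV on gEBV: 1 = correctly dispersed
                    "slope_tbv": (
                        _slope(
                            g[ok],
                            truth.reindex(members).to_numpy(dtype=float)[ok],
                        )
                        if truth is not None
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def correlation_zero_test(x: pd.Series, y: pd.Series) -> float:
    """Two-sided p-value for the null of zero correlation."""
    joined = pd.concat([x, y], axis=1).dropna()
    if len(joined) < 3:
        return np.nan
    return float(stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).pvalue)
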