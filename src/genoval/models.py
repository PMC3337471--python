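"""Breeding-value prediction models.

Four predictors are provided, all single-trait animal models on corrected
phenotypes (or pseudo-phenotypes):

* :class:`PedigreeBlup` — y = 1mu + Zu + e with var(u) = A sigma2_A, solved
  exactly from the dense mixed-model equations; no genomic information.
* :class:`SingleStepGblup` — same model with var(u) defined through the
  combined pedigree/genomic relationship matrix H, so genotyped and
  un-genotyped animals are evaluated jointly and every animal gets a gEBV.
* :class:`BayesB` — whole-genome marker regression with a mixture prior
  (probability pi of a zero marker effect), fit by MCMC; used on phenotypes
  or on de-regressed EBV with record weights.
* :func:`deregress` — converts pedigree EBV into pseudo-phenotypes with the
  evaluation shrinkage removed (dEBV = pEBV / r²) and information-content
  weights, for use as BayesB responses.

Variance components are inputs (production estimates or simulator truth),
never re-estimated. Prediction error variances come from the inverse of the
coefficient matrix; reliability is r² = 1 - PEV/sigma2_A clipped to [0, 1],
with pre-clip violations counted rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin

from ._bayesb import bayesb_chain
from .errors import ConfigurationError, DataError
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .relmat import RelationshipMatrix, a_inverse, a_matrix, g_matrix, h_inverse


@dataclass
class VarianceComponents:
    var_a: float
    var_e: float

    def __post_init__(self) -> None:
        if self.var_a <= 0.0 or self.var_e <= 0.0:
            raise ConfigurationError("variance components must be positive")

    @property
    def h2(self) -> float:
        return self.var_a / (self.var_a + self.var_e)

    @classmethod
    def from_h2(cls, h2: float, var_a: float) -> "VarianceComponents":
        if not 0.0 < h2 < 1.0:
            raise ConfigurationError("h2 must lie in the open interval (0, 1)")
        return cls(var_a, var_a * (1.0 - h2) / h2)


@dataclass
class PredictionResult:
    """Per-animal estimates from one method on one trait."""

    method: str  # BLUP | SStep | BayesB_ph | BayesB_ebv | GBLUP
    frame: pd.DataFrame  # index animal; columns estimate, pev, reliability
    mu: float = 0.0
    snp_effects: pd.DataFrame | None = None  # snp_id, effect, inclusion_prob
    n_reliability_clipped: int = 0

    @property
    def estimates(self) -> pd.Series:
        return self.frame["estimate"]


# ---------------------------------------------------------------------------
# dense mixed-model equations


def _solve_mme(
    k_inv: np.ndarray,
    ids: np.ndarray,
    y: pd.Series,
    var_a: float,
    var_e: float,
    weights: pd.Series | None = None,
    compute_pev: bool = True,
):
    """Solve [mu, u] from the single-trait animal-model MME.

    ``y`` is indexed by animal token (a subset of ``ids``); ``weights`` w_i
    scale residual precision (var(e_i) = var_e / w_i). Returns
    (mu, ebv, pev-or-None) with ebv/pev aligned to ``ids``.
    """
    if len(y) == 0:
        raise DataError("no phenotyped animals: nothing to solve")
    n = len(ids)
    index = {tok: i for i, tok in enumerate(ids)}
    try:
        rec = np.asarray([index[str(t)] for t in y.index], dtype=np.int64)
    except KeyError as exc:
        raise DataError(
            f"phenotyped animal {exc.args[0]!r} absent from relationship matrix"
        ) from None
    yv = y.to_numpy(dtype=float)
    if np.isnan(yv).any():
        raise DataError("NaN phenotype passed to the solver")
    w = (
        np.ones_like(yv)
        if weights is None
        else weights.reindex(y.index).to_numpy(dtype=float)
    )
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DataError("record weights must be finite and positive")

    lam = var_e / var_a
    C = np.zeros((n + 1, n + 1))
    rhs = np.zeros(n + 1)
    C[0, 0] = w.sum()
    np.add.at(C[0, 1:], rec, w)
    C[1:, 0] = C[0, 1:]
    diag = np.zeros(n)
    np.add.at(diag, rec, w)
    C[1:, 1:] = k_inv * lam
    C[np.arange(1, n + 1), np.arange(1, n + 1)] += diag
    rhs[0] = float(np.dot(w, yv))
    np.add.at(rhs[1:], rec, w * yv)

    if compute_pev:
        try:
            cf = scipy.linalg.cho_factor(C, check_finite=False)
            Cinv = scipy.linalg.cho_solve(cf, np.eye(n + 1), check_finite=False)
        except np.linalg.LinAlgError:
            Cinv = np.linalg.pinv(C)
        sol = Cinv @ rhs
        pev = np.diag(Cinv)[1:] * var_e
    else:
        try:
            cf = scipy.linalg.cho_factor(C, check_finite=False)
            sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(C, rhs, rcond=None)[0]
        pev = None
    return float(sol[0]), sol[1:], pev


def _result(method, ids, mu, ebv, pev, var_a) -> PredictionResult:
    frame = pd.DataFrame(index=pd.Index(ids, name="animal"))
    frame["estimate"] = ebv
    n_clipped = 0
    if pev is not None:
        frame["pev"] = pev
        rel = 1.0 - pev / var_a
        n_clipped = int(np.sum((rel < 0.0) | (rel > 1.0)))
        frame["reliability"] = np.clip(rel, 0.0, 1.0)
    else:
        frame["pev"] = np.nan
        frame["reliability"] = np.nan
    return PredictionResult(method, frame, mu=mu, n_reliability_clipped=n_clipped)


# ---------------------------------------------------------------------------
# estimators


class PedigreeBlup(BaseEstimator, RegressorMixin):
    """Pedigree-based BLUP (animal model, no genomic information)."""

    def __init__(self, var_a=1.0, var_e=1.0, compute_pev=True):
        self.var_a = var_a
        self.var_e = var_e
        self.compute_pev = compute_pev

    def fit(
        self,
        pedigree: Pedigree,
        y: pd.Series,
        weights: pd.Series | None = None,
        a_inv: RelationshipMatrix | None = None,
    ):
        if a_inv is None:
            a_inv = a_inverse(pedigree)
        self.ids_ = a_inv.ids
        self.mu_, ebv, pev = _solve_mme(
            a_inv.values, a_inv.ids, y, self.var_a, self.var_e, weights,
            self.compute_pev,
        )
        res = _result("BLUP", a_inv.ids, self.mu_, ebv, pev, self.var_a)
        self.result_ = res
        self.ebv_ = res.frame["estimate"]
        self.pev_ = res.frame["pev"]
        self.reliability_ = res.frame["reliability"]
        return self

    def predict(self, ids) -> np.ndarray:
        return self.ebv_.reindex([str(t) for t in ids]).to_numpy()


class SingleStepGblup(BaseEstimator, RegressorMixin):
    """Single-step GBLUP: joint evaluation through the combined H matrix."""

    def __init__(self, var_a=1.0, var_e=1.0, blend=0.05, compute_pev=False):
        self.var_a = var_a
        self.var_e = var_e
        self.blend = blend
        self.compute_pev = compute_pev

    def fit(
        self,
        pedigree: Pedigree,
        y: pd.Series,
        genotypes: GenotypeMatrix | None = None,
        freqs=None,
        h_inv: RelationshipMatrix | None = None,
    ):
        if h_inv is None:
            if genotypes is None:
                raise ConfigurationError("either genotypes or h_inv is required")
            g = g_matrix(genotypes, freqs)
            a22 = a_matrix(pedigree, subset=g.ids)
            h_inv = h_inverse(a_inverse(pedigree), g, a22, self.blend)
        self.h_inv_ = h_inv
        self.mu_, ebv, pev = _solve_mme(
            h_inv.values, h_inv.ids, y, self.var_a, self.var_e, None,
            self.compute_pev,
        )
        res = _result("SStep", h_inv.ids, self.mu_, ebv, pev, self.var_a)
        self.result_ = res
        self.ebv_ = res.frame["estimate"]
        self.pev_ = res.frame["pev"]
        self.reliability_ = res.frame["reliability"]
        return self

    def predict(self, ids) -> np.ndarray:
        return self.ebv_.reindex([str(t) for t in ids]).to_numpy()


@dataclass
class BayesBConfig:
    pi: float = 0.95
    chain_length: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    nu: float = 4.2
    scale: float | None = None  # derived from var_a when None
    n_mh: int = 10
    common_variance: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ConfigurationError("pi must lie in [0, 1]")
        if self.chain_length <= self.burn_in:
            raise ConfigurationError("chain_length must exceed burn_in")
        if min(self.chain_length, self.thin) <= 0 or self.burn_in < 0:
            raise ConfigurationError("chain settings must be positive")


class BayesB(BaseEstimator, RegressorMixin):
    """BayesB marker-effect model fit by Gibbs sampling with MH variance steps.

    ``fit`` accepts a :class:`GenotypeMatrix` or a plain dosage array plus a
    response aligned to its rows. Dosages are centered by training allele
    frequency; predictions are centered scores Z a-hat on the same scale.
    """

    def __init__(self, var_a=1.0, var_e=1.0, config: BayesBConfig | None = None):
        self.var_a = var_a
        self.var_e = var_e
        self.config = config

    def _dosage_array(self, X):
        if isinstance(X, GenotypeMatrix):
            return X.dosages, X.snp_ids
        X = np.asarray(X, dtype=float)
        return X, np.asarray([f"snp{j}" for j in range(X.shape[1])], dtype=object)

    def fit(self, X, y, weights=None):
        cfg = self.config or BayesBConfig()
        D, snp_ids = self._dosage_array(X)
        if np.isnan(D).any():
            raise DataError("BayesB requires complete (imputed) dosages")
        y = np.asarray(y, dtype=float)
        if len(y) != D.shape[0]:
            raise DataError("response length does not match genotype rows")
        w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

        p = D.mean(axis=0) / 2.0
        Z = D - 2.0 * p
        sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
        if sum2pq <= 0.0:
            raise DataError("all SNP monomorphic: marker model undefined")

        if cfg.common_variance:
            sigma2_common = self.var_a / sum2pq
            s2 = 0.0
        else:
            sigma2_common = 0.0
            frac = max(1.0 - cfg.pi, 1e-12)
            if cfg.scale is not None:
                s2 = cfg.scale
            else:
                # E[sigma2_j] = nu s2 / (nu - 2); match total genic variance
                s2 = self.var_a * (cfg.nu - 2.0) / (cfg.nu * frac * sum2pq)

        eff, incl, mu, var_e, acc = bayesb_chain(
            np.ascontiguousarray(Z.T),
            y,
            w,
            float(cfg.pi),
            int(cfg.chain_length),
            int(cfg.burn_in),
            int(cfg.thin),
            float(cfg.nu),
            float(s2),
            bool(cfg.common_variance),
            float(sigma2_common),
            int(cfg.n_mh),
            int(cfg.rng_seed),
        )
        self.snp_ids_ = snp_ids
        self.allele_freq_ = p
        self.effects_ = pd.Series(eff, index=snp_ids, name="effect")
        self.inclusion_prob_ = pd.Series(incl, index=snp_ids, name="inclusion_prob")
        self.mu_ = float(mu)
        self.var_e_mean_ = float(var_e)
        self.mh_acceptance_ = float(acc)
        return self

    def predict(self, X) -> np.ndarray:
        """Centered genomic score per animal: sum_j (d_ij - 2 p_j) a_j."""
        D, snp_ids = self._dosage_array(X)
        if isinstance(X, GenotypeMatrix):
            return predict_gebv(self.effects_, X, self.allele_freq_).to_numpy()
        return (D - 2.0 * self.allele_freq_) @ self.effects_.to_numpy()

    def snp_effect_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids_,
                "effect": self.effects_.to_numpy(),
                "inclusion_prob": self.inclusion_prob_.to_numpy(),
            }
        )


# ---------------------------------------------------------------------------
# functional surfaces


def pedigree_blup(
    y: pd.Series,
    a_inv: RelationshipMatrix,
    vc: VarianceComponents,
    weights: pd.Series | None = None,
    compute_pev: bool = True,
) -> PredictionResult:
    mu, ebv, pev = _solve_mme(
        a_inv.values, a_inv.ids, y, vc.var_a, vc.var_e, weights, compute_pev
    )
    return _result("BLUP", a_inv.ids, mu, ebv, pev, vc.var_a)


def ssgblup(
    y: pd.Series,
    h_inv: RelationshipMatrix,
    vc: VarianceComponents,
    compute_pev: bool = False,
) -> PredictionResult:
    mu, ebv, pev = _solve_mme(
        h_inv.values, h_inv.ids, y, vc.var_a, vc.var_e, None, compute_pev
    )
    return _result("SStep", h_inv.ids, mu, ebv, pev, vc.var_a)


def gblup(
    y: pd.Series,
    g: RelationshipMatrix,
    vc: VarianceComponents,
    compute_pev: bool = False,
) -> PredictionResult:
    """GBLUP on genotyped animals only (ridge on genomic relationships).

    Solved in the invert-free dual form u = sigma2_A G V⁻¹ (y - mu) with
    V = G sigma2_A + I sigma2_e over the recorded animals, which stays
    exact when G is rank-deficient (more animals than independent marker
    contrasts). Mainly an oracle surface for the SNP-BLUP equivalence
    checks and the all-genotyped single-step limit.
    """
    if len(y) == 0:
        raise DataError("no phenotyped animals: nothing to solve")
    pos = g.positions(y.index)
    yv = y.to_numpy(dtype=float)
    V = g.values[np.ix_(pos, pos)] * vc.var_a + np.eye(len(pos)) * vc.var_e
    cf = scipy.linalg.cho_factor(V, check_finite=False)
    ones = np.ones(len(pos))
    vi_one = scipy.linalg.cho_solve(cf, ones, check_finite=False)
    mu = float(ones @ scipy.linalg.cho_solve(cf, yv, check_finite=False))
    mu /= float(ones @ vi_one)
    alpha = scipy.linalg.cho_solve(cf, yv - mu, check_finite=False)
    ebv = vc.var_a * g.values[:, pos] @ alpha
    pev = None
    if compute_pev:
        # var(u - u_hat) = sigma2_A G - sigma2_A^2 G V^-1 G on the diagonal
        GR = g.values[:, pos]
        sol = scipy.linalg.cho_solve(cf, GR.T, check_finite=False)
        pev = vc.var_a * np.diag(g.values) - vc.var_a**2 * np.einsum(
            "ij,ji->i", GR, sol
        )
    return _result("GBLUP", g.ids, mu, ebv, pev, vc.var_a)


def bayesb(
    dosages: GenotypeMatrix,
    response: pd.Series,
    cfg: BayesBConfig,
    vc: VarianceComponents,
    weights: pd.Series | None = None,
    method: str = "BayesB_ph",
) -> PredictionResult:
    """Fit BayesB on the animals present in ``response`` and score everyone.

    Returns gEBV (centered genomic scores) for every animal in ``dosages``,
    plus the posterior-mean marker effect table.
    """
    sub = dosages.subset_animals([str(t) for t in response.index])
    model = BayesB(vc.var_a, vc.var_e, cfg)
    w = None if weights is None else weights.reindex(response.index).to_numpy(float)
    model.fit(sub, response.to_numpy(dtype=float), w)
    scores = predict_gebv(model.effects_, dosages, model.allele_freq_)
    frame = pd.DataFrame(index=pd.Index(dosages.animal_ids, name="animal"))
    frame["estimate"] = scores.to_numpy()
    frame["pev"] = np.nan
    frame["reliability"] = np.nan
    return PredictionResult(
        method, frame, mu=model.mu_, snp_effects=model.snp_effect_table()
    )


def deregress(
    pebv: pd.Series,
    accuracy: pd.Series,
    h2: float,
    c: float = 0.5,
    r2_floor: float = 0.05,
    weight_cap: float = 20.0,
) -> pd.DataFrame:
    """De-regressed EBV and information weights.

    dEBV = pEBV / r²; weight w = (1 - h²) / ((c + (1 - r²)/r²) h²), where c
    is the fraction of genetic variance not captured by markers. Animals
    with r² below ``r2_floor`` are excluded (not zero-weighted). At r² = 1
    with c = 0 the weight is unbounded and is capped at ``weight_cap``.
    """
    if r2_floor <= 0.0:
        raise ConfigurationError("r2_floor must be > 0")
    if not 0.0 < h2 < 1.0:
        raise ConfigurationError("h2 must lie in (0, 1)")
    if c < 0.0:
        raise ConfigurationError("c must be >= 0")
    r2 = accuracy.reindex(pebv.index).astype(float)
    keep = r2.notna() & (r2 >= r2_floor) & pebv.notna()
    r2 = r2[keep]
    eb = pebv[keep].astype(float)
    debv = eb / r2
    denom = (c + (1.0 - r2) / r2) * h2
    with np.errstate(divide="ignore"):
        w = np.where(denom > 0, (1.0 - h2) / denom, np.inf)
    w = np.minimum(w, weight_cap)
    return pd.DataFrame({"debv": debv, "weight": w, "r2": r2})


def predict_gebv(
    effects: pd.Series, dosages: GenotypeMatrix, freqs: np.ndarray
) -> pd.Series:
    """Centered genomic score per animal from a marker-effect vector.

    Columns are aligned by snp_id; markers in ``effects`` missing from the
    dosage matrix raise an error listing the offending ids.
    """
    pos_of = {tok: j for j, tok in enumerate(dosages.snp_ids)}
    missing = [str(s) for s in effects.index if str(s) not in pos_of]
    if missing:
        raise DataError(
            f"{len(missing)} marker(s) absent from genotypes: "
            + ", ".join(missing[:10])
        )
    cols = np.asarray([pos_of[str(s)] for s in effects.index], dtype=np.int64)
    D = dosages.dosages[:, cols]
    if np.isnan(D).any():
        raise DataError("gEBV scoring requires complete (imputed) dosages")
    Z = D - 2.0 * np.asarray(freqs, dtype=float)
    scores = Z @ effects.to_numpy(dtype=float)
    return pd.Series(scores, index=pd.Index(dosages.animal_ids, name="animal"))
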