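"""Pedigree, genomic, and combined (single-step) relationship matrices.

* ``a_matrix`` — numerator relationship matrix A by the tabular method with
  inbreeding (a_ii = 1 + F_i, F_i = a(sire, dam)/2).
* ``a_inverse`` — Henderson's rules with inbreeding coefficients.
* ``g_matrix`` — genomic relationship G = ZZ' / (2 Σ p(1-p)) from centered
  dosages (the classical first method).
* ``h_inverse`` — single-step combined inverse: A⁻¹ plus (G*⁻¹ - A₂₂⁻¹) on
  the genotyped block, with G blended toward A₂₂ to keep it invertible.

Everything is dense; a size guard rejects pedigrees beyond desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, DataError
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

#: dense-algebra guard; above this the O(n²) memory is no longer reasonable
MAX_DENSE_ANIMALS = 12_000


@dataclass
class RelationshipMatrix:
    kind: str  # A | A_inverse | A22 | G | H_inverse
    ids: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError("relationship matrix shape does not match ids")
        scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10 * scale:
            raise DataError(f"{self.kind} matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, tokens) -> np.ndarray:
        index = {tok: i for i, tok in enumerate(self.ids)}
        try:
            return np.asarray([index[str(t)] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"animal {exc.args[0]!r} not in matrix") from None

    def submatrix(self, tokens, kind: str | None = None) -> "RelationshipMatrix":
        pos = self.positions(tokens)
        return RelationshipMatrix(
            kind or self.kind,
            self.ids[pos],
            self.values[np.ix_(pos, pos)],
            dict(self.meta),
        )


def _guard(n: int) -> None:
    if n > MAX_DENSE_ANIMALS:
        raise ConfigurationError(
            f"{n} animals exceeds the dense-algebra guard ({MAX_DENSE_ANIMALS})"
        )


def a_matrix(ped: Pedigree, subset=None) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix (with inbreeding).

    With ``subset`` (an id list, typically the genotyped animals) the
    corresponding block A₂₂ is extracted and tagged as such.
    """
    n = ped.n
    _guard(n)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0:
            A[i, :i] += 0.5 * A[s, :i]
        if d >= 0:
            A[i, :i] += 0.5 * A[d, :i]
        A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    full = RelationshipMatrix("A", ped.ids, A)
    if subset is None:
        return full
    return full.submatrix(subset, kind="A22")


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one)."""
    return np.diag(a_matrix(ped).values) - 1.0


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A⁻¹ assembled directly by Henderson's rules with inbreeding."""
    n = ped.n
    _guard(n)
    F = inbreeding(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            var_mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            var_mend = 0.75 - 0.25 * F[p]
        else:
            var_mend = 1.0
        b = 1.0 / var_mend
        Ainv[i, i] += b
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= 0.5 * b
                Ainv[p, i] -= 0.5 * b
                Ainv[p, p] += 0.25 * b
        if s >= 0 and d >= 0:
            Ainv[s, d] += 0.25 * b
            Ainv[d, s] += 0.25 * b
    return RelationshipMatrix("A_inverse", ped.ids, Ainv)


def g_matrix(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Genomic relationship matrix from centered dosages.

    ``freqs`` are the base allele frequencies used for centering and
    scaling; by default the observed frequencies of the input animals (the
    only frequencies available from a distributed genotype file).
    """
    D = geno.dosages
    if np.isnan(D).any():
        raise DataError("g_matrix requires complete (imputed) dosages")
    if freqs is None:
        freqs = D.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0.0:
        raise DataError("all SNP monomorphic: genomic relationship undefined")
    Z = D - 2.0 * freqs
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix("G", geno.animal_ids, G, {"freqs": freqs})


def _inv_spd(M: np.ndarray) -> np.ndarray:
    c, low = scipy.linalg.cho_factor(M, check_finite=False)
    return scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)


def h_inverse(
    a_inv: RelationshipMatrix,
    g: RelationshipMatrix,
    a22: RelationshipMatrix,
    blend: float = 0.05,
) -> RelationshipMatrix:
    """Single-step combined relationship inverse.

    G is first blended toward the pedigree block, G* = (1-blend) G +
    blend A₂₂, then H⁻¹ = A⁻¹ with (G*⁻¹ - A₂₂⁻¹) added on the genotyped
    block, so genotyped and un-genotyped animals are evaluated jointly.
    """
    if not 0.0 <= blend < 1.0:
        raise ConfigurationError("blend must lie in [0, 1)")
    if list(g.ids) != list(a22.ids):
        a22 = a22.submatrix(g.ids)
    pos = a_inv.positions(g.ids)
    g_star = (1.0 - blend) * g.values + blend * a22.values
    try:
        g_star_inv = _inv_spd(g_star)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            "blended genomic matrix is numerically singular; increase blend"
        ) from exc
    a22_inv = _inv_spd(a22.values)
    H = a_inv.values.copy()
    H[np.ix_(pos, pos)] += g_star_inv - a22_inv
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(
        "H_inverse", a_inv.ids, H, {"blend": blend, "genotyped_ids": g.ids}
    )
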