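"""File formats: pedigree/trait CSV, whitespace genotype text, matrices.

The genotype dialect mirrors the distributed-data layout: one animal per
row, the animal token followed by one real dosage per SNP, whitespace
separated, missing coded by a configurable sentinel (default -9; the
distributed file uses 5). All joins between files are by animal token,
never by row position.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .relmat import RelationshipMatrix
from .traits import TraitTable


# -- pedigree ---------------------------------------------------------------


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (animal, sire, dam[, generation, sex]).

    Unknown parents are coded 0 or left empty. The result is topologically
    sorted; duplicate animal rows and cycles raise :class:`DataError`.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Pedigree.from_frame(frame)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# -- genotypes --------------------------------------------------------------


def read_genotypes(
    path, missing_code: float = -9.0, snp_info: str | None = None
) -> GenotypeMatrix:
    """Read whitespace-delimited dosages (animal token, then one value/SNP).

    Ragged rows raise :class:`DataError` with the offending line number;
    dosages outside [0, 2] (other than the missing code) are rejected.
    ``snp_info`` optionally names a CSV of (snp_id, chrom) giving column
    ids and chromosome labels; otherwise SNP are numbered snp1..snpM.
    """
    animals: list = []
    rows: list = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise DataError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {width})"
                )
            animals.append(parts[0])
            try:
                rows.append(np.asarray(parts[1:], dtype=float))
            except ValueError as exc:
                raise DataError(f"{path}: non-numeric dosage at line {lineno}") from exc
    if not animals:
        raise DataError(f"{path}: empty genotype file")
    D = np.vstack(rows)
    D[D == missing_code] = np.nan
    with np.errstate(invalid="ignore"):
        bad = (D < 0) | (D > 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"{path}: dosage {D[i, j]} out of range at line {i + 1}, SNP {j + 1}"
        )
    if snp_info is not None:
        info = pd.read_csv(snp_info, dtype=str)
        snp_ids = info.iloc[:, 0].to_numpy(dtype=object)
        chrom = (
            info.iloc[:, 1].to_numpy(dtype=object) if info.shape[1] > 1 else None
        )
    else:
        snp_ids = np.asarray([f"snp{j + 1}" for j in range(D.shape[1])], dtype=object)
        chrom = None
    return GenotypeMatrix(np.asarray(animals, dtype=object), snp_ids, D, chrom)


def write_genotypes(geno: GenotypeMatrix, path, missing_code: float = -9.0) -> None:
    D = np.where(np.isnan(geno.dosages), missing_code, geno.dosages)
    with open(path, "w") as fh:
        for tok, row in zip(geno.animal_ids, D):
            fh.write(str(tok) + " " + " ".join(format(v, "g") for v in row) + "\n")


def write_snp_info(geno: GenotypeMatrix, path) -> None:
    pd.DataFrame({"snp_id": geno.snp_ids, "chrom": geno.chrom}).to_csv(
        path, index=False
    )


# -- traits -----------------------------------------------------------------


def write_traits(traits: TraitTable, path, meta_path=None) -> None:
    """Trait CSV: animal, then per trait phenotype/pebv/accuracy columns."""
    out = pd.DataFrame(index=traits.phenotypes.index)
    for t in traits.trait_names:
        out[f"pheno_{t}"] = traits.phenotypes[t]
        if traits.pebv is not None:
            out[f"pebv_{t}"] = traits.pebv[t]
        if traits.accuracy is not None:
            out[f"acc_{t}"] = traits.accuracy[t]
    out.to_csv(path, index_label="animal")
    if meta_path is not None:
        pd.DataFrame(
            {"trait": traits.trait_names, "h2": traits.h2, "var_a": traits.var_a}
        ).to_csv(meta_path, index=False)


def read_traits(path, meta_path) -> TraitTable:
    frame = pd.read_csv(path, index_col="animal", dtype={"animal": str})
    frame.index = frame.index.astype(str)
    meta = pd.read_csv(meta_path).set_index("trait")
    names = list(meta.index)
    pheno = pd.DataFrame({t: frame.get(f"pheno_{t}") for t in names})
    pebv_cols = {t: frame.get(f"pebv_{t}") for t in names}
    acc_cols = {t: frame.get(f"acc_{t}") for t in names}
    has_pebv = all(v is not None for v in pebv_cols.values())
    return TraitTable(
        pheno,
        meta["h2"],
        meta["var_a"],
        pd.DataFrame(pebv_cols) if has_pebv else None,
        pd.DataFrame(acc_cols) if has_pebv else None,
    )


# -- relationship matrices --------------------------------------------------


def write_relmatrix(mat: RelationshipMatrix, path) -> None:
    """Persist a matrix: HDF5 when the path ends in .h5/.hdf5, else text
    triplets (id_i, id_j, value; upper triangle) with an ids sidecar."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=mat.values)
            fh.create_dataset(
                "ids", data=np.asarray([str(t) for t in mat.ids], dtype="S")
            )
            fh.attrs["kind"] = mat.kind
        return
    with open(path, "w") as fh:
        fh.write(f"# kind {mat.kind}\n")
        for i in range(mat.n):
            for j in range(i, mat.n):
                fh.write(f"{mat.ids[i]} {mat.ids[j]} {mat.values[i, j]:.10g}\n")


def read_relmatrix(path, kind: str | None = None) -> RelationshipMatrix:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            values = fh["values"][...]
            ids = [s.decode() for s in fh["ids"][...]]
            kind = kind or fh.attrs.get("kind", "A")
        return RelationshipMatrix(kind, np.asarray(ids, dtype=object), values)
    ids: list = []
    index: dict = {}
    triplets: list = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if kind is None and line.split()[1] == "kind":
                    kind = line.split()[2]
                continue
            a, b, v = line.split()
            for tok in (a, b):
                if tok not in index:
                    index[tok] = len(ids)
                    ids.append(tok)
            triplets.append((index[a], index[b], float(v)))
    values = np.zeros((len(ids), len(ids)))
    for i, j, v in triplets:
        values[i, j] = v
        values[j, i] = v
    return RelationshipMatrix(kind or "A", np.asarray(ids, dtype=object), values)


# -- distributed-dataset loader ---------------------------------------------


def load_distributed_dataset(directory, missing_code: float = 5.0) -> dict:
    """Load a local copy of the distributed pig dataset.

    Expects ``pedigree.csv`` (animal, sire, dam), ``genotypes.txt`` in the
    whitespace dosage dialect with the dataset's missing sentinel, and
    ``phenotypes.csv`` with per-trait phenotype/pEBV/accuracy columns. The
    dataset itself is not redistributable with this package; point this
    loader at your own copy.
    """
    directory = str(directory)
    paths = {
        "pedigree": os.path.join(directory, "pedigree.csv"),
        "genotypes": os.path.join(directory, "genotypes.txt"),
        "phenotypes": os.path.join(directory, "phenotypes.csv"),
    }
    for name, p in paths.items():
        if not os.path.exists(p):
            raise DataError(f"distributed dataset file missing: {p}")
    return {
        "pedigree": read_pedigree(paths["pedigree"]),
        "genotypes": read_genotypes(paths["genotypes"], missing_code=missing_code),
        "phenotypes": pd.read_csv(paths["phenotypes"]),
    }
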