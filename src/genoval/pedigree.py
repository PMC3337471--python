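"""Pedigree container.

A :class:`Pedigree` stores animal/sire/dam triplets in topological order
(every parent precedes all of its offspring), the form required by the
tabular relationship-matrix recursions and by gene-drop simulation. Unknown
parents are coded with index ``UNKNOWN``. Sex is validated against usage:
every animal used as a sire must be male, every dam female.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

UNKNOWN = -1

#: tokens read as "parent unknown" in input files
UNKNOWN_TOKENS = {"", "0", ".", "NA", "na", "nan", "None"}


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : array of str
        Animal tokens, parents always before offspring.
    sire, dam : int arrays
        Positional index of each animal's parent, ``UNKNOWN`` (-1) if absent.
    generation : int array
    sex : array of 'M'/'F'
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        self._index = {tok: i for i, tok in enumerate(self.ids)}
        if len(self._index) != self.n:
            raise DataError("duplicate animal ids in pedigree")
        self._check_ordered()
        self._check_sex()

    # -- validation ---------------------------------------------------------

    def _check_ordered(self) -> None:
        idx = np.arange(self.n)
        for parent in (self.sire, self.dam):
            known = parent >= 0
            if np.any(parent[known] >= idx[known]):
                bad = self.ids[np.flatnonzero(known & (parent >= idx))[0]]
                raise DataError(
                    f"pedigree not topologically ordered: parent of {bad!r} "
                    "does not precede it"
                )

    def _check_sex(self) -> None:
        for parent, want, role in ((self.sire, "M", "sire"), (self.dam, "F", "dam")):
            used = np.unique(parent[parent >= 0])
            bad = used[self.sex[used] != want]
            if bad.size:
                raise DataError(
                    f"animal {self.ids[bad[0]]!r} used as {role} but has sex "
                    f"{self.sex[bad[0]]!r}"
                )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns animal, sire, dam[, generation, sex].

        Rows may be in any order; a topological sort (stable within depth) is
        applied. Cycles and parents missing from the animal column raise
        :class:`DataError`.
        """
        cols = {c.lower(): c for c in frame.columns}
        for required in ("animal", "sire", "dam"):
            if required not in cols:
                raise DataError(f"pedigree file lacks column {required!r}")

        def tok(v) -> str:
            s = "" if pd.isna(v) else str(v)
            return "" if s in UNKNOWN_TOKENS else s

        animals = [tok(v) for v in frame[cols["animal"]]]
        if "" in animals:
            raise DataError("empty/unknown token used as an animal id")
        pos = {}
        for a in animals:
            if a in pos:
                raise DataError(f"duplicate pedigree row for animal {a!r}")
            pos[a] = len(pos)
        n = len(animals)

        def parent_idx(col) -> np.ndarray:
            out = np.full(n, UNKNOWN, dtype=np.int64)
            for i, v in enumerate(frame[col]):
                t = tok(v)
                if t == "":
                    continue
                if t == animals[i]:
                    raise DataError(f"animal {t!r} recorded as its own parent")
                if t not in pos:
                    raise DataError(f"parent {t!r} has no animal record")
                out[i] = pos[t]
            return out

        sire = parent_idx(cols["sire"])
        dam = parent_idx(cols["dam"])

        # depth-first depth computation with cycle detection
        depth = np.full(n, -1, dtype=np.int64)
        state = np.zeros(n, dtype=np.int8)  # 0 new, 1 in stack, 2 done
        for start in range(n):
            if state[start] == 2:
                continue
            stack = [start]
            while stack:
                i = stack[-1]
                if state[i] == 2:
                    stack.pop()
                    continue
                state[i] = 1
                pending = [p for p in (sire[i], dam[i]) if p >= 0 and state[p] != 2]
                if any(state[p] == 1 for p in pending):
                    raise DataError(
                        f"pedigree cycle detected involving animal {animals[i]!r}"
                    )
                if pending:
                    stack.extend(pending)
                    continue
                d = 0
                for p in (sire[i], dam[i]):
                    if p >= 0:
                        d = max(d, depth[p] + 1)
                depth[i] = d
                state[i] = 2
                stack.pop()

        order = np.lexsort((np.arange(n), depth))  # stable within depth
        remap = np.empty(n, dtype=np.int64)
        remap[order] = np.arange(n)

        def reindex_parent(par):
            out = np.full(n, UNKNOWN, dtype=np.int64)
            src = par[order]
            known = src >= 0
            out[known] = remap[src[known]]
            return out

        new_ids = np.asarray(animals, dtype=object)[order]
        new_sire = reindex_parent(sire)
        new_dam = reindex_parent(dam)

        if "generation" in cols:
            gen = frame[cols["generation"]].to_numpy(dtype=np.int64)[order]
        else:
            gen = depth[order]

        if "sex" in cols:
            sex = np.asarray(
                [str(v).strip().upper()[:1] for v in frame[cols["sex"]]], dtype=object
            )[order]
            if not set(np.unique(sex)) <= {"M", "F"}:
                raise DataError("sex column must contain only M/F")
        else:
            sex = np.full(n, "", dtype=object)
            for i in range(n):
                s, d = new_sire[i], new_dam[i]
                if s >= 0:
                    if sex[s] == "F":
                        raise DataError(
                            f"animal {new_ids[s]!r} used as both sire and dam"
                        )
                    sex[s] = "M"
                if d >= 0:
                    if sex[d] == "M":
                        raise DataError(
                            f"animal {new_ids[d]!r} used as both sire and dam"
                        )
                    sex[d] = "F"
            sex[sex == ""] = "F"

        return cls(new_ids, new_sire, new_dam, gen, sex)

    # -- accessors ----------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def positions(self, tokens) -> np.ndarray:
        """Positional indices of ``tokens``; unknown tokens raise DataError."""
        try:
            return np.asarray([self._index[str(t)] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"animal {exc.args[0]!r} not in pedigree") from None

    def __contains__(self, token) -> bool:
        return str(token) in self._index

    def to_frame(self) -> pd.DataFrame:
        def tokens(par):
            return np.where(par >= 0, self.ids[np.maximum(par, 0)], "0")

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": tokens(self.sire),
                "dam": tokens(self.dam),
                "generation": self.generation,
                "sex": self.sex,
            }
        )

    def offspring_counts(self) -> np.ndarray:
        """Number of pedigree offspring per animal."""
        out = np.zeros(self.n, dtype=np.int64)
        for par in (self.sire, self.dam):
            known = par[par >= 0]
            np.add.at(out, known, 1)
        return out

    def founder_mask(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)
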