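"""Trait table: corrected phenotypes, pedigree EBV and their accuracies.

Phenotypes are on the corrected scale (environmental effects already
removed, mean near zero). ``accuracy`` is the reliability r² = 1 - PEV/σ²A
of the pedigree EBV. Per-trait heritability and additive variance are
treated as known (production-run estimates), not re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: default five-trait panel: heritabilities and additive variances of the
#: purebred nucleus-line traits the package targets
DEFAULT_TRAIT_NAMES = ("T1", "T2", "T3", "T4", "T5")
DEFAULT_H2 = pd.Series([0.07, 0.16, 0.38, 0.58, 0.62], index=DEFAULT_TRAIT_NAMES)
DEFAULT_VAR_A = pd.Series(
    [0.22, 2.11, 0.66, 4.93, 3459.09], index=DEFAULT_TRAIT_NAMES
)


@dataclass
class TraitTable:
    phenotypes: pd.DataFrame  # animals x traits, NaN = no record
    h2: pd.Series  # per trait, in (0, 1)
    var_a: pd.Series  # per trait, > 0
    pebv: pd.DataFrame | None = None
    accuracy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.h2 = pd.Series(self.h2, dtype=float)
        self.var_a = pd.Series(self.var_a, dtype=float)
        for t in self.trait_names:
            if not 0.0 < self.h2[t] < 1.0:
                raise ConfigurationError(f"h2 for {t} must lie in (0, 1)")
            if self.var_a[t] <= 0.0:
                raise ConfigurationError(f"additive variance for {t} must be > 0")
        if self.accuracy is not None:
            vals = self.accuracy.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.any((vals < 0) | (vals > 1)):
                    raise DataError("pEBV accuracy outside [0, 1]")

    @property
    def trait_names(self) -> list:
        return list(self.phenotypes.columns)

    @property
    def animal_ids(self) -> np.ndarray:
        return self.phenotypes.index.to_numpy(dtype=object)

    def var_e(self, trait: str) -> float:
        """Residual variance implied by h² and σ²A: σ²A (1 - h²) / h²."""
        h2 = float(self.h2[trait])
        return float(self.var_a[trait]) * (1.0 - h2) / h2

    def with_pebv(self, pebv: pd.DataFrame, accuracy: pd.DataFrame) -> "TraitTable":
        return TraitTable(self.phenotypes, self.h2, self.var_a, pebv, accuracy)
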