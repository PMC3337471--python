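"""SNP filtering, Hardy-Weinberg statistic, and dosage imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genoval.errors import DataError
from genoval.genotypes import GenotypeMatrix
from genoval.pedigree import Pedigree
from genoval.qc import (
    MendelianImputer,
    QcThresholds,
    SnpFilter,
    allele_frequency,
    filter_snps,
    hwe_chi2,
    impute_dosages,
    minor_allele_frequency,
)


def _geno(columns, chrom=None, animals=None):
    D = np.asarray(columns, dtype=float).T
    animals = animals or [f"a{i}" for i in range(D.shape[0])]
    snps = [f"s{j}" for j in range(D.shape[1])]
    return GenotypeMatrix(animals, snps, D, chrom)


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 1, 2, 1], 0.5),
            ([2, 2, 2], 1.0),
            ([2, np.nan, 0], 0.5),
        ],
    )
    def test_examples(self, column, expected):
        assert allele_frequency(_geno([column]))[0] == pytest.approx(expected)

    def test_all_missing_flagged_and_dropped(self):
        g = _geno([[np.nan, np.nan], [0.0, 1.0]])
        assert np.isnan(allele_frequency(g)[0])
        kept, rep = filter_snps(g, stage=1)
        assert list(kept.snp_ids) == ["s1"]
        assert rep.table.loc[0, "drop_reason"] == "missing"

    def test_maf_folds_frequency(self):
        g = _geno([[2, 2, 2, 0]])
        assert minor_allele_frequency(g)[0] == pytest.approx(0.25)


def _counts_to_column(n0, n1, n2):
    return [0.0] * n0 + [1.0] * n1 + [2.0] * n2


class TestHweChi2:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((25, 50, 25), 0.0),  # exact HWE proportions
            ((50, 0, 50), 100.0),  # Pearson formula at p=0.5
            ((0, 0, 100), 0.0),  # monomorphic
        ],
    )
    def test_examples(self, counts, expected):
        g = _geno([_counts_to_column(*counts)])
        assert hwe_chi2(g)[0] == pytest.approx(expected)

    def test_against_textbook_pearson(self):
        """Match an independent chi-squared computation on random SNP."""
        rng = np.random.default_rng(11)
        cols = []
        expected = []
        for _ in range(50):
            n = int(rng.integers(50, 200))
            p = rng.uniform(0.1, 0.9)
            col = rng.binomial(2, p, size=n).astype(float)
            cols.append(col)
        width = max(len(c) for c in cols)
        D = np.full((len(cols), width), np.nan)
        for i, c in enumerate(cols):
            D[i, : len(c)] = c
        g = GenotypeMatrix(
            [f"a{i}" for i in range(width)],
            [f"s{j}" for j in range(len(cols))],
            D.T,
        )
        got = hwe_chi2(g)
        for j, col in enumerate(cols):
            obs = np.bincount(col.astype(int), minlength=3)
            n = obs.sum()
            ph = (obs[1] + 2 * obs[2]) / (2 * n)
            if ph in (0.0, 1.0):
                expect = 0.0
            else:
                exp = n * np.array([(1 - ph) ** 2, 2 * ph * (1 - ph), ph**2])
                expect = stats.chisquare(obs, exp).statistic
            assert got[j] == pytest.approx(expect, abs=1e-9)

    def test_fractional_dosages_round_half_up(self):
        g = _geno([[0.5, 1.49, 1.5, 0.2]])  # classes 1, 1, 2, 0
        manual = _geno([[1, 1, 2, 0]])
        assert hwe_chi2(g)[0] == pytest.approx(hwe_chi2(manual)[0])


class TestFilterSnps:
    def test_stage1_toy_table(self):
        """Hand-enumerated 5-SNP toy: X-chrom, rare, and gappy SNP drop."""
        n = 1000
        rng = np.random.default_rng(0)
        clean = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        rare = np.zeros(n)
        rare[0] = 1.0  # freq 1/2000 = 0.0005 < 0.001
        gappy = rng.binomial(2, 0.3, size=n).astype(float)
        gappy[: int(0.15 * n)] = np.nan
        xsnp = rng.binomial(2, 0.3, size=n).astype(float)
        D = np.column_stack([clean[:, 0], xsnp, rare, gappy, clean[:, 1]])
        g = GenotypeMatrix(
            [f"a{i}" for i in range(n)],
            [f"s{j}" for j in range(5)],
            D,
            ["1", "X", "1", "1", "1"],
        )
        kept, rep = filter_snps(g, stage=1)
        assert kept.n_snp == 2
        assert list(rep.table["drop_reason"]) == [
            "none",
            "chrom",
            "maf",
            "missing",
            "none",
        ]
        assert rep.n_input == 5 and rep.n_retained == 2

    def test_all_pass_identity(self):
        rng = np.random.default_rng(1)
        g = _geno(rng.binomial(2, 0.4, size=(4, 50)).astype(float).tolist())
        kept, _ = filter_snps(g, stage=1)
        np.testing.assert_array_equal(kept.dosages, g.dosages)
        assert list(kept.snp_ids) == list(g.snp_ids)

    def test_stage2_chi2_boundary_is_strict(self):
        # counts (k, 0, k) give chi2 = 2k exactly: 302 fails, 300 passes
        rng = np.random.default_rng(2)
        clean_over = rng.binomial(2, 0.4, 302).astype(float).tolist()
        clean_under = rng.binomial(2, 0.4, 300).astype(float).tolist()
        over = _geno([_counts_to_column(151, 0, 151), clean_over])
        under = _geno([_counts_to_column(150, 0, 150), clean_under])
        assert hwe_chi2(over)[0] > 300 >= hwe_chi2(under)[0]
        _, rep_over = filter_snps(over, stage=2)
        _, rep_under = filter_snps(under, stage=2)
        # the second matrix keeps its SNP; the first drops it for chi2
        assert rep_under.table.loc[0, "drop_reason"] == "none"
        assert rep_over.table.loc[0, "drop_reason"] == "chi2"

    def test_empty_result_is_error(self):
        g = _geno([[2.0, 2.0, 2.0]])
        with pytest.raises(DataError):
            filter_snps(g, stage=2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_filter_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 40, 30
        D = rng.binomial(2, rng.uniform(0.0, 0.5, m), size=(n, m)).astype(float)
        D[rng.random(D.shape) < 0.2] = np.nan
        g = GenotypeMatrix(
            [f"a{i}" for i in range(n)], [f"s{j}" for j in range(m)], D
        )
        for stage in (1, 2):
            try:
                once, _ = filter_snps(g, stage=stage)
            except DataError:
                continue  # everything dropped: nothing to re-filter
            twice, rep = filter_snps(once, stage=stage)
            assert twice.n_snp == once.n_snp


class TestImputation:
    def _ped(self):
        return Pedigree.from_frame(
            pd.DataFrame(
                {
                    "animal": ["S", "D", "X"],
                    "sire": ["0", "0", "S"],
                    "dam": ["0", "0", "D"],
                }
            )
        )

    @pytest.mark.parametrize(
        "sire_d, dam_d, freq, expected",
        [
            (2.0, 2.0, 0.9, 2.0),  # forced transmission
            (1.0, 0.0, 0.9, 0.5),  # het sire transmits 0.5
            (np.nan, np.nan, 0.3, 0.6),  # double frequency fallback
        ],
    )
    def test_single_locus_rules(self, sire_d, dam_d, freq, expected):
        D = np.array([[sire_d], [dam_d], [np.nan]])
        g = GenotypeMatrix(["S", "D", "X"], ["s0"], D)
        out = impute_dosages(g, self._ped(), np.array([freq]))
        assert out.dosages[2, 0] == pytest.approx(expected)
        assert not np.isnan(out.dosages).any()

    def test_unknown_parent_animal_uses_frequency(self):
        g = GenotypeMatrix(["Z"], ["s0"], np.array([[np.nan]]))
        out = impute_dosages(g, self._ped(), np.array([0.3]))
        assert out.dosages[0, 0] == pytest.approx(0.6)

    def test_observed_entries_untouched(self, small_pop):
        geno = small_pop.genotypes
        out = impute_dosages(geno, small_pop.pedigree)
        obs = ~np.isnan(geno.dosages)
        np.testing.assert_array_equal(out.dosages[obs], geno.dosages[obs])
        assert not np.isnan(out.dosages).any()

    def test_beats_frequency_only_imputation(self, small_pop):
        """Masking known entries: pedigree-aware fill has lower MAE."""
        geno = small_pop.genotypes
        rng = np.random.default_rng(5)
        D = geno.dosages.copy()
        known = np.argwhere(~np.isnan(D))
        picks = known[rng.choice(len(known), 2000, replace=False)]
        truth = D[picks[:, 0], picks[:, 1]].copy()
        D[picks[:, 0], picks[:, 1]] = np.nan
        masked = GenotypeMatrix(geno.animal_ids, geno.snp_ids, D, geno.chrom)
        freq = allele_frequency(masked)
        out = impute_dosages(masked, small_pop.pedigree, freq)
        sap = out.dosages[picks[:, 0], picks[:, 1]]
        mae_sap = np.abs(sap - truth).mean()
        mae_freq = np.abs(2 * freq[picks[:, 1]] - truth).mean()
        assert mae_sap < mae_freq


class TestEstimators:
    def test_snp_filter_transform(self, small_pop):
        geno = small_pop.genotypes
        est = SnpFilter(stage=1, thresholds=QcThresholds())
        out = est.fit(geno).transform(geno)
        assert out.n_snp == est.report_.n_retained
        assert est.get_params()["stage"] == 1

    def test_imputer_round(self, small_pop):
        est = MendelianImputer(pedigree=small_pop.pedigree)
        out = est.fit(small_pop.genotypes).transform(small_pop.genotypes)
        assert not np.isnan(out.dosages).any()
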