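import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from triohet import (
    ROLE_F1,
    ROLE_FEMALE,
    ROLE_MALE,
    gene_expression_heterosis,
    heterosis_indices,
    mph_from_oph_bph,
    phenotype_heterosis,
    simulate_phenotype,
)
from triohet.datasets import nicotine_heterosis_table, nicotine_trial_means

positive = st.floats(min_value=0.01, max_value=1e4)


class TestHeterosisIndices:
    def test_mid_parent_identity(self):
        h = heterosis_indices(1.5, 1.0, 2.0)
        assert h.mph_pct == pytest.approx(0.0)

    def test_equal_parents_collapse_indices(self):
        h = heterosis_indices(1.2, 1.0, 1.0)
        assert h.oph_pct == h.mph_pct == h.bph_pct == pytest.approx(20.0)

    def test_direct_arithmetic(self):
        h = heterosis_indices(2.0, 1.0, 1.5)
        assert h.oph_pct == pytest.approx(100 / 3)
        assert h.mph_pct == pytest.approx(60.0)
        assert h.bph_pct == pytest.approx(100.0)

    def test_parent_order_irrelevant(self):
        a = heterosis_indices(2.0, 1.0, 1.5)
        b = heterosis_indices(2.0, 1.5, 1.0)
        assert a == b

    def test_nonpositive_parent_rejected(self):
        with pytest.raises(ValueError):
            heterosis_indices(1.0, 0.0, 1.0)

    @given(positive, positive, positive)
    def test_round_trip_identity(self, f1, p1, p2):
        h = heterosis_indices(f1, p1, p2)
        assert mph_from_oph_bph(h.oph_pct, h.bph_pct) == pytest.approx(
            h.mph_pct, rel=1e-9, abs=1e-9
        )

    @given(positive, positive, positive)
    def test_index_ordering(self, f1, p1, p2):
        h = heterosis_indices(f1, p1, p2)
        assert h.oph_pct <= h.mph_pct + 1e-9
        assert h.mph_pct <= h.bph_pct + 1e-9

    @given(positive, positive, positive)
    def test_f1_above_high_parent_makes_all_positive(self, hp_margin, p1, p2):
        f1 = max(p1, p2) * 1.01 + hp_margin
        h = heterosis_indices(f1, p1, p2)
        assert h.oph_pct > 0 and h.mph_pct > 0 and h.bph_pct > 0


class TestMphFromOphBph:
    @pytest.mark.parametrize("oph,bph,expected", [(0, 0, 0), (10, 10, 10)])
    def test_degenerate_cases(self, oph, bph, expected):
        assert mph_from_oph_bph(oph, bph) == pytest.approx(expected)

    @pytest.mark.parametrize("oph,bph,expected", [(24.65, 46.18, 34.56), (33.48, 58.26, 44.82)])
    def test_published_nicotine_rows(self, oph, bph, expected):
        assert mph_from_oph_bph(oph, bph) == pytest.approx(expected, abs=0.005)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            mph_from_oph_bph(-100.0, 10.0)


class TestPhenotypeHeterosis:
    def _table(self, f1, pf, pm, year=2015, stage="AT", reps=3):
        rows = []
        for geno, mean in ((ROLE_FEMALE, pf), (ROLE_MALE, pm), (ROLE_F1, f1)):
            for r in range(1, reps + 1):
                rows.append({"genotype": geno, "year": year, "stage": stage,
                             "replicate": r, "value": mean})
        return pd.DataFrame(rows)

    def test_mid_parent_f1_gives_zero_mph(self):
        het = phenotype_heterosis(self._table(1.75, 1.5, 2.0))
        assert het["mph_pct"].iloc[0] == pytest.approx(0.0)

    def test_noiseless_constructed_means_recover_mph(self):
        # F1 = 1.4482 * MP
        pf, pm = 2.0, 3.0
        het = phenotype_heterosis(self._table(1.4482 * 2.5, pf, pm))
        assert het["mph_pct"].iloc[0] == pytest.approx(44.82, abs=1e-9)

    def test_replicate_order_invariance(self):
        t = self._table(2.6, 1.5, 2.0)
        t2 = t.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(phenotype_heterosis(t), phenotype_heterosis(t2))

    def test_missing_genotype_names_cell(self):
        t = self._table(2.6, 1.5, 2.0)
        t = t[t["genotype"] != ROLE_MALE]
        with pytest.raises(ValueError, match="2015"):
            phenotype_heterosis(t)

    def test_builtin_trial_means_recover_published_indices(self):
        pheno = simulate_phenotype(nicotine_trial_means(), noise_sd=0.0, seed=0)
        het = phenotype_heterosis(pheno).set_index(["year", "stage"])
        ref = nicotine_heterosis_table().set_index(["year", "stage"])
        for cell in ref.index:
            assert het.loc[cell, "oph_pct"] == pytest.approx(ref.loc[cell, "oph_pct"], abs=1e-9)
            assert het.loc[cell, "bph_pct"] == pytest.approx(ref.loc[cell, "bph_pct"], abs=1e-9)
            # MPH only up to the rounding of the published inputs
            assert het.loc[cell, "mph_pct"] == pytest.approx(ref.loc[cell, "mph_pct"], abs=0.01)


class TestGeneExpressionHeterosis:
    def _fpkm(self, rows):
        idx = [f"g{i}" for i in range(len(rows))]
        fpkm = pd.DataFrame(rows, index=idx, columns=["s1", "s2", "s3"])
        meta = pd.DataFrame(
            {"role": [ROLE_FEMALE, ROLE_MALE, ROLE_F1], "replicate": [1, 1, 1]},
            index=pd.Index(["s1", "s2", "s3"], name="sample"),
        )
        return fpkm, meta

    def test_f1_equal_high_parent_zero_oph(self):
        fpkm, meta = self._fpkm([[2.0, 4.0, 4.0]])
        out = gene_expression_heterosis(fpkm, meta)
        assert out["oph_pct"].iloc[0] == pytest.approx(0.0)

    def test_all_equal_means_all_zero(self):
        fpkm, meta = self._fpkm([[3.0, 3.0, 3.0]])
        out = gene_expression_heterosis(fpkm, meta)
        assert out[["oph_pct", "mph_pct", "bph_pct"]].iloc[0].tolist() == [0, 0, 0]

    def test_four_fold_overdominant_gene(self):
        fpkm, meta = self._fpkm([[1.0, 1.0, 4.0]])
        out = gene_expression_heterosis(fpkm, meta)
        assert out["oph_pct"].iloc[0] == pytest.approx(300.0)

    def test_zero_parent_flagged_not_dropped(self):
        fpkm, meta = self._fpkm([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0]])
        out = gene_expression_heterosis(fpkm, meta)
        assert not out["ok"].iloc[0] and np.isnan(out["oph_pct"].iloc[0])
        assert out["ok"].iloc[1]
        assert len(out) == 2
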