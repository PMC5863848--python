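import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from triohet import (
    ROLE_F1,
    ROLE_FEMALE,
    ROLE_MALE,
    SimulationConfig,
    bh_adjust,
    call_deg,
    estimate_size_factors,
    nb_test,
    simulate_trio_counts,
)

from conftest import make_trio


def brute_force_bh(p):
    """Textbook step-up: q_(i) = min_{j>=i} ( m * p_(j) / j )."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 11)[:, None], (1, 3)) * 7
        sf = estimate_size_factors(make_trio(counts))
        np.testing.assert_allclose(sf, 1.0)

    def test_two_by_two_hand_computation(self):
        # genes (10,20) and (30,60): geometric means sqrt(200), sqrt(1800);
        # every ratio in column 1 is 1/sqrt(2), in column 2 sqrt(2)
        counts = pd.DataFrame([[10, 20], [30, 60]], index=["g1", "g2"], columns=["a", "b"])
        sf = estimate_size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_doubling_one_column_doubles_its_factor(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 200, size=(10, 3))
        sf1 = estimate_size_factors(make_trio(counts))
        counts2 = counts.copy()
        counts2[:, 1] *= 2
        sf2 = estimate_size_factors(make_trio(counts2))
        # doubling one column scales its own factor by 2^(2/3) relative to
        # the others' 2^(-1/3): the *ratio* doubles
        assert (sf2.iloc[1] / sf2.iloc[0]) / (sf1.iloc[1] / sf1.iloc[0]) == pytest.approx(2.0)

    def test_no_common_positive_gene_raises_with_fallback_hint(self):
        counts = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5]])
        with pytest.raises(ValueError, match="pseudo"):
            estimate_size_factors(make_trio(counts))
        sf = estimate_size_factors(make_trio(counts), allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestBhAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_three_ordered(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_exhaustive_small_vectors(self):
        grid = [0.01, 0.2, 0.5, 0.75, 0.99]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), brute_force_bh(combo), atol=1e-12
                )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_matches_brute_force_random(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_nan_rejected_with_indices(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            bh_adjust([0.1, np.nan, 0.2])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestNbTest:
    def test_identical_groups_null_result(self):
        counts = np.tile(np.arange(10, 110, 10)[:, None], (1, 3))
        trio = make_trio(counts)
        tbl = nb_test(trio, (ROLE_FEMALE, ROLE_F1), "fixed:0.1")
        np.testing.assert_allclose(tbl["log2fc"], 0.0)
        assert (tbl["p_raw"] >= 0.99).all()

    def test_poisson_single_library_matches_conditional_binomial(self):
        # With alpha=0 and unit size factors, k1 vs k2 is exactly
        # k2 | k1+k2 ~ Binomial(k1+k2, 1/2); the NB Wald p must track it.
        pairs = [(450, 500), (300, 360), (800, 880), (500, 500), (200, 260), (1000, 1150)]
        for k1, k2 in pairs:
            counts = np.array([[k1, k1, k2], [k1, k1, k1]])  # second gene balances sf
            trio = make_trio(counts)
            sf = pd.Series(1.0, index=trio.counts.columns)
            tbl = nb_test(trio, (ROLE_FEMALE, ROLE_F1), "fixed:0", size_factors=sf)
            exact = stats.binomtest(k2, k1 + k2, 0.5).pvalue
            assert abs(tbl["p_raw"].iloc[0] - exact) <= 0.02, (k1, k2)

    def test_null_type_one_error_in_band(self):
        cfg = SimulationConfig(
            n_genes=2000, class_proportions={"null": 1.0}, n_replicates=3,
            dispersion=0.1, seed=11,
        )
        trio, _, _ = simulate_trio_counts(cfg)
        tbl = nb_test(trio, (ROLE_FEMALE, ROLE_F1), "per_group")
        frac = float((tbl["p_raw"] < 0.05).mean())
        assert 0.025 <= frac <= 0.10

    def test_swapping_contrast_negates_lfc_keeps_p(self, tiny_trio):
        fwd = nb_test(tiny_trio, (ROLE_FEMALE, ROLE_F1), "fixed:0.05")
        rev = nb_test(tiny_trio, (ROLE_F1, ROLE_FEMALE), "fixed:0.05")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)

    def test_per_group_requires_replicates(self, tiny_trio):
        with pytest.raises(ValueError, match="replicates"):
            nb_test(tiny_trio, (ROLE_FEMALE, ROLE_F1), "per_group")

    def test_negative_fixed_dispersion_rejected(self, tiny_trio):
        with pytest.raises(ValueError, match="dispersion"):
            nb_test(tiny_trio, (ROLE_FEMALE, ROLE_F1), "fixed:-1")


class TestCallDeg:
    @pytest.mark.parametrize(
        "p,lfc,expected",
        [
            (0.04, 1.5, "up"),
            (0.04, 0.5, "ns"),
            (0.5, 5.0, "ns"),
            (0.04, -1.5, "down"),
            (0.05, 1.0, "up"),  # thresholds are inclusive
        ],
    )
    def test_threshold_logic(self, p, lfc, expected):
        tbl = pd.DataFrame({"log2fc": [lfc], "p_raw": [p], "q_bh": [p]}, index=["g"])
        out = call_deg(tbl, alpha=0.05, min_fold=2.0)
        assert out["call"].iloc[0] == expected

    def test_raw_p_mode(self):
        tbl = pd.DataFrame({"log2fc": [2.0], "p_raw": [0.01], "q_bh": [0.2]}, index=["g"])
        assert call_deg(tbl)["call"].iloc[0] == "ns"
        assert call_deg(tbl, use_adjusted=False)["call"].iloc[0] == "up"

    def test_parameter_validation(self):
        tbl = pd.DataFrame({"log2fc": [0.0], "p_raw": [1.0], "q_bh": [1.0]})
        with pytest.raises(ValueError):
            call_deg(tbl, alpha=0.0)
        with pytest.raises(ValueError):
            call_deg(tbl, min_fold=0.5)
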