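"""Min-max scaling, pair enumeration and NDWTI algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ndwti.texture_index import (
    NDWTIPair,
    apply_minmax,
    canonical_pair_name,
    compute_ndwti,
    enumerate_pairs,
    fit_minmax,
    ndwti_table,
    pair_name,
    split_pair_name,
)
from ndwti.wavelet import wt_feature_names

scaled_values = st.floats(0.0, 1.5, allow_nan=False)


class TestMinMax:
    def test_scaled_training_column(self):
        params = fit_minmax(pd.DataFrame({"f": [2.0, 4.0, 6.0]}))
        out = apply_minmax(params, pd.DataFrame({"f": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_constant_column_scales_to_zero(self):
        params = fit_minmax(pd.DataFrame({"f": [3.0, 3.0, 3.0]}))
        out = apply_minmax(params, pd.DataFrame({"f": [3.0, 7.0]}))
        np.testing.assert_allclose(out["f"], [0.0, 0.0])

    def test_training_extremes_hit_zero_and_one(self, rng):
        df = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        out = apply_minmax(fit_minmax(df), df)
        np.testing.assert_allclose(out.min(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.max(), 1.0, atol=1e-12)

    def test_out_of_range_value_not_clipped(self):
        params = fit_minmax(pd.DataFrame({"f": [2.0, 6.0]}))
        out = apply_minmax(params, pd.DataFrame({"f": [8.0]}))
        assert out["f"].iloc[0] == pytest.approx(1.5)

    def test_value_at_training_min_is_zero(self):
        params = fit_minmax(pd.DataFrame({"f": [2.0, 6.0]}))
        assert apply_minmax(params, pd.DataFrame({"f": [2.0]}))["f"].iloc[0] == 0.0

    def test_unknown_feature_rejected(self):
        params = fit_minmax(pd.DataFrame({"f": [2.0, 6.0]}))
        with pytest.raises(KeyError):
            apply_minmax(params, pd.DataFrame({"g": [1.0]}))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_minmax(pd.DataFrame({"f": [1.0]}))


class TestPairEnumeration:
    def test_full_wt_set_yields_4032_ordered_pairs(self):
        names = wt_feature_names()
        pairs = enumerate_pairs(names)
        assert len(pairs) == 4032  # 64 * 63

    def test_class_partition_counts(self):
        """2256 high-high, 240 low-low, 1536 mixed: 48*47 + 16*15 + 2*16*48."""
        names = wt_feature_names()
        assert len(enumerate_pairs(names, "high_high")) == 2256
        assert len(enumerate_pairs(names, "low_low")) == 240
        assert len(enumerate_pairs(names, "low_high")) == 1536

    def test_low_frequency_restriction(self):
        low = [n for n in wt_feature_names() if n.startswith("LL")]
        assert len(low) == 16
        assert len(enumerate_pairs(low)) == 240

    def test_three_arbitrary_names(self):
        assert len(enumerate_pairs(["a1", "b2", "c3"])) == 6

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(["x", "x"])

    def test_class_from_subband_prefixes(self):
        assert NDWTIPair("LL_NIR_Var", "LL_Red_Mea").pair_class == "low_low"
        assert NDWTIPair("HH_NIR_Var", "LH_Red_Mea").pair_class == "high_high"
        assert NDWTIPair("LL_NIR_Var", "HH_NIR_Ene").pair_class == "low_high"


class TestPairNames:
    @pytest.mark.parametrize(
        "wt1,wt2",
        [
            ("LL_NIR_Var", "LL_Red_Mea"),
            ("LL_Red-edge_Mea", "HH_Red_Ent"),  # hyphenated band label
            ("HH_Red-edge_Var", "LH_Red-edge_Ent"),
        ],
    )
    def test_split_inverts_format(self, wt1, wt2):
        assert split_pair_name(pair_name(wt1, wt2)) == (wt1, wt2)

    def test_canonical_name_orientation_free(self):
        a = pair_name("LL_NIR_Var", "LL_Red_Mea")
        b = pair_name("LL_Red_Mea", "LL_NIR_Var")
        assert canonical_pair_name(a) == canonical_pair_name(b)


class TestComputeNdwti:
    def test_equal_inputs_give_zero(self):
        assert compute_ndwti(0.4, 0.4) == 0.0

    def test_worked_example(self):
        assert compute_ndwti(0.8, 0.2) == pytest.approx(0.6)

    def test_zero_sum_guard(self):
        assert compute_ndwti(0.0, 0.0) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(a=scaled_values, b=scaled_values)
    def test_antisymmetry_and_range(self, a, b):
        x = compute_ndwti(a, b)
        assert x == pytest.approx(-compute_ndwti(b, a), abs=1e-12)
        assert -1.0 <= x <= 1.0


class TestNdwtiTable:
    def test_reversed_pair_has_equal_abs_spearman(self, rng):
        """|rho| with any response is identical for a pair and its reversal
        (antisymmetry of the index)."""
        scaled = pd.DataFrame(
            rng.random((30, 3)), columns=["LL_NIR_Var", "LL_Red_Mea", "HH_NIR_Ene"]
        )
        y = rng.random(30)
        pairs = enumerate_pairs(list(scaled.columns))
        table = ndwti_table(scaled, pairs)
        fwd = table[pair_name("LL_NIR_Var", "HH_NIR_Ene")]
        rev = table[pair_name("HH_NIR_Ene", "LL_NIR_Var")]
        r_f = stats.spearmanr(fwd, y).statistic
        r_r = stats.spearmanr(rev, y).statistic
        assert abs(r_f) == pytest.approx(abs(r_r), abs=1e-12)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_table_shape_and_column_names(self, rng):
        scaled = pd.DataFrame(rng.random((5, 3)), columns=["LL_a_b", "LH_c_d", "HH_e_f"])
        table = ndwti_table(scaled, enumerate_pairs(list(scaled.columns)))
        assert table.shape == (5, 6)
        assert "NDWTI(LL_a_b-LH_c_d)" in table.columns
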