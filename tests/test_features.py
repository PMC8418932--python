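import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegfocus.features import (
    EntropyConfig,
    FeatureMatrix,
    extract_features,
    feature_names,
    kws_mask,
    kws_pvalues,
    le_entropy,
    ll2_entropy,
    sure_entropy,
    th_entropy,
)
from eegfocus.tqwt import decompose, design_params

CFG = EntropyConfig()

finite_seqs = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=1, max_size=30
)


class TestEntropyValues:
    def test_le_examples(self):
        assert le_entropy([1.0]) == 0.0
        assert le_entropy([0.0, 0.0, 0.0]) == 0.0
        # log(4) + log(1/4) cancels in any base
        assert le_entropy([2.0, 0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_le_log_base_switch(self):
        cfg2 = EntropyConfig(log_base=2)
        assert le_entropy([2.0], cfg2) == pytest.approx(2.0)  # log2(4)
        assert le_entropy([2.0]) == pytest.approx(np.log(4.0))

    def test_ll2_examples(self):
        assert ll2_entropy([1.0, 0.0, 0.0]) == 0.0
        assert ll2_entropy([3.0, 4.0]) == pytest.approx(np.log(25.0), abs=1e-12)

    def test_ll2_scaling_property(self, rng):
        s = rng.standard_normal(20)
        c = 3.7
        assert ll2_entropy(c * s) == pytest.approx(
            ll2_entropy(s) + 2 * np.log(abs(c)), abs=1e-10
        )

    def test_ll2_all_zero_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert ll2_entropy([0.0, 0.0]) == 0.0

    def test_sure_examples(self):
        assert sure_entropy([0.0, 0.0]) == 0.0
        # 3 - 1 + (0.01 + 0.04 + 0.04)
        assert sure_entropy([0.1, 0.3, 0.5]) == pytest.approx(2.09, abs=1e-12)

    def test_sure_closed_form_large_coeffs(self):
        # all |s_i| >> eps: n kept + n*eps^2 from the clipped sum
        s = np.full(7, 5.0)
        assert sure_entropy(s) == pytest.approx(7 + 7 * 0.04, abs=1e-12)

    def test_th_examples(self):
        assert th_entropy([0.1, 0.3, 0.5]) == 2.0
        assert th_entropy([0.0, 0.0]) == 0.0
        # ties at exactly eps count as below threshold
        assert th_entropy([0.2, -0.2]) == 0.0
        # thresholds compare magnitudes, not signed values
        assert th_entropy([-0.5, -0.1]) == 1.0

    @pytest.mark.parametrize(
        "func", [le_entropy, ll2_entropy, sure_entropy, th_entropy]
    )
    def test_empty_input_rejected(self, func):
        with pytest.raises(ValueError):
            func([])

    @settings(max_examples=25, deadline=None)
    @given(finite_seqs)
    def test_permutation_invariance(self, s):
        s = np.array(s)
        perm = np.random.default_rng(1).permutation(len(s))
        for func in (le_entropy, ll2_entropy, sure_entropy, th_entropy):
            assert func(s) == pytest.approx(func(s[perm]), rel=1e-9, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(finite_seqs, st.integers(0, 29), st.floats(0.3, 10))
    def test_threshold_entropies_monotone_in_magnitude(self, s, idx, bump):
        s = np.array(s)
        idx = idx % len(s)
        grown = s.copy()
        grown[idx] = np.sign(grown[idx] or 1.0) * (abs(grown[idx]) + bump)
        assert th_entropy(grown) >= th_entropy(s)
        assert sure_entropy(grown) >= sure_entropy(s) - 1e-12


class TestFeatureVector:
    def test_dimension_is_four_per_subband(self, rng):
        sb = decompose(rng.standard_normal(10239), design_params(3, 3, 26))
        vec = extract_features(sb)
        assert vec.shape == (108,)
        assert np.isfinite(vec).all()

    def test_minimal_dimension(self, rng):
        sb = decompose(rng.standard_normal(256), design_params(3, 3, 1))
        assert extract_features(sb).shape == (8,)

    def test_block_structure_follows_subband_shuffle(self, rng):
        """Shuffling subband order permutes all four entropy blocks alike."""
        sb = decompose(rng.standard_normal(1024), design_params(3, 3, 4))
        vec = extract_features(sb)
        perm = [2, 0, 3, 1, 4]
        shuffled = decompose(rng.standard_normal(1024), design_params(3, 3, 4))
        seqs = sb.subbands
        shuffled.details = [seqs[i] for i in perm[:-1]]
        shuffled.approximation = seqs[perm[-1]]
        vec_shuffled = extract_features(shuffled)
        k = len(perm)
        for block in range(4):
            np.testing.assert_allclose(
                vec_shuffled[block * k : (block + 1) * k],
                vec[block * k : (block + 1) * k][perm],
            )

    def test_feature_names_layout(self):
        names = feature_names(2)
        assert names == [
            "LE_d1", "LE_d2", "LE_a2",
            "LL2_d1", "LL2_d2", "LL2_a2",
            "SURE_d1", "SURE_d2", "SURE_a2",
            "TH_d1", "TH_d2", "TH_a2",
        ]


def _permutation_pvalue(a, b, n_draws=10000, seed=0):
    """Independent oracle: label-permutation null of the KW H statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = stats.kruskal(a, b).statistic
    count = 0
    for _ in range(n_draws):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[: len(a)]], pooled[perm[len(a) :]]
        if stats.kruskal(pa, pb).statistic >= observed:
            count += 1
    return count / n_draws


class TestKruskalWallisScreening:
    def test_identical_distributions_give_p_near_one(self, rng):
        block = rng.standard_normal((10, 4))
        m = FeatureMatrix(
            np.vstack([block, block]),
            ["focal"] * 10 + ["nonfocal"] * 10,
        )
        assert (kws_pvalues(m) > 0.9).all()
        assert not kws_mask(m).any()

    def test_separated_feature_highly_significant(self, rng):
        lo = rng.uniform(0, 1, (20, 1))
        hi = rng.uniform(5, 6, (20, 1))
        m = FeatureMatrix(np.vstack([lo, hi]), ["focal"] * 20 + ["nonfocal"] * 20)
        assert kws_pvalues(m)[0] < 1e-6
        assert kws_mask(m)[0]

    def test_matches_permutation_null_on_toy_columns(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(8) + 1.0  # moderate shift: mid-range p
        m = FeatureMatrix(
            np.concatenate([a, b])[:, None], ["focal"] * 8 + ["nonfocal"] * 8
        )
        p_chi2 = kws_pvalues(m)[0]
        p_perm = _permutation_pvalue(a, b)
        assert p_chi2 == pytest.approx(p_perm, abs=0.05)

    def test_single_class_rejected(self, rng):
        m = FeatureMatrix(rng.standard_normal((6, 2)), ["focal"] * 6)
        with pytest.raises(ValueError):
            kws_pvalues(m)

    def test_constant_column_gets_p_one(self, rng):
        vals = np.column_stack([np.ones(12), rng.standard_normal(12)])
        m = FeatureMatrix(vals, ["focal"] * 6 + ["nonfocal"] * 6)
        assert kws_pvalues(m)[0] == 1.0


class TestFeatureMatrix:
    def test_select_restricts_columns(self, rng):
        m = FeatureMatrix(rng.standard_normal((4, 3)), ["focal", "focal",
                          "nonfocal", "nonfocal"], ["a", "b", "c"])
        sub = m.select([True, False, True])
        assert sub.feature_names == ["a", "c"]
        np.testing.assert_array_equal(sub.values, m.values[:, [0, 2]])

    def test_csv_roundtrip(self, tmp_path, rng):
        m = FeatureMatrix(
            rng.standard_normal((4, 2)), ["focal"] * 2 + ["nonfocal"] * 2
        )
        m.to_csv(tmp_path / "m.csv")
        back = FeatureMatrix.from_csv(tmp_path / "m.csv")
        np.testing.assert_allclose(back.values, m.values)
        assert back.labels.tolist() == m.labels.tolist()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.array([[np.nan]]), ["focal"])


def test_focal_class_has_lower_entropy_mid_low_subbands(small_matrix):
    """Focal-like records are less random: their mean LE and LL2 sit below
    the nonfocal class in most mid/low-frequency subbands."""
    m = small_matrix
    focal = m.values[m.labels == "focal"].mean(axis=0)
    nonfocal = m.values[m.labels == "nonfocal"].mean(axis=0)
    names = m.feature_names
    for ent in ("LE", "LL2"):
        idx = [
            i
            for i, n in enumerate(names)
            if n.startswith(ent + "_") and not n.endswith(("d1", "d2", "d3"))
        ]
        lower = sum(focal[i] < nonfocal[i] for i in idx)
        assert lower > len(idx) / 2
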