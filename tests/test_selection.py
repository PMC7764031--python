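"""Greedy reversed-correlation selection against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eegselect as es
from eegselect.bands import FeatureMatrix
from eegselect.selection import FIXED_SETS


# ---------------------------------------------------------------------------
# Independent oracle: explicit loops, scipy pearsonr, no shared code paths
# ---------------------------------------------------------------------------

def oracle_greedy(values, n_select):
    """Brute-force evaluation of the greedy minimum-mean-|r| criterion."""
    n, p = values.shape

    def absr(i, j):
        return abs(stats.pearsonr(values[:, i], values[:, j]).statistic)

    selected = []
    remaining = list(range(p))
    # step 1: lowest mean |r| against all other columns
    means = []
    for i in remaining:
        means.append(np.mean([absr(i, j) for j in remaining if j != i]))
    first = remaining[int(np.argmin(_tie_round(means)))]
    selected.append(first)
    remaining.remove(first)
    # later steps: lowest mean |r| against the selected set
    while len(selected) < n_select:
        means = [
            np.mean([absr(i, j) for j in selected]) for i in remaining
        ]
        nxt = remaining[int(np.argmin(_tie_round(means)))]
        selected.append(nxt)
        remaining.remove(nxt)
    return selected


def _tie_round(means):
    # argmin with the implementation's tie rule: lower index wins within 1e-12
    m = np.asarray(means)
    return np.where(m <= m.min() + 1e-12, m.min(), m)


def _fm(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {"subject": "S", "trial": np.arange(len(values)), "second": 0}
    )
    return FeatureMatrix(values, names, meta)


def _random_matrix(rng, n_rows, n_cols):
    """Random covariance structures: blocks, noise, affine mixtures."""
    kind = rng.integers(3)
    if kind == 0:
        return rng.standard_normal((n_rows, n_cols))
    if kind == 1:  # random loading structure
        k = rng.integers(1, max(2, n_cols // 2))
        load = rng.standard_normal((n_cols, k))
        fac = rng.standard_normal((n_rows, k))
        return fac @ load.T + 0.3 * rng.standard_normal((n_rows, n_cols))
    base = rng.standard_normal((n_rows, n_cols))  # clone-ish blocks
    for j in range(1, n_cols, 3):
        base[:, j] = base[:, j - 1] + 0.2 * rng.standard_normal(n_rows)
    return base


class TestCorrelationMatrix:
    def test_affine_dependence_gives_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        C = es.correlation_matrix(_fm(np.column_stack([a, 2 * a + 3])))
        assert C[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_independent_columns_near_zero_matches_pearson_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 10000))
        C = es.correlation_matrix(_fm(np.column_stack([x, y])))
        # brute-force Pearson on the same draw
        expected = abs(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert C[0, 1] == pytest.approx(expected, abs=1e-12)
        assert C[0, 1] < 0.05

    def test_anticorrelated_counts_as_fully_redundant(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        C = es.correlation_matrix(_fm(np.column_stack([a, -a])))
        assert C[0, 1] == pytest.approx(1.0)

    def test_signed_mode_keeps_sign(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        C = es.correlation_matrix(_fm(np.column_stack([a, -a])), absolute=False)
        assert C[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_column_errors_with_names(self):
        X = _fm(np.column_stack([np.ones(20), np.arange(20.0)]), ["const", "ramp"])
        with pytest.raises(ValueError, match="const"):
            es.correlation_matrix(X)


class TestDropConstant:
    def test_drops_and_reports(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((30, 4))
        values[:, 2] = 0.0
        X = _fm(values)
        reduced, dropped = es.drop_constant(X)
        assert dropped == ["f2"]
        assert reduced.feature_names == ["f0", "f1", "f3"]
        np.testing.assert_array_equal(reduced.values, values[:, [0, 1, 3]])

    def test_identity_when_all_variable(self):
        X = _fm(np.random.default_rng(4).standard_normal((30, 3)))
        reduced, dropped = es.drop_constant(X)
        assert dropped == []
        np.testing.assert_array_equal(reduced.values, X.values)

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            es.drop_constant(_fm(np.ones((10, 3))))


class TestFixedSets:
    def test_all_sets_have_three_canonical_features(self):
        band_names = {b.name for b in es.DEFAULT_BANDS}
        for s in FIXED_SETS.values():
            assert len(s.features) == 3
            for feat in s.features:
                ch, band = feat.rsplit("_", 1)
                assert ch in es.DEAP_CHANNEL_ORDER
                assert band in band_names

    @pytest.mark.parametrize(
        "set_id, features, emotions",
        [
            ("CHS1", ("PO4_theta", "FC6_beta", "Cz_beta"), {"valence"}),
            ("CHS2", ("CP6_theta", "Cz_alpha", "FC2_beta"), {"arousal"}),
            ("CHS3", ("FC2_beta", "FC6_beta", "Cz_beta"), {"valence"}),
            ("CHS4", ("PO4_beta", "FC1_beta", "FC6_beta"), {"arousal"}),
            ("CHS5", ("FC6_beta", "P4_theta", "PO4_theta"), {"valence"}),
            ("CHS6", ("Cz_beta", "Fz_beta", "Pz_beta"), {"valence", "arousal"}),
            ("CHS7", ("Cz_theta", "Fz_theta", "Pz_theta"), {"valence", "arousal"}),
        ],
    )
    def test_registry_contents(self, set_id, features, emotions):
        s = es.get_fixed_set(set_id)
        assert s.features == features
        assert s.emotions == emotions

    def test_unknown_id(self):
        with pytest.raises(KeyError, match="CHS9"):
            es.get_fixed_set("CHS9")


class TestGreedySelection:
    def test_clone_pair_plus_independent(self):
        rng = np.random.default_rng(5)
        f3 = rng.standard_normal(200)
        f1 = rng.standard_normal(200)
        f2 = f1 + 0.01 * rng.standard_normal(200)
        X = _fm(np.column_stack([f1, f2, f3]), ["f1", "f2", "f3"])
        assert es.rca_select(X, 1).selected == ("f3",)
        full = es.rca_select(X, 3)
        assert full.selected[0] == "f3"
        assert set(full.selected) == {"f1", "f2", "f3"}

    def test_invalid_n(self):
        X = _fm(np.random.default_rng(6).standard_normal((50, 4)))
        with pytest.raises(ValueError):
            es.rca_select(X, 0)
        with pytest.raises(ValueError):
            es.rca_select(X, 5)

    def test_constant_columns_excluded_and_reported(self):
        rng = np.random.default_rng(7)
        values = rng.standard_normal((100, 5))
        values[:, 1] = 7.0
        X = _fm(values)
        res = es.rca_select(X, 4)
        assert res.dropped_constant == ("f1",)
        assert "f1" not in res.selected
        assert len(res.selected) == 4

    def test_scores_are_nonnegative_and_sized(self):
        X = _fm(np.random.default_rng(8).standard_normal((80, 6)))
        res = es.rca_select(X, 4)
        assert len(res.scores) == 4
        assert all(s >= 0 for s in res.scores)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = int(rng.integers(4, 21))
        n_rows = int(rng.integers(50, 501))
        values = _random_matrix(rng, n_rows, n_cols)
        n_sel = int(rng.integers(1, n_cols + 1))
        got = es.ReversedCorrelationSelector(n_features_to_select=n_sel).fit(values)
        assert got.selection_order_ == oracle_greedy(values, n_sel)

    def test_block_covariance_example_against_oracle(self):
        rng = np.random.default_rng(42)
        lat = rng.standard_normal((200, 2))
        values = np.column_stack(
            [
                lat[:, 0] + 0.1 * rng.standard_normal(200),
                lat[:, 0] + 0.1 * rng.standard_normal(200),
                lat[:, 0] + 0.1 * rng.standard_normal(200),
                lat[:, 1] + 0.1 * rng.standard_normal(200),
                lat[:, 1] + 0.1 * rng.standard_normal(200),
                rng.standard_normal(200),
            ]
        )
        sel = es.ReversedCorrelationSelector(n_features_to_select=6).fit(values)
        assert sel.selection_order_ == oracle_greedy(values, 6)
        assert sel.selection_order_[0] == 5  # the independent column first


class TestSelectorInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_affine_rescaling_leaves_selection_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        values = _random_matrix(rng, 150, 8)
        base = es.rca_select(_fm(values), 4).selected
        scale = rng.uniform(0.1, 10.0, 8)
        offset = rng.uniform(-5.0, 5.0, 8)
        transformed = es.rca_select(_fm(values * scale + offset), 4).selected
        assert transformed == base

    def test_labels_are_never_consulted(self):
        rng = np.random.default_rng(10)
        values = _random_matrix(rng, 120, 6)
        sel = es.ReversedCorrelationSelector(n_features_to_select=3)
        a = sel.fit(values, y=rng.integers(0, 2, 120)).selection_order_
        b = sel.fit(values, y=None).selection_order_
        c = sel.fit(values, y=rng.permutation(120)).selection_order_
        assert a == b == c

    def test_deterministic(self):
        values = _random_matrix(np.random.default_rng(11), 100, 7)
        r1 = es.rca_select(_fm(values), 5)
        r2 = es.rca_select(_fm(values.copy()), 5)
        assert r1 == r2


class TestSklearnInterface:
    def test_transform_and_support(self):
        values = np.random.default_rng(12).standard_normal((60, 5))
        sel = es.ReversedCorrelationSelector(n_features_to_select=2).fit(values)
        out = sel.transform(values)
        assert out.shape == (60, 2)
        assert sel.support_.sum() == 2
        assert sel.get_support(indices=True).tolist() == sorted(
            sel.selection_order_
        )

    def test_get_set_params_round_trip(self):
        sel = es.ReversedCorrelationSelector(n_features_to_select=4, absolute=False)
        params = sel.get_params()
        clone = es.ReversedCorrelationSelector().set_params(**params)
        assert clone.get_params() == params

    def test_pipeline_composition(self):
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        rng = np.random.default_rng(13)
        values = rng.standard_normal((100, 6))
        y = (values[:, 0] > 0).astype(int)
        pipe = Pipeline(
            [
                ("select", es.ReversedCorrelationSelector(n_features_to_select=3)),
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="rbf")),
            ]
        )
        pipe.fit(values, y)
        assert pipe.predict(values).shape == (100,)

    def test_fixed_set_selector(self, small_features):
        X, _ = small_features
        sel = es.FixedSetSelector(es.get_fixed_set("CHS6"),
                                  feature_names=X.feature_names)
        sel.fit(X.values)
        out = sel.transform(X.values)
        assert out.shape == (X.n_instances, 3)
        assert sel.selected_names_ == ["Cz_beta", "Fz_beta", "Pz_beta"]

    def test_fixed_set_selector_missing_feature(self):
        sel = es.FixedSetSelector(("Cz_beta",), feature_names=["Pz_beta"])
        with pytest.raises(KeyError, match="Cz_beta"):
            sel.fit(np.zeros((4, 1)))
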