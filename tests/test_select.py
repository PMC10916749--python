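import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

import oracles
from petrad.select import (
    mrmr_rank,
    pearson_prune,
    quantile_bin,
    select_features,
    select_top_fraction,
)


def make_table(rng, n=60, n_noise=8):
    labels = np.repeat([0, 1], n // 2)
    cols = {"signal": labels + rng.normal(0, 0.2, n)}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), labels


def test_mi_estimator_matches_contingency_oracle(rng):
    x = quantile_bin(rng.normal(0, 1, 80))
    y = rng.integers(0, 2, 80)
    assert mutual_info_score(y, x) == pytest.approx(
        oracles.mutual_information_nats(x, y), abs=1e-12
    )


class TestMRMR:
    def test_label_copy_ranked_first(self, rng):
        table, labels = make_table(rng)
        result = mrmr_rank(table, labels)
        assert result.ranked_features[0] == "signal"

    def test_duplicate_of_top_feature_penalized(self, rng):
        table, labels = make_table(rng)
        table["signal_copy"] = table["signal"].to_numpy()
        # a second, weaker but non-redundant informative feature
        table["signal2"] = labels + rng.normal(0, 0.6, len(labels))
        result = mrmr_rank(table, labels)
        assert result.ranked_features[0] in ("signal", "signal_copy")
        assert result.ranked_features[1] == "signal2"

    def test_full_ranking_is_permutation(self, rng):
        table, labels = make_table(rng)
        result = mrmr_rank(table, labels, k=table.shape[1])
        assert sorted(result.ranked_features) == sorted(table.columns)

    def test_deterministic(self, rng):
        table, labels = make_table(rng)
        a = mrmr_rank(table, labels).ranked_features
        b = mrmr_rank(table, labels).ranked_features
        assert a == b

    def test_constant_feature_ranked_last(self, rng):
        table, labels = make_table(rng, n_noise=3)
        table["flat"] = 1.0
        result = mrmr_rank(table, labels)
        assert result.ranked_features[-1] == "flat"
        assert result.scores["flat"] == 0.0

    def test_nan_features_dropped_and_reported(self, rng):
        table, labels = make_table(rng, n_noise=3)
        table.loc[3, "noise1"] = np.nan
        result = mrmr_rank(table, labels)
        assert result.dropped_nan_features == ["noise1"]
        assert "noise1" not in result.ranked_features

    def test_planted_features_recovered_in_top_k(self, rng):
        """All planted label-associated features land in the top k
        (Monte-Carlo over 20 replicates)."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(900 + rep)
            labels = np.repeat([0, 1], 30)
            cols = {}
            for m in range(3):
                cols[f"planted{m}"] = labels * (1 + m) + r.normal(0, 0.3, 60)
            for i in range(27):
                cols[f"noise{i}"] = r.normal(0, 1, 60)
            result = mrmr_rank(pd.DataFrame(cols), labels, k=6)
            top = set(result.ranked_features[:6])
            hits += {"planted0", "planted1", "planted2"} <= top
        assert hits == 20


class TestTopFraction:
    @pytest.mark.parametrize("n_feat,fraction,expected", [(215, 0.10, 21), (30, 0.10, 3), (10, 0.10, 1)])
    def test_floor_rule(self, rng, n_feat, fraction, expected):
        table, labels = make_table(rng, n_noise=n_feat - 1)
        result = mrmr_rank(table, labels)
        select_top_fraction(result, fraction, n_total=n_feat)
        assert result.k_selected == expected

    def test_fraction_one_keeps_all(self, rng):
        table, labels = make_table(rng)
        result = select_top_fraction(mrmr_rank(table, labels), 1.0)
        assert result.selected == result.ranked_features


class TestPearsonPrune:
    def test_identical_features_only_first_kept(self, rng):
        table, labels = make_table(rng, n_noise=2)
        table["signal_copy"] = table["signal"].to_numpy()
        result = select_top_fraction(mrmr_rank(table, labels), 1.0)
        result = pearson_prune(result, table)
        assert "signal" in result.kept_after_prune
        assert "signal_copy" not in result.kept_after_prune

    def test_planted_correlations_match_hand_enumeration(self, rng):
        """Greedy rule on a design with known pairwise correlations: a is
        kept; b (r~0.9 with a) is dropped; c (r~0.1 with a) is kept."""
        n = 2000
        a = rng.normal(0, 1, n)
        b = 0.9 * a + np.sqrt(1 - 0.9**2) * rng.normal(0, 1, n)
        c = 0.1 * a + np.sqrt(1 - 0.1**2) * rng.normal(0, 1, n)
        table = pd.DataFrame({"a": a, "b": b, "c": c})
        from petrad.select import SelectionResult

        result = SelectionResult(ranked_features=["a", "b", "c"], scores={}, k_selected=3)
        result = pearson_prune(result, table, r_threshold=0.30)
        assert result.kept_after_prune == ["a", "c"]

    def test_reference_four_feature_matrix_passes_certificate(self):
        """A 4x4 correlation structure whose largest off-diagonal |r| is
        0.2994 keeps all four features at the < 0.30 rule."""
        target = np.array(
            [
                [1.0, -0.1489, -0.2330, -0.0365],
                [-0.1489, 1.0, 0.2994, -0.2223],
                [-0.2330, 0.2994, 1.0, -0.2239],
                [-0.0365, -0.2223, -0.2239, 1.0],
            ]
        )
        # draw exact-correlation data via the Cholesky factor
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, (4, 5000))
        z = (z - z.mean(1, keepdims=True))
        cov = z @ z.T
        z = np.linalg.inv(np.linalg.cholesky(cov / z.shape[1])) @ z
        x = np.linalg.cholesky(target) @ z
        names = ["maximum", "ldlgle", "dn", "iqr"]
        table = pd.DataFrame(dict(zip(names, x)))
        assert np.allclose(table.corr().to_numpy(), target, atol=1e-10)
        from petrad.select import SelectionResult

        result = SelectionResult(ranked_features=names, scores={}, k_selected=4)
        result = pearson_prune(result, table, r_threshold=0.30)
        assert result.kept_after_prune == names
        off = result.correlation_matrix.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() == pytest.approx(0.2994, abs=1e-10)


def test_select_features_certificate_invariant(rng):
    table, labels = make_table(rng, n=80, n_noise=20)
    result = select_features(table, labels, fraction=0.5, r_threshold=0.30)
    kept = result.kept_after_prune
    corr = result.correlation_matrix.to_numpy()
    if len(kept) > 1:
        assert np.abs(corr[~np.eye(len(kept), dtype=bool)]).max() < 0.30
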