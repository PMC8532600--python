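"""Correlation pruning, split/normalization and the four classifier backends."""

import itertools

import numpy as np
import pandas as pd
import pytest

from flanksense import modeling
from flanksense.modeling import ModelSpec, SplitSpec


def _table(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestPruneCorrelated:
    def test_duplicate_column_removed(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        t = _table({"f1": a, "f2": a.copy(), "f3": b})
        res = modeling.prune_correlated(t, cutoff=0.8, feature_cols=["f1", "f2", "f3"])
        assert sorted(res.removed + res.retained) == ["f1", "f2", "f3"]
        assert len(res.removed) == 1 and res.removed[0] in ("f1", "f2")
        assert "f3" in res.retained

    def test_cutoff_one_removes_nothing(self, rng):
        t = _table({f"f{i}": rng.normal(size=100) for i in range(5)})
        res = modeling.prune_correlated(t, cutoff=1.0, feature_cols=list(t.columns))
        assert res.removed == []

    def test_constant_column_dropped_first(self, rng):
        t = _table({"f1": rng.normal(size=50), "f2": np.ones(50), "f3": rng.normal(size=50)})
        res = modeling.prune_correlated(t, feature_cols=list(t.columns))
        assert "f2" in res.removed

    def test_matches_minimal_removal_oracle(self, rng):
        """On small tables the greedy result coincides with the exhaustive
        minimal removal set that clears every >= cutoff pair."""
        n = 400
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        t = _table(
            {
                "a": z1,
                "b": z1 + 0.1 * rng.normal(size=n),   # |r(a,b)| ~ 0.995
                "c": z1 + 0.45 * rng.normal(size=n),  # correlated with a, b
                "d": z2,                              # independent
            }
        )
        cols = list(t.columns)
        cutoff = 0.8
        corr = t[cols].corr().abs().to_numpy()

        def clears(removal):
            keep = [i for i, c in enumerate(cols) if c not in removal]
            return all(corr[i, j] < cutoff for i, j in itertools.combinations(keep, 2))

        minimal = min(
            (
                set(sub)
                for k in range(len(cols) + 1)
                for sub in itertools.combinations(cols, k)
                if clears(set(sub))
            ),
            key=len,
        )
        res = modeling.prune_correlated(t, cutoff=cutoff, feature_cols=cols)
        assert len(res.removed) == len(minimal)
        assert clears(set(res.removed))

    def test_post_state_invariant(self, rng):
        base = rng.normal(size=(300, 4))
        mix = rng.normal(size=(4, 12))
        t = pd.DataFrame(base @ mix + 0.3 * rng.normal(size=(300, 12)), columns=[f"f{i}" for i in range(12)])
        res = modeling.prune_correlated(t, cutoff=0.8, feature_cols=list(t.columns))
        resid = t[res.retained].corr().abs().to_numpy()
        np.fill_diagonal(resid, 0)
        assert resid.max() < 0.8

    def test_too_few_features(self, rng):
        with pytest.raises(ValueError):
            modeling.prune_correlated(_table({"f1": rng.normal(size=10)}), feature_cols=["f1"])


class TestSplitAndNormalize:
    def _toy(self, rng, n=100):
        t = _table({"f1": rng.normal(2, 3, n), "f2": rng.normal(-1, 0.5, n)})
        t["posture"] = rng.choice(["S", "RSR"], n)
        return t

    def test_partition_sizes(self, rng):
        t = self._toy(rng)
        tr, te, _ = modeling.split_and_normalize(t, SplitSpec(0.75, seed=1), ["f1", "f2"])
        assert len(tr) == 75 and len(te) == 25

    def test_training_statistics_define_the_scale(self, rng):
        t = self._toy(rng)
        tr, te, norm = modeling.split_and_normalize(t, SplitSpec(0.75, seed=1), ["f1", "f2"])
        assert tr["f1"].mean() == pytest.approx(0.0, abs=1e-10)
        assert tr["f2"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        # a hypothetical row equal to the training mean maps to the origin
        mean_row = pd.DataFrame([norm.mean])
        np.testing.assert_allclose(norm.transform(mean_row).to_numpy(float), 0.0, atol=1e-12)

    def test_split_is_a_seeded_partition(self, rng):
        t = self._toy(rng)
        t["row_id"] = np.arange(len(t))
        a_tr, a_te, _ = modeling.split_and_normalize(t, SplitSpec(seed=9), ["f1", "f2"])
        b_tr, b_te, _ = modeling.split_and_normalize(t, SplitSpec(seed=9), ["f1", "f2"])
        assert set(a_tr["row_id"]) | set(a_te["row_id"]) == set(range(len(t)))
        assert not (set(a_tr["row_id"]) & set(a_te["row_id"]))
        assert list(a_tr["row_id"]) == list(b_tr["row_id"])

    def test_constant_training_feature_is_named(self, rng):
        t = self._toy(rng)
        t["dead"] = 1.0
        with pytest.raises(ValueError, match="dead"):
            modeling.split_and_normalize(t, SplitSpec(seed=0), ["f1", "dead"])

    def test_empty_table(self):
        with pytest.raises(ValueError):
            modeling.split_and_normalize(pd.DataFrame(), SplitSpec(seed=0), [])


def _blobs(rng, n=200, separation=20.0):
    half = n // 2
    x = np.vstack([rng.normal(0, 1, (half, 2)), rng.normal(separation, 1, (half, 2))])
    y = np.array(["a"] * half + ["b"] * half)
    order = rng.permutation(n)
    df = pd.DataFrame(x[order], columns=["f1", "f2"])
    df["label"] = y[order]
    return df


class TestFitPredict:
    @pytest.mark.parametrize("algorithm", modeling.ALGORITHMS)
    def test_separable_blobs_are_perfectly_classified(self, algorithm, rng):
        """Two >= 10-sigma-separated Gaussian blobs: every backend is exact."""
        df = _blobs(rng)
        tr, te, _ = modeling.split_and_normalize(df, SplitSpec(seed=3), ["f1", "f2"])
        yhat = modeling.fit_predict(ModelSpec(algorithm, seed=5), tr, te, ["f1", "f2"], "label")
        assert (yhat == te["label"].to_numpy()).all()

    def test_one_nearest_neighbor_memorizes(self, rng):
        df = _blobs(rng, separation=0.5)  # heavily overlapping
        spec = ModelSpec("KNN", hyperparameters={"n_neighbors": 1})
        yhat = modeling.fit_predict(spec, df, df, ["f1", "f2"], "label")
        assert (yhat == df["label"].to_numpy()).all()

    @pytest.mark.parametrize("algorithm", ["RF", "XGB"])
    def test_seeded_backends_reproduce(self, algorithm, rng):
        df = _blobs(rng, separation=1.0)
        tr, te, _ = modeling.split_and_normalize(df, SplitSpec(seed=3), ["f1", "f2"])
        a = modeling.fit_predict(ModelSpec(algorithm, seed=7), tr, te, ["f1", "f2"], "label")
        b = modeling.fit_predict(ModelSpec(algorithm, seed=7), tr, te, ["f1", "f2"], "label")
        np.testing.assert_array_equal(a, b)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            ModelSpec("MLP")
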