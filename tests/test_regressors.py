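import numpy as np
import pytest

from potencybench import regressors as R
from potencybench.metrics import mae
from potencybench.records import CompoundRecord
from potencybench.synthetic_data import SyntheticSARConfig, generate_activity_class


def comp(cid, pic50, bits, n_bits=16):
    fp = np.zeros(n_bits, dtype=np.uint8)
    fp[list(bits)] = 1
    sub = "LOW" if pic50 < 7 else ("MID" if pic50 < 9 else "HIGH")
    return CompoundRecord(compound_id=cid, pic50=pic50, fingerprint=fp, subrange=sub)


@pytest.fixture(scope="module")
def sar_class():
    cfg = SyntheticSARConfig(
        n_series=20, compounds_per_series=10, min_per_subrange=0, seed=5
    )
    return generate_activity_class(cfg, "SAR")


class TestMedianRegression:
    @pytest.mark.parametrize(
        "potencies,median",
        [([5.0, 7.0, 9.0], 7.0), ([6.0, 8.0], 7.0), ([7.4], 7.4)],
    )
    def test_stored_median(self, potencies, median):
        train = [comp(f"t{i}", p, [i]) for i, p in enumerate(potencies)]
        model = R.fit(R.MR, train)
        assert model.median_ == median

    def test_constant_predictions(self):
        train = [comp(f"t{i}", p, [i]) for i, p in enumerate([5, 7.4, 7.4, 9, 10])]
        test = [comp(f"x{i}", 6.0, [i]) for i in range(5)]
        res = R.predict(R.fit(R.MR, train), test)
        assert (res.rows["y_pred"] == 7.4).all()

    def test_train_mae_is_mean_abs_deviation_from_median(self, rng):
        y = rng.uniform(5, 11, 31)
        train = [comp(f"t{i}", v, [i % 16]) for i, v in enumerate(y)]
        model = R.fit(R.MR, train)
        res = R.predict(model, train)
        expected = np.mean(np.abs(y - np.median(y)))
        assert mae(res.rows["y_true"], res.rows["y_pred"]) == pytest.approx(expected)


class TestNearestNeighbors:
    def test_exact_match_dominates(self):
        train = [comp("a", 6.0, [0, 1]), comp("b", 9.0, [4, 5])]
        test = [comp("x", 7.0, [4, 5])]
        res = R.predict(R.fit(R.NN1, train), test)
        assert res.rows["y_pred"].iloc[0] == 9.0

    def test_3nn_unweighted_mean_at_equal_similarity(self):
        train = [comp(c, p, [0, 1]) for c, p in zip("abc", [6.0, 7.0, 8.0])]
        test = [comp("x", 7.0, [0, 1])]
        res = R.predict(R.fit(R.NN3, train), test)
        assert res.rows["y_pred"].iloc[0] == pytest.approx(7.0)

    def test_k_exceeds_training_size(self):
        train = [comp("a", 6.0, [0])]
        with pytest.raises(ValueError):
            R.fit(R.NN3, train)

    def test_nesting_with_replicated_neighbor(self):
        """1-NN and 3-NN agree when the nearest neighbor appears 3x."""
        train = [comp(c, 8.5, [2, 3]) for c in "abc"] + [comp("d", 5.5, [9])]
        test = [comp("x", 8.0, [2, 3])]
        p1 = R.predict(R.fit(R.NN1, train), test).rows["y_pred"].iloc[0]
        p3 = R.predict(R.fit(R.NN3, train), test).rows["y_pred"].iloc[0]
        assert p1 == p3 == 8.5

    def test_tie_break_deterministic(self):
        train = [comp(c, p, [0, 1]) for c, p in zip("abcd", [5.0, 6.0, 8.0, 10.0])]
        test = [comp("x", 7.0, [0, 1])]
        preds = {
            R.predict(R.fit(R.NN1, train, seed=3), test).rows["y_pred"].iloc[0]
            for _ in range(3)
        }
        assert len(preds) == 1


class TestSVR:
    def test_selected_C_in_grid(self, sar_class):
        train = sar_class.compounds[:200]
        model = R.fit(R.SVR, train, seed=0)
        assert model.params["C"] in R.DEFAULT_GRID.svr_C

    def test_training_error_shrinks_with_C(self):
        cfg = SyntheticSARConfig(
            n_series=10, compounds_per_series=10, noise_sd=0.0,
            min_per_subrange=0, seed=2,
        )
        cls = generate_activity_class(cfg)
        train = cls.compounds

        def train_mae(C):
            grid = R.HyperparamGrid(svr_C=(C,))
            model = R.fit(R.SVR, train, grid=grid)
            res = R.predict(model, train)
            return mae(res.rows["y_true"], res.rows["y_pred"])

        assert train_mae(1000.0) < train_mae(1.0)
        assert train_mae(1000.0) < 0.2

    def test_holdout_fallback_for_tiny_training_set(self):
        train = [comp(f"t{i}", 5.5 + i, [i]) for i in range(4)]
        model = R.fit(R.SVR, train, seed=0)
        assert model.params["C"] in R.DEFAULT_GRID.svr_C

    def test_r2_selection_cost(self, sar_class):
        train = sar_class.compounds[:60]
        model = R.fit(R.SVR, train, cost="R2", seed=0)
        assert model.cost == "R2"
        assert model.params["C"] in R.DEFAULT_GRID.svr_C


class TestRFR:
    def test_grid_selection_and_reproducibility(self, sar_class):
        train = sar_class.compounds[:60]
        test = sar_class.compounds[60:90]
        grid = R.HyperparamGrid(
            rfr_n_trees=(10, 20),
            rfr_min_samples_split=(2,),
            rfr_min_samples_leaf=(1,),
            rfr_max_features=("sqrt",),
        )
        m1 = R.fit(R.RFR, train, grid=grid, seed=7)
        m2 = R.fit(R.RFR, train, grid=grid, seed=7)
        assert m1.params == m2.params
        assert m1.params["n_trees"] in (10, 20)
        p1 = R.predict(m1, test).rows["y_pred"]
        p2 = R.predict(m2, test).rows["y_pred"]
        assert np.array_equal(p1, p2)


class TestReproducibilityAndErrors:
    def test_svr_seeded_reproducibility(self, sar_class):
        train = sar_class.compounds[:80]
        test = sar_class.compounds[80:120]
        r1 = R.predict(R.fit(R.SVR, train, seed=11), test).rows
        r2 = R.predict(R.fit(R.SVR, train, seed=11), test).rows
        assert r1.equals(r2)

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            R.fit(R.MR, [])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            R.fit("DNN", [comp("a", 6.0, [0])])

    def test_empty_test_set(self):
        train = [comp("a", 6.0, [0]), comp("b", 8.0, [1])]
        res = R.predict(R.fit(R.MR, train), [])
        assert len(res) == 0

    def test_fingerprint_length_mismatch(self):
        train = [comp("a", 6.0, [0]), comp("b", 8.0, [1])]
        test = [comp("x", 7.0, [0], n_bits=32)]
        with pytest.raises(ValueError):
            R.predict(R.fit(R.NN1, train), test)
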