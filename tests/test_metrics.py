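import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from potencybench.metrics import (
    PredictionResult,
    decompose_by_subrange,
    mae,
    metrics_to_frame,
    r2_determination,
    r2_pearson,
    rmse,
    signed_rank_p,
    wilcoxon_pairwise,
)

vectors = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=1,
    max_size=30,
)


def exact_signed_rank_p(x, y):
    """Independent oracle: full 2^n enumeration of the signed-rank null."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    w_all = signs @ ranks
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    p = ((w_all <= lo).sum() + (w_all >= hi).sum()) / len(w_all)
    return min(1.0, p)


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "func,y,yhat,expected",
        [
            (mae, [5, 7, 9], [5, 7, 9], 0.0),
            (mae, [5, 7, 9], [6, 7, 8], 2.0 / 3.0),
            (mae, [5, 9], [7, 7], 2.0),
            (rmse, [5, 7, 9], [5, 7, 9], 0.0),
            (rmse, [5, 9], [7, 7], 2.0),  # equal residuals: RMSE == MAE
            (rmse, [5, 7, 9], [6, 7, 8], np.sqrt(2.0 / 3.0)),
        ],
    )
    def test_hand_examples(self, func, y, yhat, expected):
        assert func(y, yhat) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("func", [mae, rmse])
    def test_errors(self, func):
        with pytest.raises(ValueError):
            func([1, 2], [1])
        with pytest.raises(ValueError):
            func([], [])

    @given(vectors, vectors)
    def test_mae_le_rmse(self, y, yhat):
        n = min(len(y), len(yhat))
        y, yhat = y[:n], yhat[:n]
        assert mae(y, yhat) <= rmse(y, yhat) + 1e-12

    def test_brute_force_agreement(self, rng):
        """All metrics agree with direct loops over residuals to 1e-12."""
        for _ in range(100):
            n = int(rng.integers(2, 40))
            y = rng.normal(7, 1.5, n)
            yhat = y + rng.normal(0, 0.7, n)
            m = sum(abs(a - b) for a, b in zip(y, yhat)) / n
            r = (sum((a - b) ** 2 for a, b in zip(y, yhat)) / n) ** 0.5
            assert mae(y, yhat) == pytest.approx(m, abs=1e-12)
            assert rmse(y, yhat) == pytest.approx(r, abs=1e-12)


class TestCorrelation:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0]
        assert r2_pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert r2_pearson([1, 2, 3], [4, 4, 4]) is None
        assert r2_pearson([4, 4, 4], [1, 2, 3]) is None

    def test_hand_example(self):
        assert r2_pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25)

    def test_determination(self):
        y = [5.0, 7.0, 9.0]
        assert r2_determination(y, y) == pytest.approx(1.0)
        assert r2_determination(y, [7.0, 7.0, 7.0]) == pytest.approx(0.0)
        assert r2_determination(y, [6.0, 7.0, 8.0]) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            r2_determination([4.0, 4.0], [1.0, 2.0])

    def test_determination_can_be_negative(self):
        assert r2_determination([5.0, 9.0], [9.0, 5.0]) < 0


def _result(y_true, y_pred, subranges):
    return PredictionResult(
        method="X",
        class_id="C",
        trial_index=0,
        rows=pd.DataFrame(
            dict(
                compound_id=[f"c{i}" for i in range(len(y_true))],
                y_true=y_true,
                y_pred=y_pred,
                subrange=subranges,
            )
        ),
    )


class TestDecomposition:
    def test_all_mid(self):
        res = _result([7.5, 8.0], [7.0, 8.5], ["MID", "MID"])
        recs = {r.scope: r for r in decompose_by_subrange(res)}
        assert recs["LOW"].n == 0 and recs["LOW"].mae is None
        assert recs["HIGH"].n == 0
        assert recs["GLOBAL"].mae == recs["MID"].mae

    def test_count_conservation_and_weighted_mean(self, rng):
        n = 60
        y = rng.uniform(5, 11, n)
        yhat = y + rng.normal(0, 1, n)
        subs = [
            "LOW" if v < 7 else ("MID" if v < 9 else "HIGH") for v in y
        ]
        recs = {r.scope: r for r in decompose_by_subrange(_result(y, yhat, subs))}
        assert sum(recs[s].n for s in ("LOW", "MID", "HIGH")) == recs["GLOBAL"].n
        weighted = (
            sum(recs[s].n * recs[s].mae for s in ("LOW", "MID", "HIGH") if recs[s].n)
            / recs["GLOBAL"].n
        )
        assert recs["GLOBAL"].mae == pytest.approx(weighted, abs=1e-12)

    def test_metrics_frame_shape(self, rng):
        y = rng.uniform(5, 11, 10)
        subs = ["MID"] * 10
        recs = decompose_by_subrange(_result(y, y, subs))
        df = metrics_to_frame(recs)
        assert list(df["scope"]) == ["GLOBAL", "LOW", "MID", "HIGH"]


class TestWilcoxon:
    def test_identical_lists_not_significant(self):
        a = list(np.linspace(0.4, 0.8, 10))
        res = wilcoxon_pairwise({"A": a, "B": list(a)})
        assert res[0].p_value == 1.0
        assert not res[0].significant

    def test_pair_count_five_methods(self, rng):
        scores = {m: rng.normal(0.6, 0.05, 10) for m in "ABCDE"}
        res = wilcoxon_pairwise(scores)
        assert len(res) == 10  # C(5, 2)

    def test_constant_shift_significant(self):
        x = list(range(1, 11))
        y = [v + 1 for v in x]
        p = signed_rank_p(x, y)
        assert p == pytest.approx(2 / 1024)
        assert p < 0.005

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_pairwise({"A": [1, 2, 3], "B": [1, 2]})

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0.6, 0.1, 10)
            y = x + rng.normal(0.0, 0.08, 10)
            assert signed_rank_p(x, y) == pytest.approx(
                exact_signed_rank_p(x, y), abs=1e-12
            )
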