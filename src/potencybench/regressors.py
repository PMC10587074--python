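"""Potency regression models and no-learning controls.

Two machine-learning models and three controls:

* **SVR** — epsilon-insensitive support vector regression with a
  precomputed Tanimoto kernel on the training fingerprints; the cost
  parameter C is optimized over {1, 10, 100, 1000} by grid search with
  3-fold cross-validation (stratified by potency sub-range for balanced
  training sets).
* **RFR** — random forest regression on the raw 2048-bit fingerprints,
  grid over number of trees (50, 100, 200), min samples per split
  (2, 3, 5, 10), min samples per leaf (1, 2, 5, 10) and max features
  (sqrt, log2), searched the same way.
* **1-NN / 3-NN** — assign the potency of the most Tanimoto-similar
  training compound, or the unweighted mean over the three most similar.
* **MR** — median regression, the simplest null control: every test
  compound receives the training-set median potency.

Model selection is guided by MAE or, as a control, by R^2 (coefficient of
determination).  Ties in CV cost are broken toward the smaller C / the
earlier (simpler) tree setting; k-NN similarity ties toward the lowest
training index after a seeded shuffle.  Everything is reproducible from
(data, grid, seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVR as _SkSVR

from . import metrics as _metrics
from .fingerprints import tanimoto_matrix
from .metrics import PredictionResult
from .records import SUBRANGES, CompoundRecord

logger = logging.getLogger(__name__)

SVR = "SVR"
RFR = "RFR"
NN1 = "1-NN"
NN3 = "3-NN"
MR = "MR"
METHODS: tuple[str, ...] = (SVR, RFR, NN1, NN3, MR)

SVR_EPSILON = 0.1  # common default; only C is grid-searched


@dataclass(frozen=True)
class HyperparamGrid:
    """Hyperparameter search space for SVR and RFR."""

    svr_C: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    rfr_n_trees: tuple[int, ...] = (50, 100, 200)
    rfr_min_samples_split: tuple[int, ...] = (2, 3, 5, 10)
    rfr_min_samples_leaf: tuple[int, ...] = (1, 2, 5, 10)
    rfr_max_features: tuple[str, ...] = ("sqrt", "log2")

    def __post_init__(self) -> None:
        for name in (
            "svr_C", "rfr_n_trees", "rfr_min_samples_split",
            "rfr_min_samples_leaf", "rfr_max_features",
        ):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty grid: {name}")


DEFAULT_GRID = HyperparamGrid()

#: Single-point RFR grid for scaled-down studies (SVR keeps its full grid).
FAST_RFR_GRID = HyperparamGrid(
    rfr_n_trees=(100,),
    rfr_min_samples_split=(2,),
    rfr_min_samples_leaf=(1,),
    rfr_max_features=("sqrt",),
)


@dataclass
class FittedModel:
    """A fitted regressor plus everything needed to predict and replay."""

    method: str
    params: dict
    cost: str
    seed: int
    train_fps: Optional[np.ndarray] = None
    train_y: Optional[np.ndarray] = None
    estimator: object = None
    median_: Optional[float] = None
    k: Optional[int] = None
    tiebreak_order: Optional[np.ndarray] = field(default=None, repr=False)

    def provenance(self) -> dict:
        """JSON-serializable sidecar describing the fit."""
        return dict(
            method=self.method,
            params={k: v for k, v in self.params.items()},
            cost=self.cost,
            seed=int(self.seed),
            n_train=0 if self.train_y is None else int(len(self.train_y)),
            median=self.median_,
        )


def _cost_value(y_true, y_pred, cost: str) -> float:
    """Value to *minimize* during model selection."""
    if cost == "MAE":
        return _metrics.mae(y_true, y_pred)
    if cost == "R2":
        return -_metrics.r2_determination(y_true, y_pred)
    raise ValueError(f"unknown selection cost {cost!r} (use 'MAE' or 'R2')")


def _is_balanced(train: Sequence[CompoundRecord]) -> bool:
    counts = {s: 0 for s in SUBRANGES}
    for c in train:
        if c.subrange not in counts:
            return False
        counts[c.subrange] += 1
    vals = list(counts.values())
    return vals[0] == vals[1] == vals[2] and vals[0] > 0


def _cv_folds(
    n: int, labels: Optional[np.ndarray], seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """3-fold CV indices; 50/50 holdout fallback for degenerate sets.

    Stratification by sub-range applies only when every sub-range has at
    least 3 members (3-fold stratification is undefined below that).
    """
    if n < 6:
        # fewer than 2 compounds per fold: single 50/50 train/validation split
        logger.info("grid search: n=%d too small for 3-fold CV, 50/50 holdout", n)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        half = n // 2
        return [(perm[half:], perm[:half])]
    if labels is not None:
        _, cnt = np.unique(labels, return_counts=True)
        if cnt.min() >= 3:
            skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            return list(skf.split(np.zeros(n), labels))
    kf = KFold(n_splits=3, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def _grid_search(candidates, evaluate) -> tuple[int, float]:
    """Index of the best candidate; ties keep the earlier (simpler) one."""
    best_i, best_cost = 0, np.inf
    for i, cand in enumerate(candidates):
        c = evaluate(cand)
        if c < best_cost:
            best_i, best_cost = i, c
    return best_i, best_cost


def fit(
    method: str,
    train: Sequence[CompoundRecord],
    grid: HyperparamGrid = DEFAULT_GRID,
    cost: str = "MAE",
    seed: int = 0,
) -> FittedModel:
    """Fit one method on a training set of curated compounds."""
    if len(train) == 0:
        raise ValueError("empty training set")
    y = np.array([c.pic50 for c in train], dtype=float)

    if method == MR:
        return FittedModel(
            method=MR, params={}, cost=cost, seed=seed,
            train_y=y, median_=float(np.median(y)),
        )

    X = np.vstack([c.fingerprint for c in train]).astype(np.uint8)

    if method in (NN1, NN3):
        k = 1 if method == NN1 else 3
        if k > len(train):
            raise ValueError(f"{method}: k={k} exceeds training size {len(train)}")
        order = np.random.default_rng(seed).permutation(len(train))
        return FittedModel(
            method=method, params={"k": k}, cost=cost, seed=seed,
            train_fps=X, train_y=y, k=k, tiebreak_order=order,
        )

    labels = (
        np.array([c.subrange for c in train]) if _is_balanced(train) else None
    )
    folds = _cv_folds(len(train), labels, seed)

    if method == SVR:
        K = tanimoto_matrix(X)

        def eval_C(C: float) -> float:
            costs = []
            for tr, val in folds:
                est = _SkSVR(kernel="precomputed", C=C, epsilon=SVR_EPSILON)
                est.fit(K[np.ix_(tr, tr)], y[tr])
                pred = est.predict(K[np.ix_(val, tr)])
                costs.append(_cost_value(y[val], pred, cost))
            return float(np.mean(costs))

        i, cv_cost = _grid_search(grid.svr_C, eval_C)
        C = grid.svr_C[i]
        est = _SkSVR(kernel="precomputed", C=C, epsilon=SVR_EPSILON)
        est.fit(K, y)
        return FittedModel(
            method=SVR, params={"C": C, "epsilon": SVR_EPSILON, "cv_cost": cv_cost},
            cost=cost, seed=seed, train_fps=X, train_y=y, estimator=est,
        )

    if method == RFR:
        combos = list(
            itertools.product(
                grid.rfr_n_trees,
                grid.rfr_min_samples_split,
                grid.rfr_min_samples_leaf,
                grid.rfr_max_features,
            )
        )

        def make(combo) -> RandomForestRegressor:
            n_trees, mss, msl, mf = combo
            return RandomForestRegressor(
                n_estimators=n_trees,
                min_samples_split=mss,
                min_samples_leaf=msl,
                max_features=mf,
                random_state=seed,
                n_jobs=1,
            )

        def eval_combo(combo) -> float:
            costs = []
            for tr, val in folds:
                est = make(combo)
                est.fit(X[tr], y[tr])
                costs.append(_cost_value(y[val], est.predict(X[val]), cost))
            return float(np.mean(costs))

        if len(combos) == 1:
            i, cv_cost = 0, float("nan")
        else:
            i, cv_cost = _grid_search(combos, eval_combo)
        n_trees, mss, msl, mf = combos[i]
        est = make(combos[i])
        est.fit(X, y)
        return FittedModel(
            method=RFR,
            params={
                "n_trees": n_trees, "min_samples_split": mss,
                "min_samples_leaf": msl, "max_features": mf,
                "cv_cost": cv_cost,
            },
            cost=cost, seed=seed, train_fps=X, train_y=y, estimator=est,
        )

    raise ValueError(f"unknown method {method!r}")


def predict(
    model: FittedModel,
    test: Sequence[CompoundRecord],
    class_id: str = "",
    trial_index: int = 0,
    ladder_size: Optional[int] = None,
) -> PredictionResult:
    """Predict pIC50 for a list of test compounds."""
    ids = [c.compound_id for c in test]
    y_true = np.array([c.pic50 for c in test], dtype=float)
    subs = [c.subrange for c in test]

    if len(test) == 0:
        y_pred = np.array([])
    elif model.method == MR:
        y_pred = np.full(len(test), model.median_)
    else:
        Xt = np.vstack([c.fingerprint for c in test]).astype(np.uint8)
        if Xt.shape[1] != model.train_fps.shape[1]:
            raise ValueError("test fingerprint length differs from training")
        if model.method in (NN1, NN3):
            order = model.tiebreak_order
            S = tanimoto_matrix(Xt, model.train_fps[order])
            # stable argsort => ties resolved by lowest post-shuffle index
            top = np.argsort(-S, axis=1, kind="stable")[:, : model.k]
            y_pred = model.train_y[order][top].mean(axis=1)
        else:  # SVR / RFR
            if model.method == SVR:
                Kt = tanimoto_matrix(Xt, model.train_fps)
                y_pred = model.estimator.predict(Kt)
            else:
                y_pred = model.estimator.predict(Xt)

    rows = pd.DataFrame(
        dict(compound_id=ids, y_true=y_true, y_pred=y_pred, subrange=subs)
    )
    return PredictionResult(
        method=model.method,
        class_id=class_id,
        trial_index=trial_index,
        rows=rows,
        ladder_size=ladder_size,
    )
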