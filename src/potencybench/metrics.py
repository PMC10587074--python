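"""Error metrics, sub-range decomposition and significance testing.

Prediction accuracy is evaluated with the mean absolute error

    MAE(y, yhat) = (1/n) * sum_i |y_i - yhat_i|,

the root mean squared error

    RMSE(y, yhat) = sqrt( sum_i (y_i - yhat_i)^2 / n ),

and the squared Pearson correlation coefficient r^2 between observed and
predicted potencies.  The coefficient of determination R^2 = 1 - SSres/SStot
serves only as an alternative model-selection cost.  Method comparisons use
the two-sided Wilcoxon signed-rank test over per-trial metric values at the
Bonferroni-corrected threshold alpha = 0.005 (n = 10 method pairs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import SUBRANGES

logger = logging.getLogger(__name__)

ALPHA = 0.005
N_CORRECTION = 10


@dataclass
class PredictionResult:
    """Observed/predicted potency pairs for one (method, class, trial).

    ``rows`` is a DataFrame with columns ``compound_id``, ``y_true``,
    ``y_pred`` and ``subrange`` (the sub-range of the *experimental*
    potency, which defines sub-range membership in the decomposition).
    """

    method: str
    class_id: str
    trial_index: int
    rows: pd.DataFrame
    ladder_size: Optional[int] = None

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class MetricRecord:
    method: str
    class_id: str
    trial_index: int
    scope: str  # GLOBAL | LOW | MID | HIGH
    n: int
    mae: Optional[float]
    rmse: Optional[float]
    r2: Optional[float]  # None when undefined (constant predictions)
    ladder_size: Optional[int] = None


@dataclass
class SignificanceResult:
    metric: str
    method_a: str
    method_b: str
    p_value: float
    alpha: float = ALPHA
    n_correction: int = N_CORRECTION
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value < self.alpha


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def mae(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean absolute error; >= 0, zero iff the vectors coincide."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean squared error; always >= MAE (power-mean inequality)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2_pearson(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Squared Pearson correlation in [0, 1], or None when undefined.

    Undefined when either vector is constant (zero variance) — notably for
    median regression, whose predictions are a single value.  Reported as
    missing, never coerced to 0.
    """
    x, y = _check_pair(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("r2_pearson undefined: constant input vector")
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_determination(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot (may be negative)."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: constant observed values")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _record(
    result: PredictionResult, scope: str, rows: pd.DataFrame
) -> MetricRecord:
    if len(rows) == 0:
        return MetricRecord(
            method=result.method,
            class_id=result.class_id,
            trial_index=result.trial_index,
            scope=scope,
            n=0,
            mae=None,
            rmse=None,
            r2=None,
            ladder_size=result.ladder_size,
        )
    y = rows["y_true"].to_numpy()
    yhat = rows["y_pred"].to_numpy()
    return MetricRecord(
        method=result.method,
        class_id=result.class_id,
        trial_index=result.trial_index,
        scope=scope,
        n=len(rows),
        mae=mae(y, yhat),
        rmse=rmse(y, yhat),
        r2=r2_pearson(y, yhat) if len(rows) >= 2 else None,
        ladder_size=result.ladder_size,
    )


def decompose_by_subrange(result: PredictionResult) -> list[MetricRecord]:
    """GLOBAL plus per-sub-range metric records for one prediction result.

    Sub-range membership follows the experimental potency: a record of
    scope LOW is computed only over test compounds whose observed pIC50
    falls in [5, 7), and so on.  Empty sub-ranges yield records with n=0
    and missing metrics rather than being dropped, so bookkeeping stays
    exact (sub-range counts always sum to the GLOBAL count).
    """
    records = [_record(result, "GLOBAL", result.rows)]
    for sub in SUBRANGES:
        records.append(
            _record(result, sub, result.rows[result.rows["subrange"] == sub])
        )
    return records


def signed_rank_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (the standard zero-discard convention);
    if every difference is zero the samples are indistinguishable and the
    p-value is 1.  The exact null distribution is used for n <= 25 paired
    differences (the normal approximation is poor at the n = 10 trials used
    here), the corrected normal approximation beyond.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.shape != np.asarray(x).shape:
        raise ValueError("paired samples must have equal length")
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    return float(res.pvalue)


def wilcoxon_pairwise(
    scores_by_method: Mapping[str, Sequence[float]],
    metric: str = "MAE",
    alpha: float = ALPHA,
    n_correction: int = N_CORRECTION,
) -> list[SignificanceResult]:
    """All pairwise signed-rank comparisons between methods.

    ``scores_by_method`` maps each method to its per-trial metric values
    (same trials, hence paired).  Five methods give C(5,2) = 10 unordered
    pairs, matching the Bonferroni correction factor n = 10.
    """
    lengths = {len(v) for v in scores_by_method.values()}
    if len(lengths) > 1:
        raise ValueError("per-method score lists must have equal length")
    out = []
    for a, b in itertools.combinations(scores_by_method, 2):
        p = signed_rank_p(scores_by_method[a], scores_by_method[b])
        out.append(
            SignificanceResult(
                metric=metric,
                method_a=a,
                method_b=b,
                p_value=p,
                alpha=alpha,
                n_correction=n_correction,
            )
        )
    return out


def metrics_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    """Tidy table of metric records (one row per record)."""
    return pd.DataFrame(
        dict(
            method=r.method,
            class_id=r.class_id,
            trial_index=r.trial_index,
            scope=r.scope,
            ladder_size=r.ladder_size,
            n=r.n,
            mae=r.mae,
            rmse=r.rmse,
            r2=r.r2,
        )
        for r in records
    )


def significance_to_frame(
    results: Sequence[SignificanceResult], **extra
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(
            metric=r.metric,
            method_a=r.method_a,
            method_b=r.method_b,
            p_value=r.p_value,
            alpha=r.alpha,
            n_correction=r.n_correction,
            significant=r.significant,
        )
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
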