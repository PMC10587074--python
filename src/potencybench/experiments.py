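"""End-to-end experiment families.

Three studies, mirroring the benchmark-diagnosis design:

1. **Distribution diagnostics** — per-class potency summaries (median,
   quartiles, sub-range populations) and within-sub-range pairwise
   Tanimoto similarity distributions.
2. **Global + sub-range benchmark** — 10-trial random 50/50 splits, all
   five methods, metrics decomposed by potency sub-range, pairwise
   Wilcoxon significance on per-trial MAE/RMSE/r^2.
3. **Ladder learning curves** — balanced (or imbalanced control) training
   sets of increasing size 6..330 against a fixed test set, per-sub-range
   error curves.

Outputs are tidy DataFrames (written as TSV when an output directory is
given); every result is replayable from (config, master seed).
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as M
from . import regressors as R
from . import splits as S
from .fingerprints import tanimoto_matrix
from .records import SUBRANGES, ActivityClass

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one benchmark or ladder run."""

    methods: tuple[str, ...] = R.METHODS
    n_trials: int = 10
    seed: int = 0
    cost: str = "MAE"
    grid: R.HyperparamGrid = field(default_factory=lambda: R.DEFAULT_GRID)
    protocol: str = S.RANDOM_5050
    nested_ladder: bool = True
    out_dir: Optional[str] = None


def _derived_seed(master: int, *parts) -> int:
    """Stable per-(class, trial, ...) seed below 2**31."""
    tag = zlib.crc32("|".join(str(p) for p in parts).encode("utf-8"))
    ss = np.random.SeedSequence([int(master), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def pairwise_similarities(cls: ActivityClass) -> dict[str, np.ndarray]:
    """Within-sub-range pairwise Tanimoto similarities.

    For each sub-range with k compounds, returns the k*(k-1)/2 upper-triangle
    similarity values; a sub-range with fewer than 2 compounds yields an
    empty array (flagged by the caller's summary).
    """
    out: dict[str, np.ndarray] = {}
    index = cls.by_id()
    for sub, ids in cls.subrange_ids().items():
        if len(ids) < 2:
            out[sub] = np.array([])
            continue
        fps = np.vstack([index[i].fingerprint for i in ids])
        T = tanimoto_matrix(fps)
        iu = np.triu_indices(len(ids), k=1)
        out[sub] = T[iu]
    return out


def distribution_report(
    classes: Sequence[ActivityClass], out_dir: Optional[str] = None
) -> pd.DataFrame:
    """Per-class potency and similarity diagnostics as a tidy table."""
    rows = []
    for cls in classes:
        pot = cls.potencies()
        counts = cls.subrange_counts()
        sims = pairwise_similarities(cls)
        row = dict(
            class_id=cls.class_id,
            n=len(cls),
            median_pic50=float(np.median(pot)),
            q1_pic50=float(np.percentile(pot, 25)),
            q3_pic50=float(np.percentile(pot, 75)),
            qualified=cls.qualified,
        )
        for sub in SUBRANGES:
            row[f"n_{sub.lower()}"] = counts[sub]
            s = sims[sub]
            row[f"sim_pairs_{sub.lower()}"] = int(s.size)
            row[f"sim_median_{sub.lower()}"] = (
                float(np.median(s)) if s.size else None
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        _write_tsv(df, Path(out_dir) / "distribution_report.tsv")
    return df


def _run_plans(
    cls: ActivityClass,
    plans: Sequence[S.SplitPlan],
    config: RunConfig,
) -> list[M.MetricRecord]:
    """Fit/predict/decompose every (plan, method) combination."""
    index = cls.by_id()
    records: list[M.MetricRecord] = []
    for plan in plans:
        train = [index[i] for i in plan.train_ids]
        test = [index[i] for i in plan.test_ids]
        for method in config.methods:
            seed = _derived_seed(
                config.seed, cls.class_id, plan.protocol,
                plan.trial_index, plan.ladder_size, method,
            )
            try:
                model = R.fit(
                    method, train, grid=config.grid, cost=config.cost,
                    seed=seed,
                )
                result = R.predict(
                    model, test, class_id=cls.class_id,
                    trial_index=plan.trial_index,
                    ladder_size=plan.ladder_size,
                )
            except Exception:
                logger.exception(
                    "aborting (%s, trial %d, size %s, %s)",
                    cls.class_id, plan.trial_index, plan.ladder_size, method,
                )
                continue
            records.extend(M.decompose_by_subrange(result))
    return records


def run_benchmark(
    classes: Sequence[ActivityClass], config: Optional[RunConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global + sub-range benchmark on random 50/50 splits.

    Returns (metrics table, significance table).  The significance table
    holds, per class and per metric (MAE, RMSE, r^2), the pairwise
    Wilcoxon signed-rank comparisons over the per-trial GLOBAL values;
    methods with undefined per-trial values (e.g. MR's r^2) are excluded
    from that metric's comparisons.
    """
    config = config or RunConfig()
    all_records: list[M.MetricRecord] = []
    sig_frames: list[pd.DataFrame] = []
    for cls in classes:
        plans = S.random_5050_splits(cls, config.n_trials, config.seed)
        records = _run_plans(cls, plans, config)
        all_records.extend(records)
        df = M.metrics_to_frame(records)
        g = df[df["scope"] == "GLOBAL"]
        for metric in ("mae", "rmse", "r2"):
            scores = {}
            for method in config.methods:
                vals = g.loc[g["method"] == method, metric]
                if vals.notna().all() and len(vals) == config.n_trials:
                    scores[method] = vals.to_numpy()
            if len(scores) >= 2:
                res = M.wilcoxon_pairwise(scores, metric=metric.upper())
                sig_frames.append(
                    M.significance_to_frame(res, class_id=cls.class_id)
                )
    metrics_df = M.metrics_to_frame(all_records)
    sig_df = (
        pd.concat(sig_frames, ignore_index=True)
        if sig_frames
        else pd.DataFrame()
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_tsv(metrics_df, out / "benchmark_metrics.tsv")
        _write_tsv(sig_df, out / "benchmark_significance.tsv")
    return metrics_df, sig_df


def run_ladder(
    classes: Sequence[ActivityClass], config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Learning-curve study over the training-set ladder.

    Uses the balanced protocol unless ``config.protocol`` is
    ``IMBALANCED_LADDER``.  Classes that cannot support the ladder (too few
    compounds in a sub-range) are skipped with a logged reason.
    """
    config = config or RunConfig(protocol=S.BALANCED_LADDER)
    all_records: list[M.MetricRecord] = []
    for cls in classes:
        try:
            if config.protocol == S.IMBALANCED_LADDER:
                plans = S.imbalanced_ladder_splits(
                    cls, config.n_trials, config.seed
                )
            else:
                plans = S.balanced_ladder_splits(
                    cls, config.n_trials, config.seed,
                    nested=config.nested_ladder,
                )
        except ValueError as exc:
            logger.warning("skipping class %s: %s", cls.class_id, exc)
            continue
        all_records.extend(_run_plans(cls, plans, config))
    df = M.metrics_to_frame(all_records)
    if config.out_dir is not None:
        _write_tsv(df, Path(config.out_dir) / "ladder_metrics.tsv")
    return df


def ladder_median_curves(metrics_df: pd.DataFrame) -> pd.DataFrame:
    """Median-over-trials MAE per (class, method, scope, ladder size)."""
    df = metrics_df.dropna(subset=["mae", "ladder_size"])
    return (
        df.groupby(["class_id", "method", "scope", "ladder_size"])["mae"]
        .median()
        .reset_index(name="median_mae")
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# optional minimal plotting (TSVs are the canonical output)

def plot_distributions(classes: Sequence[ActivityClass], path) -> None:
    """Kernel-density plot of per-class potency distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.linspace(5, 11, 200)
    for cls in classes:
        kde = gaussian_kde(cls.potencies())
        ax.plot(xs, kde(xs), label=cls.class_id)
    ax.set_xlabel("pIC50")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_ladder_curves(metrics_df: pd.DataFrame, path) -> None:
    """Median MAE vs ladder size, one panel per scope."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = ladder_median_curves(metrics_df)
    scopes = [s for s in ("GLOBAL", *SUBRANGES) if s in set(curves["scope"])]
    fig, axes = plt.subplots(
        1, len(scopes), figsize=(3 * len(scopes), 3), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, scope in zip(axes, scopes):
        sub = curves[curves["scope"] == scope]
        for method, grp in sub.groupby("method"):
            agg = grp.groupby("ladder_size")["median_mae"].median()
            ax.plot(agg.index, agg.values, marker="o", ms=3, label=method)
        ax.set_title(scope, fontsize=9)
        ax.set_xlabel("training set size")
    axes[0].set_ylabel("median MAE (pIC50)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
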