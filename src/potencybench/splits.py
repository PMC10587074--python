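"""Train/test partition protocols.

Three protocols are provided:

* ``RANDOM_5050`` — 10 independent trials of random 50/50 compound
  partitioning, not balanced across potency sub-ranges (the standard
  benchmark setting);
* ``BALANCED_LADDER`` — per trial, nested training sets of sizes
  6, 12, 18, 30, 48, 78, 126, 204, 330 with equal per-sub-range counts
  (2, 4, 6, ... per sub-range), evaluated against one fixed sub-range
  balanced test set built from the compounds left outside the largest
  (330-compound) training pool;
* ``IMBALANCED_LADDER`` — the control: the same total training sizes
  sampled uniformly from the whole class, tested on the remainder.

Every plan is reconstructible from (class, protocol, master seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .records import SUBRANGES, ActivityClass

RANDOM_5050 = "RANDOM_5050"
BALANCED_LADDER = "BALANCED_LADDER"
IMBALANCED_LADDER = "IMBALANCED_LADDER"

_PROTO_CODE = {RANDOM_5050: 1, BALANCED_LADDER: 2, IMBALANCED_LADDER: 3}

#: Balanced training-set ladder: 6 (2 per sub-range) up to 330 (110 each).
_LADDER_SIZES = (6, 12, 18, 30, 48, 78, 126, 204, 330)


@dataclass(frozen=True)
class SplitPlan:
    """One reproducible train/test partition."""

    class_id: str
    trial_index: int
    seed: int
    protocol: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ladder_size: Optional[int] = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def ladder_sizes() -> list[int]:
    """Training-set sizes of the balanced ladder, smallest to largest."""
    return list(_LADDER_SIZES)


def _rng(
    master_seed: int, class_id: str, protocol: str, trial: int
) -> np.random.Generator:
    """Independent, reproducible stream per (class, protocol, trial)."""
    tag = zlib.crc32(class_id.encode("utf-8"))
    ss = np.random.SeedSequence(
        [int(master_seed), tag, _PROTO_CODE[protocol], int(trial)]
    )
    return np.random.default_rng(ss)


def random_5050_splits(
    cls: ActivityClass, n_trials: int = 10, seed: int = 0
) -> list[SplitPlan]:
    """Random 50/50 partitions for ``n_trials`` independent trials.

    No sub-range stratification.  For odd class sizes the training set
    receives the extra compound.
    """
    n = len(cls)
    if n < 2:
        raise ValueError(f"class {cls.class_id}: need >= 2 compounds")
    ids = np.array(cls.ids())
    n_train = (n + 1) // 2
    plans = []
    for t in range(n_trials):
        rng = _rng(seed, cls.class_id, RANDOM_5050, t)
        perm = rng.permutation(n)
        plans.append(
            SplitPlan(
                class_id=cls.class_id,
                trial_index=t,
                seed=seed,
                protocol=RANDOM_5050,
                train_ids=tuple(ids[perm[:n_train]]),
                test_ids=tuple(ids[perm[n_train:]]),
            )
        )
    return plans


def balanced_ladder_splits(
    cls: ActivityClass,
    n_trials: int = 10,
    seed: int = 0,
    nested: bool = True,
) -> list[SplitPlan]:
    """Balanced incremental training sets with a fixed balanced test set.

    Per trial: each sub-range is permuted once; its first 110 compounds form
    the training pool (the 330-compound largest training set).  Training
    sets of size ``s`` take ``s/3`` compounds per sub-range from the pool —
    nested by construction (each size extends the previous) unless
    ``nested=False``, in which case each size draws independently from the
    pool.  The test set is built from the compounds *outside* the pool,
    balanced with respect to the scarcest sub-range (in practice 9-11,
    which holds the fewest compounds): every sub-range contributes that
    many compounds.

    Raises
    ------
    ValueError
        Naming the deficient sub-range when a sub-range holds fewer than
        111 compounds (110 for the pool plus at least 1 for the test set).
    """
    per_pool = _LADDER_SIZES[-1] // 3
    sub_ids = cls.subrange_ids()
    for s in SUBRANGES:
        if len(sub_ids[s]) < per_pool + 1:
            raise ValueError(
                f"class {cls.class_id}: sub-range {s} has {len(sub_ids[s])} "
                f"compounds, needs >= {per_pool + 1} for the balanced ladder"
            )
    plans = []
    for t in range(n_trials):
        rng = _rng(seed, cls.class_id, BALANCED_LADDER, t)
        pool: dict[str, np.ndarray] = {}
        rest: dict[str, np.ndarray] = {}
        for s in SUBRANGES:
            perm = rng.permutation(np.array(sub_ids[s]))
            pool[s] = perm[:per_pool]
            rest[s] = perm[per_pool:]
        n_test_per = min(len(rest[s]) for s in SUBRANGES)
        test_ids = tuple(
            np.concatenate([rest[s][:n_test_per] for s in SUBRANGES])
        )
        for size in _LADDER_SIZES:
            k = size // 3
            if nested:
                train = np.concatenate([pool[s][:k] for s in SUBRANGES])
            else:
                train = np.concatenate(
                    [rng.choice(pool[s], size=k, replace=False) for s in SUBRANGES]
                )
            plans.append(
                SplitPlan(
                    class_id=cls.class_id,
                    trial_index=t,
                    seed=seed,
                    protocol=BALANCED_LADDER,
                    train_ids=tuple(train),
                    test_ids=test_ids,
                    ladder_size=size,
                )
            )
    return plans


def imbalanced_ladder_splits(
    cls: ActivityClass, n_trials: int = 10, seed: int = 0
) -> list[SplitPlan]:
    """Control ladder: the same total sizes without sub-range quotas.

    Per trial, one permutation of the whole class; training sets are nested
    prefixes of sizes 6..330 and the test set is everything beyond the
    330-compound pool (hence imbalanced, mirroring the class composition).
    """
    n = len(cls)
    need = _LADDER_SIZES[-1] + 3
    if n < need:
        raise ValueError(
            f"class {cls.class_id}: {n} compounds, needs >= {need} "
            "for the imbalanced ladder"
        )
    ids = np.array(cls.ids())
    plans = []
    for t in range(n_trials):
        rng = _rng(seed, cls.class_id, IMBALANCED_LADDER, t)
        perm = rng.permutation(n)
        test_ids = tuple(ids[perm[_LADDER_SIZES[-1]:]])
        for size in _LADDER_SIZES:
            plans.append(
                SplitPlan(
                    class_id=cls.class_id,
                    trial_index=t,
                    seed=seed,
                    protocol=IMBALANCED_LADDER,
                    train_ids=tuple(ids[perm[:size]]),
                    test_ids=test_ids,
                    ladder_size=size,
                )
            )
    return plans


def save_plans(plans: list[SplitPlan], path) -> None:
    """Serialize plans as JSON for exact experiment replay."""
    Path(path).write_text(
        json.dumps([asdict(p) for p in plans], indent=1), encoding="utf-8"
    )


def load_plans(path) -> list[SplitPlan]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        SplitPlan(
            class_id=d["class_id"],
            trial_index=d["trial_index"],
            seed=d["seed"],
            protocol=d["protocol"],
            train_ids=tuple(d["train_ids"]),
            test_ids=tuple(d["test_ids"]),
            ladder_size=d.get("ladder_size"),
        )
        for d in raw
    ]
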