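"""Synthetic activity classes with analogue-series SAR structure.

The generator emulates the statistical anatomy of curated ChEMBL-style
activity classes used in potency-prediction benchmarks, so the whole
pipeline runs with no download:

* a unimodal pIC50 distribution whose bulk sits at intermediate potency and
  whose class median falls in the interval [7, 8];
* heavy-enough tails that each of the three potency sub-ranges (LOW [5,7),
  MID [7,9), HIGH [9,11]) can be populated to a requested quota;
* analogue-series clustering expressed through binary fingerprints: the
  compounds of one series share a block of "core" bits and differ in a
  random subset of "substituent" bits, so within-series Tanimoto similarity
  is high and between-series similarity is low;
* a learnable fingerprint -> potency mapping: potency is the series base
  potency plus additive per-substituent-bit effects plus Gaussian noise,
  clipped to the curation window [5, 11].

No synthetic SMILES are produced — the downstream pipeline consumes
fingerprints, and ECFP4 generation is exercised separately on real SMILES.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .curation import assign_subrange, qualify_class
from .fingerprints import fingerprint_from_hex, fingerprint_to_hex
from .records import SUBRANGES, ActivityClass, CompoundRecord

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["compound_id", "smiles", "pIC50", "fingerprint_hex", "series_id"]

#: pIC50 intervals from which top-up series bases are drawn, per sub-range.
_TOPUP_BASE = {"LOW": (5.7, 6.5), "MID": (7.3, 8.3), "HIGH": (9.3, 10.1)}


class SubrangeQuotaError(RuntimeError):
    """A sub-range quota could not be met within the attempt budget."""

    def __init__(self, subrange: str, have: int, need: int):
        super().__init__(
            f"sub-range {subrange}: only {have} of the required "
            f"{need} compounds after the top-up budget was exhausted"
        )
        self.subrange = subrange


@dataclass(frozen=True)
class SyntheticSARConfig:
    """Parameters of one synthetic activity class.

    Series base potencies are drawn from a Student-t distribution
    (``base_potency_df`` degrees of freedom) centred at ``base_potency_loc``
    with scale ``base_potency_scale``: a two-sided unimodal distribution
    concentrated near 7.5 whose heavy tails populate the [9, 11] sub-range.
    Each substituent bit carries a fixed additive potency effect drawn from
    N(0, substituent_effect_sd); measurement noise is N(0, noise_sd).
    All potency parameters are in pIC50 units.
    """

    n_series: int = 100
    compounds_per_series: int = 6
    core_bits_per_series: int = 16
    substituent_bits: int = 384
    total_bits: int = 2048
    base_potency_loc: float = 7.5
    base_potency_scale: float = 0.75
    base_potency_df: float = 4.0
    substituents_per_compound: int = 8
    substituent_effect_sd: float = 0.15
    noise_sd: float = 0.3
    min_per_subrange: int = 75
    max_topup_rounds: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_bits < (
            self.n_series * self.core_bits_per_series + self.substituent_bits
        ):
            raise ValueError(
                "total_bits must cover n_series * core_bits_per_series "
                "+ substituent_bits"
            )
        if self.noise_sd < 0 or self.substituent_effect_sd < 0:
            raise ValueError("noise and effect scales must be >= 0")
        if self.min_per_subrange < 0:
            raise ValueError("min_per_subrange must be >= 0")
        if self.substituents_per_compound > self.substituent_bits:
            raise ValueError("substituents_per_compound exceeds the pool")


def _series_core_bits(cfg: SyntheticSARConfig, rng: np.random.Generator):
    """Core-bit block for a new series, sampled from the core region.

    The core region is everything above the substituent region; sampling is
    without replacement within a series, so two series overlap only by
    chance (a few bits out of >1000), keeping between-series Tanimoto low.
    """
    lo = cfg.substituent_bits
    return rng.choice(
        np.arange(lo, cfg.total_bits), size=cfg.core_bits_per_series,
        replace=False,
    )


def _make_series_compounds(
    cfg: SyntheticSARConfig,
    rng: np.random.Generator,
    series_index: int,
    base: float,
    effects: np.ndarray,
    n_compounds: int,
    id_offset: int,
) -> tuple[list[CompoundRecord], int]:
    """Generate one analogue series; returns (compounds, n_clipped)."""
    core = _series_core_bits(cfg, rng)
    clipped = 0
    out = []
    for j in range(n_compounds):
        subs = rng.choice(
            cfg.substituent_bits, size=cfg.substituents_per_compound,
            replace=False,
        )
        fp = np.zeros(cfg.total_bits, dtype=np.uint8)
        fp[core] = 1
        fp[subs] = 1
        pot = base + float(effects[subs].sum())
        if cfg.noise_sd > 0:
            pot += rng.normal(0.0, cfg.noise_sd)
        if pot < 5.0 or pot > 11.0:
            clipped += 1
            pot = float(np.clip(pot, 5.0, 11.0))
        out.append(
            CompoundRecord(
                compound_id=f"SYN{id_offset + j:05d}",
                pic50=float(pot),
                fingerprint=fp,
                smiles=None,
                subrange=assign_subrange(pot),
                series_id=f"S{series_index:03d}",
            )
        )
    return out, clipped


def generate_activity_class(
    config: SyntheticSARConfig, class_id: str = "SYN-0", name: str = ""
) -> ActivityClass:
    """Generate one synthetic activity class.

    The initial draw builds ``n_series`` analogue series of
    ``compounds_per_series`` compounds each.  If any potency sub-range then
    holds fewer than ``min_per_subrange`` compounds, additional series whose
    base potency lies inside the deficient sub-range are appended (targeted
    top-up) until every quota is met or ``max_topup_rounds`` series have
    been added, in which case :class:`SubrangeQuotaError` is raised.

    Deterministic: the same (config, seed) yields byte-identical classes.
    """
    rng = np.random.default_rng(config.seed)
    effects = (
        rng.normal(0.0, config.substituent_effect_sd, config.substituent_bits)
        if config.substituent_effect_sd > 0
        else np.zeros(config.substituent_bits)
    )
    compounds: list[CompoundRecord] = []
    clipped_total = 0
    for s in range(config.n_series):
        base = config.base_potency_loc + config.base_potency_scale * float(
            rng.standard_t(config.base_potency_df)
        )
        base = float(np.clip(base, 5.0, 11.0))
        series, clipped = _make_series_compounds(
            config, rng, s, base, effects, config.compounds_per_series,
            id_offset=len(compounds),
        )
        compounds.extend(series)
        clipped_total += clipped

    def counts() -> dict[str, int]:
        c = {s: 0 for s in SUBRANGES}
        for rec in compounds:
            c[rec.subrange] += 1
        return c

    n_topup = 0
    series_index = config.n_series
    while True:
        have = counts()
        deficient = [
            s for s in SUBRANGES if have[s] < config.min_per_subrange
        ]
        if not deficient:
            break
        if n_topup >= config.max_topup_rounds:
            worst = min(deficient, key=lambda s: have[s])
            raise SubrangeQuotaError(
                worst, have[worst], config.min_per_subrange
            )
        target = deficient[0]
        lo, hi = _TOPUP_BASE[target]
        base = float(rng.uniform(lo, hi))
        series, clipped = _make_series_compounds(
            config, rng, series_index, base, effects,
            config.compounds_per_series, id_offset=len(compounds),
        )
        compounds.extend(series)
        clipped_total += clipped
        series_index += 1
        n_topup += 1

    if clipped_total:
        logger.info(
            "class %s: %d potency values clipped to [5, 11]",
            class_id, clipped_total,
        )
    cls = ActivityClass(
        class_id=class_id,
        name=name or class_id,
        compounds=compounds,
        metadata=dict(
            config=dataclasses.asdict(config),
            n_series_total=series_index,
            n_clipped=clipped_total,
        ),
    )
    qualify_class(cls, config.min_per_subrange)
    return cls


def generate_benchmark_suite(
    n_classes: int,
    base_config: SyntheticSARConfig = SyntheticSARConfig(),
    seed: int = 0,
) -> list[ActivityClass]:
    """Generate a suite of classes with class-dependent potency peaks.

    Real activity classes share the qualitative shape (intermediate-potency
    bulk, median in [7, 8]) but differ in where their distribution peaks;
    the suite shifts each class's base-potency location across [-0.25, +0.35]
    around the configured centre and derives an independent per-class seed.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    ss = np.random.SeedSequence([int(seed), 0x5AB])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_classes)]
    if n_classes == 1:
        offsets = [0.0]
    else:
        offsets = list(np.linspace(-0.25, 0.35, n_classes))
    out = []
    for i in range(n_classes):
        cfg = dataclasses.replace(
            base_config,
            base_potency_loc=base_config.base_potency_loc + float(offsets[i]),
            seed=child_seeds[i],
        )
        out.append(
            generate_activity_class(cfg, class_id=f"SYN-{i}", name=f"synthetic target {i}")
        )
    return out


class ClassCsvError(ValueError):
    """Malformed synthetic-class CSV (carries the offending row number)."""


def write_class_csv(cls: ActivityClass, path) -> None:
    """Write a class in the package CSV schema (UTF-8, one header row)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for c in cls.compounds:
            w.writerow(
                [
                    c.compound_id,
                    c.smiles or "",
                    repr(float(c.pic50)),  # full precision round-trip
                    fingerprint_to_hex(c.fingerprint),
                    c.series_id or "",
                ]
            )


def read_class_csv(
    path, class_id: Optional[str] = None, n_bits: int = 2048,
    min_per_subrange: int = 75,
) -> ActivityClass:
    """Read a class CSV written by :func:`write_class_csv`.

    Round-trip identity holds field for field.  Rows with a pIC50 outside
    [5, 11] or a malformed schema raise :class:`ClassCsvError` naming the
    row number.
    """
    path = Path(path)
    compounds = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or "pIC50" not in header:
            raise ClassCsvError(f"{path}: missing header with a pIC50 column")
        idx = {name: header.index(name) for name in header}
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ClassCsvError(f"{path} row {rownum}: malformed row")
            try:
                pic50 = float(row[idx["pIC50"]])
            except ValueError as exc:
                raise ClassCsvError(
                    f"{path} row {rownum}: non-numeric pIC50"
                ) from exc
            if not (5.0 <= pic50 <= 11.0):
                raise ClassCsvError(
                    f"{path} row {rownum}: pIC50 {pic50} outside [5, 11]"
                )
            fp = fingerprint_from_hex(row[idx["fingerprint_hex"]], n_bits=n_bits)
            compounds.append(
                CompoundRecord(
                    compound_id=row[idx["compound_id"]],
                    pic50=pic50,
                    fingerprint=fp,
                    smiles=row[idx["smiles"]] or None,
                    subrange=assign_subrange(pic50),
                    series_id=row[idx["series_id"]] or None,
                )
            )
    cls = ActivityClass(class_id=class_id or path.stem, compounds=compounds)
    qualify_class(cls, min_per_subrange)
    return cls
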