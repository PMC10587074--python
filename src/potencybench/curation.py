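"""Compound-level curation filters and activity-class qualification.

Curation keeps compounds with pIC50 in the window [5, 11] and (when a mass
is known) a molecular mass of at most 1000 Da, assigns each survivor to one
of the three potency sub-ranges, and qualifies a class for benchmarking when
every sub-range holds at least 75 compounds.

The sub-ranges are nominally 5-6.9, 7-8.9 and 9-11; this module uses the
gap-free half-open convention LOW = [5, 7), MID = [7, 9), HIGH = [9, 11]
(boundaries configurable via ``edges``).
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import SUBRANGES, ActivityClass, CompoundRecord

logger = logging.getLogger(__name__)

#: Curation window and interior sub-range boundaries on the pIC50 scale.
DEFAULT_EDGES: tuple[float, float, float, float] = (5.0, 7.0, 9.0, 11.0)

#: Qualification threshold: minimum compounds per sub-range.
MIN_PER_SUBRANGE: int = 75

#: Maximum molecular mass retained by curation (Da).
MASS_MAX: float = 1000.0


class PotencyRangeError(ValueError):
    """pIC50 outside the curation window [5, 11]."""


def assign_subrange(
    pic50: float, edges: Sequence[float] = DEFAULT_EDGES
) -> str:
    """Map a curated pIC50 to its sub-range label.

    LOW for [5, 7), MID for [7, 9), HIGH for [9, 11] under default edges.

    Raises
    ------
    PotencyRangeError
        If ``pic50`` lies outside ``[edges[0], edges[-1]]``.
    """
    lo, m1, m2, hi = edges
    if not (lo <= pic50 <= hi) or math.isnan(pic50):
        raise PotencyRangeError(
            f"pIC50 {pic50} outside curation window [{lo}, {hi}]"
        )
    if pic50 < m1:
        return "LOW"
    if pic50 < m2:
        return "MID"
    return "HIGH"


def _as_record(row) -> CompoundRecord:
    """Normalize a raw row (CompoundRecord or mapping) to a CompoundRecord."""
    if isinstance(row, CompoundRecord):
        return row
    if isinstance(row, Mapping):
        pic50 = row.get("pic50", row.get("pIC50"))
        return CompoundRecord(
            compound_id=str(row.get("compound_id")),
            pic50=float(pic50),
            fingerprint=row.get("fingerprint"),
            smiles=row.get("smiles") or None,
            mol_mass=(
                float(row["mol_mass"])
                if row.get("mol_mass") not in (None, "")
                else None
            ),
            series_id=row.get("series_id") or None,
        )
    raise TypeError(f"cannot curate row of type {type(row).__name__}")


def curate(
    records: Iterable,
    mass_max: float = MASS_MAX,
    edges: Sequence[float] = DEFAULT_EDGES,
    interference_filter: Optional[Callable[[CompoundRecord], bool]] = None,
) -> list[CompoundRecord]:
    """Apply the compound-level filters and assign sub-range labels.

    Rows may be :class:`CompoundRecord` objects or mappings with keys
    ``compound_id``, ``pic50`` (or ``pIC50``) and optionally ``smiles``,
    ``mol_mass``, ``fingerprint``, ``series_id``.

    Rules, applied in order while preserving input order of survivors:

    * rows with a non-numeric potency are skipped (logged, not fatal);
    * rows with pIC50 outside the curation window are dropped;
    * rows with a *known* mass above ``mass_max`` are dropped (rows without
      a mass are retained — synthetic compounds carry no mass);
    * ``interference_filter``, when given, is a hook returning True to keep
      a compound (assay-interference screening is the upstream extractor's
      job; the default is pass-through).
    """
    out: list[CompoundRecord] = []
    for i, row in enumerate(records):
        try:
            rec = _as_record(row)
        except (TypeError, ValueError) as exc:
            logger.warning("curation: skipping row %d (%s)", i, exc)
            continue
        if math.isnan(rec.pic50) or not (edges[0] <= rec.pic50 <= edges[-1]):
            continue
        if rec.mol_mass is not None and rec.mol_mass > mass_max:
            continue
        if interference_filter is not None and not interference_filter(rec):
            continue
        sub = assign_subrange(rec.pic50, edges)
        if rec.subrange != sub:
            rec = rec.copy(subrange=sub)
        out.append(rec)
    return out


def qualify_class(
    cls: ActivityClass, min_per_subrange: int = MIN_PER_SUBRANGE
) -> bool:
    """Check the per-sub-range population rule and set ``cls.qualified``.

    A class qualifies when every one of the three sub-ranges contains at
    least ``min_per_subrange`` compounds.
    """
    counts = cls.subrange_counts()
    cls.qualified = all(counts[s] >= min_per_subrange for s in SUBRANGES)
    return cls.qualified


def load_class_csv(
    path,
    class_id: Optional[str] = None,
    name: str = "",
    columns: Optional[Mapping[str, str]] = None,
    mass_max: float = MASS_MAX,
    n_bits: int = 2048,
    min_per_subrange: int = MIN_PER_SUBRANGE,
) -> ActivityClass:
    """Load and curate an activity class from a conforming CSV table.

    Accepts the package's own CSV schema (``compound_id, smiles, pIC50,
    fingerprint_hex, series_id``) as well as externally curated class tables
    via ``columns``, a mapping from the canonical column names above (plus
    optional ``mol_mass``) to the file's actual column names.  When the file
    carries SMILES but no fingerprint column, 2048-bit ECFP4 fingerprints
    are computed from the structures.
    """
    import pandas as pd

    from . import fingerprints as fp_mod

    df = pd.read_csv(path)
    colmap = dict(columns or {})

    def col(canon: str):
        name_ = colmap.get(canon, canon)
        return df[name_] if name_ in df.columns else None

    pic50 = col("pIC50")
    if pic50 is None:
        pic50 = col("pic50")
    if pic50 is None:
        raise KeyError(f"{path}: no potency column (expected 'pIC50')")
    ids = col("compound_id")
    if ids is None:
        ids = pd.Series([f"C{i}" for i in range(len(df))])
    smiles = col("smiles")
    fphex = col("fingerprint_hex")
    mass = col("mol_mass")
    series = col("series_id")

    rows = []
    for i in range(len(df)):
        fp = None
        if fphex is not None and isinstance(fphex.iloc[i], str) and fphex.iloc[i]:
            fp = fp_mod.fingerprint_from_hex(fphex.iloc[i], n_bits=n_bits)
        elif smiles is not None and isinstance(smiles.iloc[i], str) and smiles.iloc[i]:
            fp = fp_mod.ecfp4(smiles.iloc[i], n_bits=n_bits)
        rows.append(
            dict(
                compound_id=str(ids.iloc[i]),
                pic50=pic50.iloc[i],
                smiles=smiles.iloc[i] if smiles is not None else None,
                mol_mass=mass.iloc[i] if mass is not None else None,
                fingerprint=fp,
                series_id=(
                    str(series.iloc[i])
                    if series is not None and isinstance(series.iloc[i], str)
                    else None
                ),
            )
        )
    compounds = curate(rows, mass_max=mass_max)
    cls = ActivityClass(
        class_id=class_id or str(path), name=name, compounds=compounds
    )
    qualify_class(cls, min_per_subrange)
    return cls
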