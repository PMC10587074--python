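"""Core data containers: compounds and activity classes.

An *activity class* (target set) is the set of curated compounds with a
measured potency (pIC50) against one protein target.  Compounds carry a
fixed-length binary fingerprint and a potency sub-range label: LOW for
pIC50 in [5, 7), MID for [7, 9), HIGH for [9, 11].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

#: Canonical sub-range labels, in increasing potency order.
SUBRANGES: tuple[str, str, str] = ("LOW", "MID", "HIGH")

#: Scopes used in metric records: the whole test set plus the three sub-ranges.
SCOPES: tuple[str, str, str, str] = ("GLOBAL",) + SUBRANGES


@dataclass
class CompoundRecord:
    """One compound: identity, optional structure, fingerprint and potency.

    Parameters
    ----------
    compound_id
        Opaque unique identifier within a class.
    pic50
        Negative decadic logarithm of the IC50; curated values lie in [5, 11].
    fingerprint
        Binary vector (dtype uint8, values 0/1), typically 2048 bits.
    smiles
        Optional structure; empty/None for synthetic compounds.
    mol_mass
        Optional molecular mass in Da.
    subrange
        Potency sub-range label ("LOW", "MID", "HIGH"), assigned by curation.
    series_id
        Optional analogue-series tag (synthetic data records its series).
    """

    compound_id: str
    pic50: float
    fingerprint: Optional[np.ndarray] = None
    smiles: Optional[str] = None
    mol_mass: Optional[float] = None
    subrange: Optional[str] = None
    series_id: Optional[str] = None

    def copy(self, **changes) -> "CompoundRecord":
        return replace(self, **changes)

    def __eq__(self, other) -> bool:  # fingerprint needs array comparison
        if not isinstance(other, CompoundRecord):
            return NotImplemented
        same_fp = (
            (self.fingerprint is None and other.fingerprint is None)
            or (
                self.fingerprint is not None
                and other.fingerprint is not None
                and np.array_equal(self.fingerprint, other.fingerprint)
            )
        )
        return (
            same_fp
            and self.compound_id == other.compound_id
            and self.pic50 == other.pic50
            and self.smiles == other.smiles
            and self.mol_mass == other.mol_mass
            and self.subrange == other.subrange
            and self.series_id == other.series_id
        )


@dataclass
class ActivityClass:
    """A named target set of compounds with qualification metadata."""

    class_id: str
    name: str = ""
    compounds: list[CompoundRecord] = field(default_factory=list)
    qualified: bool = False
    #: free-form provenance (e.g. synthetic generator parameters, clipped mass)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.compound_id for c in self.compounds]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"duplicate compound_ids in class {self.class_id!r}"
            )

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.compounds)

    def ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    def by_id(self) -> dict[str, CompoundRecord]:
        return {c.compound_id: c for c in self.compounds}

    def select(self, ids: Iterable[str]) -> list[CompoundRecord]:
        """Compounds for the given ids, in the given order."""
        index = self.by_id()
        return [index[i] for i in ids]

    def potencies(self) -> np.ndarray:
        return np.array([c.pic50 for c in self.compounds], dtype=float)

    def fingerprint_matrix(self) -> np.ndarray:
        """Stack fingerprints into an (n_compounds, n_bits) uint8 matrix."""
        if not self.compounds:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.vstack([c.fingerprint for c in self.compounds]).astype(np.uint8)

    def subrange_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SUBRANGES}
        for c in self.compounds:
            if c.subrange in counts:
                counts[c.subrange] += 1
        return counts

    def subrange_ids(self) -> dict[str, list[str]]:
        """Compound ids per sub-range, preserving class order."""
        out: dict[str, list[str]] = {s: [] for s in SUBRANGES}
        for c in self.compounds:
            if c.subrange in out:
                out[c.subrange].append(c.compound_id)
        return out
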