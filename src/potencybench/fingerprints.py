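"""Folded ECFP4 fingerprints and Tanimoto similarity / kernel matrices.

Compounds are represented by the folded 2048-bit extended-connectivity
fingerprint with bond diameter 4 (ECFP4, Morgan radius 2), computed with
RDKit.  Tanimoto similarity |a AND b| / |a OR b| doubles as the (positive
semidefinite) kernel for support vector regression and as the similarity
used by the nearest-neighbor controls.
"""

from __future__ import annotations

import functools
import logging
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_BITS_DEFAULT = 2048


class SmilesParseError(ValueError):
    """Raised when RDKit cannot parse a SMILES string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


@functools.lru_cache(maxsize=8)
def _morgan_generator(n_bits: int):
    from rdkit.Chem import rdFingerprintGenerator

    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)


def ecfp4(smiles: str, n_bits: int = N_BITS_DEFAULT) -> np.ndarray:
    """Folded binary ECFP4 (Morgan radius 2) fingerprint of a SMILES.

    Deterministic for a given RDKit version: the same molecule yields the
    same bit vector regardless of the SMILES spelling.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return _morgan_generator(n_bits).GetFingerprintAsNumPy(mol).astype(np.uint8)


def fingerprint_to_hex(bits: np.ndarray) -> str:
    """Serialize a binary fingerprint as a hex string (bit length * 1/4)."""
    bits = np.asarray(bits, dtype=np.uint8)
    return np.packbits(bits).tobytes().hex()


def fingerprint_from_hex(s: str, n_bits: Optional[int] = None) -> np.ndarray:
    """Inverse of :func:`fingerprint_to_hex`."""
    raw = np.unpackbits(np.frombuffer(bytes.fromhex(s), dtype=np.uint8))
    if n_bits is not None:
        if n_bits > raw.size:
            raise ValueError(
                f"hex string encodes {raw.size} bits, need {n_bits}"
            )
        raw = raw[:n_bits]
    return raw.astype(np.uint8)


def tanimoto(
    a: np.ndarray, b: np.ndarray, zero_zero: float = 1.0
) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary vectors.

    Symmetric and bounded in [0, 1]; equals 1 iff the set bits coincide.
    A pair of all-zero fingerprints has an undefined ratio; by convention
    it is reported as ``zero_zero`` (default 1.0: identical empty bit sets),
    logged, since valid molecules always set at least one bit.
    """
    a = np.asarray(a, dtype=np.uint8)
    b = np.asarray(b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError(
            f"fingerprint length mismatch: {a.shape} vs {b.shape}"
        )
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        logger.warning("tanimoto of two all-zero fingerprints -> %s", zero_zero)
        return float(zero_zero)
    return inter / union


def _stack(fps: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    arr = np.asarray(fps, dtype=np.uint8)
    if arr.ndim == 1 and arr.size == 0:
        return arr.reshape(0, 0)
    if arr.ndim != 2:
        raise ValueError("expected a sequence of equal-length fingerprints")
    return arr


def tanimoto_matrix(
    A: Sequence[np.ndarray] | np.ndarray,
    B: Optional[Sequence[np.ndarray] | np.ndarray] = None,
    zero_zero: float = 1.0,
) -> np.ndarray:
    """Pairwise Tanimoto matrix; T[i, j] = tanimoto(A[i], B[j]).

    With ``B=None`` the Gram matrix of ``A`` is returned: symmetric, unit
    diagonal (for non-empty fingerprints), and positive semidefinite up to
    numerical round-off — the kernel matrix for SVR.
    """
    A = _stack(A)
    B = A if B is None else _stack(B)
    if A.size == 0 or B.size == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"fingerprint length mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    Af = A.astype(np.float64)
    Bf = B.astype(np.float64)
    inter = Af @ Bf.T  # exact: counts are small integers
    pa = Af.sum(axis=1)[:, None]
    pb = Bf.sum(axis=1)[None, :]
    union = pa + pb - inter
    out = np.full_like(inter, float(zero_zero))
    np.divide(inter, union, out=out, where=union > 0)
    return out
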