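"""Fingerprint generators, similarity metrics and the substructure prescreen
fingerprint.

Fingerprints are exchanged as dense numpy 0/1 vectors of a fixed width per
named generator; the store persists them as set-bit index lists.  Generators
and metrics live in plain registries so user code can plug in its own
implementations under new names (looked up everywhere a fingerprint or a
metric is asked for: similarity search, diversity selection, reports).

The substructure prescreen fingerprint is a path/ring pattern fingerprint
folded to exactly 1056 bits — 33 machine words of 32 bits — with the
superset guarantee: if Q is a substructure of M then every bit set for Q is
set for M, so screening by bitwise containment never discards a true match.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

#: 33 unsigned 32-bit words.
SUBFP_WORDS = 33
SUBFP_BITS = SUBFP_WORDS * 32

BitVector = np.ndarray  # dtype uint8, values in {0, 1}


def from_on_bits(on_bits, n_bits: int) -> BitVector:
    vec = np.zeros(n_bits, dtype=np.uint8)
    idx = np.asarray(list(on_bits), dtype=np.int64)
    if idx.size:
        if idx.min() < 0 or idx.max() >= n_bits:
            raise ValueError(f"bit index out of range for {n_bits}-bit vector")
        vec[idx] = 1
    return vec


def to_on_bits(vec: BitVector) -> list[int]:
    return np.flatnonzero(vec).tolist()


def _rdkit_bv_to_numpy(bv) -> BitVector:
    vec = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    on = list(bv.GetOnBits())
    if on:
        vec[on] = 1
    return vec


# -- similarity fingerprints -------------------------------------------------

def maccs_fingerprint(mol: Chem.Mol) -> BitVector:
    """166 structural keys (+1 unused leading bit, RDKit convention)."""
    return _rdkit_bv_to_numpy(MACCSkeys.GenMACCSKeys(mol))


_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def morgan_fingerprint(mol: Chem.Mol) -> BitVector:
    """Circular (ECFP4-like) fingerprint folded to 1024 bits."""
    return _rdkit_bv_to_numpy(_morgan_gen.GetFingerprint(mol))


FINGERPRINTS: dict[str, Callable[[Chem.Mol], BitVector]] = {}
FINGERPRINT_BITS: dict[str, int] = {}


def register_fingerprint(name: str, fn: Callable[[Chem.Mol], BitVector], n_bits: int):
    if name in FINGERPRINTS:
        raise ValueError(f"fingerprint {name!r} already registered")
    FINGERPRINTS[name] = fn
    FINGERPRINT_BITS[name] = n_bits


def get_fingerprint_fn(name: str) -> Callable[[Chem.Mol], BitVector]:
    try:
        return FINGERPRINTS[name]
    except KeyError:
        raise KeyError(
            f"unknown fingerprint {name!r}; available: {sorted(FINGERPRINTS)}"
        ) from None


register_fingerprint("maccs", maccs_fingerprint, 167)
register_fingerprint("morgan2", morgan_fingerprint, 1024)


# -- substructure prescreen fingerprint --------------------------------------

def substructure_fingerprint(mol: Chem.Mol) -> BitVector:
    return _rdkit_bv_to_numpy(Chem.PatternFingerprint(mol, fpSize=SUBFP_BITS))


def is_subset(query: BitVector, target: BitVector) -> bool:
    """True when every bit of ``query`` is also set in ``target``."""
    return not np.any(query & ~target)


# -- similarity metrics ------------------------------------------------------

def tanimoto(a: BitVector, b: BitVector) -> float:
    """|a AND b| / |a OR b|; defined as 0 when both vectors are empty."""
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def dice(a: BitVector, b: BitVector) -> float:
    total = int(np.sum(a)) + int(np.sum(b))
    if total == 0:
        return 0.0
    return 2 * int(np.sum(a & b)) / total


def continuous_tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto generalised to real-valued vectors: sum(min)/sum(max).

    Used for comparing a member bit vector with a per-bit frequency
    (average fingerprint) vector; coincides with the binary Tanimoto on 0/1
    input.
    """
    hi = np.maximum(a, b).sum()
    if hi == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / hi)


METRICS: dict[str, Callable[[BitVector, BitVector], float]] = {}


def register_metric(name: str, fn: Callable[[BitVector, BitVector], float]):
    if name in METRICS:
        raise ValueError(f"metric {name!r} already registered")
    METRICS[name] = fn


def get_metric(name: str) -> Callable[[BitVector, BitVector], float]:
    try:
        return METRICS[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; available: {sorted(METRICS)}"
        ) from None


register_metric("tanimoto", tanimoto)
register_metric("dice", dice)
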