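"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = "ACGT"

# uint8 code <-> base maps for vectorized work
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """Encode ACGT to uint8 codes 0..3 (anything else -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability `rate`.

    Substitutions always change the base (uniform over the 3 alternatives),
    so expected identity to the input is exactly 1 - rate.
    """
    if rate < 0 or rate >= 1:
        raise ValueError("substitution rate must be in [0, 1)")
    if rate == 0 or not seq:
        return seq
    codes = encode(seq).copy()
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes)


def identity(a: str, b: str) -> float:
    """Base-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        raise ValueError("empty sequences")
    return float(np.mean(encode(a) == encode(b)))
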