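"""Shared low-level helpers: base encoding, reverse complement, seed derivation."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_N = 4

# byte-level lookup tables for fast encode / complement
_ENCODE_LUT = np.full(256, CODE_N, dtype=np.uint8)
for _b, _i in BASE_TO_CODE.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A"),
               ("a", "t"), ("c", "g"), ("g", "c"), ("t", "a")]:
    _COMP_LUT[ord(_a)] = ord(_b)

_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    arr = _COMP_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][::-1]
    return arr.tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes][::-1]


def derive_seed(*parts) -> int:
    """Stable sub-stream seed below 2**31, derived by hashing the parts.

    Identical part tuples always map to the same seed, independent of process
    hash randomisation, so any specimen/stage can be regenerated in isolation.
    """
    key = ":".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)
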