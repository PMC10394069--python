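"""Reference genome container with 1-based, optionally circular coordinates.

Mitochondrial genomes are circular; every coordinate in this package is
1-based inclusive, matching the convention in which diagnostic sites such as
the control-region positions are reported. Fetches on a circular reference
wrap transparently through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import encode

_VALID = set("ACGT")


@dataclass(frozen=True)
class ReferenceGenome:
    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("reference sequence must be non-empty")
        seq = self.sequence.upper()
        if set(seq) - _VALID:
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"reference alphabet restricted to ACGT, found {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position `pos`; wraps when circular."""
        L = len(self.sequence)
        if self.circular:
            return self.sequence[(pos - 1) % L]
        if not 1 <= pos <= L:
            raise IndexError(f"position {pos} outside linear reference 1..{L}")
        return self.sequence[pos - 1]

    def fetch(self, start: int, length: int) -> str:
        """Substring of `length` bases starting at 1-based `start` (wrapping)."""
        L = len(self.sequence)
        if length < 0:
            raise ValueError("length must be >= 0")
        if self.circular:
            i = (start - 1) % L
            dbl = self.sequence + self.sequence
            if length > L:
                raise ValueError("fetch longer than circular genome")
            return dbl[i:i + length]
        if start < 1 or start + length - 1 > L:
            raise IndexError(f"interval {start}..{start + length - 1} outside 1..{L}")
        return self.sequence[start - 1:start - 1 + length]

    def doubled(self) -> str:
        """Doubled sequence for circular matching (linear: the sequence itself)."""
        return self.sequence + self.sequence if self.circular else self.sequence

    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def with_base(self, pos: int, base: str) -> "ReferenceGenome":
        L = len(self.sequence)
        i = (pos - 1) % L if self.circular else pos - 1
        s = self.sequence[:i] + base + self.sequence[i + 1:]
        return ReferenceGenome(self.name, s, self.circular)
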