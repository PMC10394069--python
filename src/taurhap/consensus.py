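"""Consensus calling from pileups with a 75% majority threshold.

At every reference position the winning allele (base or deletion) is emitted
when it holds at least ``threshold`` of the depth (inclusive: an exact-75%
tie is a call) and the depth reaches ``min_depth``; otherwise N.  Insertions
must clear the same support rule.  ``min_depth`` (default 3) is this
package's explicit stand-in for an interactive assembler's unspecified
"highest quality" setting; raw counts are used throughout, not
quality-weighted ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import Pileup

_ALLELES = np.frombuffer(b"ACGT-", dtype=np.uint8)


@dataclass
class ConsensusSequence:
    """Called consensus in reference coordinates.

    ``aligned`` has exactly reference length, one character per reference
    position over A/C/G/T/N/'-' ('-' = consensus deletion); ``insertions``
    maps the 1-based position each insertion follows to its motif.  The
    ungapped ``sequence`` property splices insertions in and drops deletions.
    """

    aligned: str
    insertions: dict
    depth: np.ndarray
    winning_fraction: np.ndarray
    threshold: float
    min_depth: int

    def __len__(self):
        return len(self.aligned)

    @property
    def sequence(self) -> str:
        if not self.insertions:
            return self.aligned.replace("-", "")
        parts = []
        for i, ch in enumerate(self.aligned, start=1):
            if ch != "-":
                parts.append(ch)
            ins = self.insertions.get(i)
            if ins:
                parts.append(ins)
        return "".join(parts)

    def base_at(self, pos: int) -> str:
        """Character at 1-based reference position (N, or '-' for deletion)."""
        return self.aligned[pos - 1]

    @property
    def n_fraction(self) -> float:
        return self.aligned.count("N") / len(self.aligned)

    @property
    def low_confidence_mask(self) -> np.ndarray:
        return np.frombuffer(self.aligned.encode(), dtype=np.uint8) == ord("N")

    def to_call_table(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({
            "pos": np.arange(1, len(self.aligned) + 1),
            "call": list(self.aligned),
            "depth": self.depth,
            "winning_fraction": np.round(self.winning_fraction, 6),
        }).to_csv(str(path), sep="\t", index=False)

    def to_fasta(self, path: str | Path, name: str = "consensus") -> None:
        from .simulate import write_fasta
        write_fasta({name: self.sequence}, path)


def call_consensus(pileup: Pileup, threshold: float = 0.75,
                   min_depth: int = 3) -> ConsensusSequence:
    """Call the consensus from per-position allele counts."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    if depth.sum() == 0:
        warnings.warn("empty pileup: consensus is all N", stacklevel=2)
    winner = counts.argmax(axis=1)
    top = counts[np.arange(len(counts)), winner]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    called = (depth >= max(min_depth, 1)) & (frac >= threshold)
    chars = np.where(called, _ALLELES[winner], ord("N")).astype(np.uint8)
    aligned = chars.tobytes().decode("ascii")

    insertions = {}
    for pos, motifs in pileup.insertions.items():
        motif, count = max(motifs.items(), key=lambda kv: (kv[1], kv[0]))
        d = depth[(pos - 1) % pileup.ref_length]
        if d >= min_depth and d > 0 and count / d >= threshold:
            insertions[pos] = motif

    return ConsensusSequence(aligned=aligned, insertions=insertions,
                             depth=depth, winning_fraction=frac,
                             threshold=threshold, min_depth=min_depth)
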