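"""Haplotype diversity, segregating sites and haplogroup frequency tables.

Haplotype diversity is Nei's unbiased gene diversity,

    H = n (1 - sum_i p_i^2) / (n - 1),

the probability that two sequences drawn without replacement carry different
haplotypes — the statistic polymorphism-analysis tools report for a
control-region alignment.  Nucleotide diversity (pi) is the mean pairwise
difference per included site; segregating sites (S) are columns with at
least two observed alleles after gap/N columns are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._util import encode
from .network import HaplotypeTable, collapse_haplotypes

#: sub-clade to reporting-label rollup used for frequency tables
DEFAULT_ROLLUP = {"T1a": "T1", "T1b": "T1", "T1b1": "T1", "T1c": "T1",
                  "T1c1a1": "T1c1a1", "T1d": "T1", "T123": "T"}


def haplotype_diversity(multiplicities) -> float:
    """Nei's unbiased haplotype diversity from haplotype counts."""
    counts = [int(c) for c in multiplicities]
    if any(c < 1 for c in counts):
        raise ValueError("all multiplicities must be >= 1")
    n = sum(counts)
    if n < 2:
        raise ValueError(f"haplotype diversity undefined for n={n} (< 2)")
    p2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - p2) / (n - 1)


@dataclass
class DiversityReport:
    n: int
    k: int
    H: float
    S: int
    pi: float
    included_sites: int
    dropped_columns: int
    region: object = None

    def rounded(self) -> dict:
        """Report view (3-decimal H, 4-decimal pi); full precision retained."""
        return {"n": self.n, "k": self.k, "H": round(self.H, 3),
                "S": self.S, "pi": round(self.pi, 4),
                "included_sites": self.included_sites}

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame([{
            "n_sequences": self.n, "n_haplotypes": self.k,
            "haplotype_diversity": self.H, "segregating_sites": self.S,
            "nucleotide_diversity": self.pi,
            "included_sites": self.included_sites,
            "dropped_columns": self.dropped_columns,
        }]).to_csv(str(path), sep="\t", index=False)


def summarize(sequences, region=None) -> DiversityReport:
    """Collapse an alignment and compute n, k, H, S and pi over a region."""
    table = collapse_haplotypes(sequences, region=region)
    n = table.n_sequences
    if n < 2:
        raise ValueError("need at least two sequences")
    k = len(table)
    H = haplotype_diversity(table.multiplicity) if k >= 1 else 0.0

    mat = np.vstack([encode(s) for s in table.sequences])
    mult = np.asarray(table.multiplicity)
    n_sites = mat.shape[1]
    S = int(sum(len(np.unique(mat[:, j])) > 1 for j in range(n_sites)))

    # pi: mean pairwise difference per site over all n(n-1)/2 sequence pairs
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    num = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            num += mult[i] * mult[j] * diff[i, j]
    pi = num / (n * (n - 1) / 2) / n_sites
    return DiversityReport(n=n, k=k, H=H, S=S, pi=float(pi),
                           included_sites=n_sites,
                           dropped_columns=len(table.dropped_columns),
                           region=region)


@dataclass
class FrequencyTable:
    counts: dict             # reporting label -> count
    n: int

    @property
    def frequencies(self) -> dict:
        return {k: v / self.n for k, v in self.counts.items()} if self.n else {}

    def rounded(self, ndigits: int = 2) -> dict:
        return {k: round(v, ndigits) for k, v in self.frequencies.items()}

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        freqs = self.frequencies
        pd.DataFrame(
            [(k, self.counts[k], freqs[k], round(freqs[k], 2))
             for k in sorted(self.counts)],
            columns=["haplogroup", "count", "frequency", "frequency_2dp"],
        ).to_csv(str(path), sep="\t", index=False)


def haplogroup_frequencies(calls, rollup: dict | None = None) -> FrequencyTable:
    """Counts and frequencies per reporting label, sub-clades rolled up.

    ``calls`` is a list of MtCall objects or (specimen_id, label) pairs;
    non-assigned calls are counted under "unassigned".  Full-precision
    frequencies sum to 1; the report view rounds to 2 decimals.
    """
    if rollup is None:
        rollup = DEFAULT_ROLLUP
    counter: Counter = Counter()
    total = 0
    for call in calls:
        if hasattr(call, "status"):
            label = call.haplogroup if call.status == "assigned" else None
        else:
            _sid, label = call
        counter[rollup.get(label, label) if label else "unassigned"] += 1
        total += 1
    return FrequencyTable(counts=dict(counter), n=total)
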