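"""Y-chromosome haplogroup typing from the seven-marker intron matrix.

Three main bovine paternal lineages are distinguished by five SNPs, one
(AT)n microsatellite and one 2-bp indel across five Y introns: Y1 and Y2
(taurine, north/south European gradient) and Y3 (indicine).  A specimen's
marker states are read off per-region consensus sequences in reference
coordinates; the allele vector is then matched exactly against the three
haplogroup rows, requiring at least ``min_callable`` callable markers and a
unique consistent row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

from .consensus import ConsensusSequence
from .simulate import load_y_config

MARKER_NAMES = ("ddx3y1_snp", "ddx3y1_at_repeat", "ddx3y7_snp", "uty19_snp",
                "zfy9_snp", "zfy10_snp", "zfy10_indel")


@dataclass(frozen=True)
class YAlleleVector:
    """States at the seven markers; None means uncallable."""

    ddx3y1_snp: str | None = None
    ddx3y1_at_repeat: int | None = None
    ddx3y7_snp: str | None = None
    uty19_snp: str | None = None
    zfy9_snp: str | None = None
    zfy10_snp: str | None = None
    zfy10_indel: str | None = None     # "present" | "absent" | None

    def __post_init__(self):
        if self.ddx3y1_at_repeat is not None and self.ddx3y1_at_repeat < 0:
            raise ValueError("repeat count must be >= 0")
        for f in ("ddx3y1_snp", "ddx3y7_snp", "uty19_snp", "zfy9_snp", "zfy10_snp"):
            v = getattr(self, f)
            if v is not None and v not in "ACGTN":
                raise ValueError(f"{f} must be a base or None, got {v!r}")
        if self.zfy10_indel not in (None, "present", "absent"):
            raise ValueError(f"zfy10_indel must be present/absent/None")

    def n_callable(self) -> int:
        return sum(getattr(self, m) is not None and getattr(self, m) != "N"
                   for m in MARKER_NAMES)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in MARKER_NAMES}


def haplogroup_table(config: dict | None = None) -> dict:
    """The three published haplogroup rows as YAlleleVector-compatible dicts."""
    cfg = config or load_y_config()
    table = {}
    for name, row in cfg["haplogroups"].items():
        table[name] = {m: row[m] for m in MARKER_NAMES}
    return table


def _aligned_string(consensus) -> str:
    if isinstance(consensus, ConsensusSequence):
        return consensus.aligned
    return consensus


def _genotype_snp(aligned: str, pos: int) -> str | None:
    if pos > len(aligned):
        return None
    b = aligned[pos - 1]
    return None if b in ("N", "-") else b


def _genotype_microsat(aligned: str, pos: int, unit: str) -> int | None:
    """Repeat units of the maximal uninterrupted run containing the anchor.

    Consensus deletions ('-') inside the run are removed first (a contracted
    microsatellite appears as deleted units against the reference frame);
    any N in or immediately flanking the run makes the marker uncallable.
    """
    if pos > len(aligned):
        return None
    # map anchor into the gap-free string
    gaps_before = aligned[:pos - 1].count("-")
    ungapped = aligned.replace("-", "")
    anchor = pos - 1 - gaps_before
    if anchor >= len(ungapped):
        return None
    for m in re.finditer(f"(?:{unit})+", ungapped):
        if m.start() <= anchor < m.end():
            lo = max(m.start() - 1, 0)
            hi = min(m.end() + 1, len(ungapped))
            if "N" in ungapped[lo:hi]:
                return None
            return (m.end() - m.start()) // len(unit)
    return None


def _genotype_indel(aligned: str, pos: int, motif: str) -> str | None:
    if pos + len(motif) - 1 > len(aligned):
        return None
    window = aligned[pos - 1:pos - 1 + len(motif)]
    if "N" in window:
        return None
    if window == motif:
        return "present"
    if window == "-" * len(motif):
        return "absent"
    return None


def genotype_y_markers(regions: dict, config: dict | None = None) -> YAlleleVector:
    """Read the seven marker states from per-region consensus sequences.

    ``regions`` maps region name (ddx3y1, ddx3y7, uty19, zfy9, zfy10) to a
    ConsensusSequence or an aligned reference-frame string.  Missing regions
    leave their markers uncallable; a vector is always returned.
    """
    cfg = config or load_y_config()
    values: dict = {}
    for mname, m in cfg["markers"].items():
        region = m["region"]
        if region not in regions or regions[region] is None:
            values[mname] = None
            continue
        aligned = _aligned_string(regions[region])
        pos = int(m["position"])
        if m["type"] == "snp":
            values[mname] = _genotype_snp(aligned, pos)
        elif m["type"] == "microsatellite":
            values[mname] = _genotype_microsat(aligned, pos, m["unit"])
        else:
            values[mname] = _genotype_indel(aligned, pos, m["motif"])
    return YAlleleVector(**values)


def assign_y_haplogroup(vector: YAlleleVector, config: dict | None = None,
                        min_callable: int = 4) -> str:
    """Exact match of callable markers against the three haplogroup rows.

    Returns the haplogroup when exactly one row is consistent with every
    callable marker and at least ``min_callable`` markers are callable;
    otherwise "unassigned".  Marker evaluation order does not matter.
    """
    if vector.n_callable() < min_callable:
        return "unassigned"
    table = haplogroup_table(config)
    consistent = []
    for name, row in table.items():
        ok = True
        for m in MARKER_NAMES:
            v = getattr(vector, m)
            if v is None or v == "N":
                continue
            if v != row[m]:
                ok = False
                break
        if ok:
            consistent.append(name)
    return consistent[0] if len(consistent) == 1 else "unassigned"
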