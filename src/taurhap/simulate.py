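"""Synthetic ancient-DNA data: references, haplotypes, damaged reads, cohorts.

The simulator is the closed-loop counterpart of the analysis stages: it
generates a circular mitogenome-like reference, haplotype sequences carrying
diagnostic-panel alleles, and short sequencing reads bearing the canonical
post-mortem damage signature — an excess of C→T substitutions at 5' read ends
and the complementary G→A excess at 3' ends, produced by cytosine deamination
in single-stranded overhangs.  Damage follows the standard two-rate overhang
model: each fragment receives geometrically distributed single-stranded
overhangs at both termini; cytosines deaminate with probability ``delta_ss``
inside an overhang and ``delta_ds`` in the double-stranded core, after which
a uniform per-base sequencing error is applied.  Every introduced change is
recorded, so truth alignments are exact.

Fragment lengths are log-normal (location ``log(frag_mean)``, scale
``frag_sd``); fragment start positions are uniform on the circle and strands
are uniform.  Fragments longer than the genome are resampled, never emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from ._util import BASES, TRANSITION, TRANSVERSIONS, decode, derive_seed, encode, revcomp
from .panels import DiagnosticPanel, PanelSet
from .reference import ReferenceGenome

_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

# reads shorter than this are unusable for seed-based mapping and are resampled,
# mirroring the minimum-length cut applied to real aDNA libraries
MIN_FRAGMENT_LENGTH = 20

DEFAULT_QUALITY_CHAR = "I"  # Phred+33 Q40, fixed by default


class GenerationError(RuntimeError):
    """Raised when a requested synthetic construct cannot be generated."""


@dataclass(frozen=True)
class DamageParams:
    """Parameters of the ancient-read simulator (and targets for the profiler).

    overhang_p   geometric parameter of single-strand overhang length per terminus
                 (overhang length = geometric(overhang_p) - 1, support 0,1,2,...)
    delta_ss     C deamination probability in single-stranded overhangs
    delta_ds     C deamination probability in the double-stranded core
    frag_mean    log-normal location parameter, exp-scale (median length, bases)
    frag_sd      log-normal scale parameter (log-bases)
    seq_error    uniform per-base sequencing error rate
    coverage     target mean depth
    """

    overhang_p: float = 0.3
    delta_ss: float = 0.4
    delta_ds: float = 0.02
    frag_mean: float = 70.0
    frag_sd: float = 0.3
    seq_error: float = 0.001
    coverage: float = 30.0

    def __post_init__(self):
        for name in ("overhang_p", "delta_ss", "delta_ds", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.overhang_p <= 1.0:
            raise ValueError("overhang_p must be in (0,1]")
        if self.frag_mean <= 0:
            raise ValueError("frag_mean must be > 0")
        if self.frag_sd < 0:
            raise ValueError("frag_sd must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")

    @property
    def mean_fragment_length(self) -> float:
        """Mean of the log-normal length distribution (before truncation)."""
        return self.frag_mean * math.exp(self.frag_sd ** 2 / 2.0)

    def expected_terminal_ct(self) -> float:
        """Closed-form expected C→T rate at 5' read position 1.

        Position 1 lies in the 5' overhang unless the overhang has length 0,
        which happens with probability ``overhang_p``; sequencing error then
        perturbs the observed rate.
        """
        q = 1.0 - self.overhang_p
        deam = q * self.delta_ss + (1.0 - q) * self.delta_ds
        e = self.seq_error
        return deam * (1.0 - e) + (1.0 - deam) * (e / 3.0)


@dataclass(frozen=True)
class SimulatedRead:
    """A sequenced fragment with exact truth about its origin.

    ``sequence`` is the read as sequenced (5'→3'); ``source`` is the
    corresponding undamaged haplotype sequence in the same orientation.
    ``start`` is the 1-based leftmost haplotype coordinate of the fragment;
    ``changes`` records every position where sequence differs from source as
    (read_pos_1based, source_base, read_base, kind).
    """

    name: str
    sequence: str
    start: int
    strand: str           # '+' or '-'
    changes: tuple = ()
    quality: str = ""

    def __len__(self):
        return len(self.sequence)

    @property
    def source(self) -> str:
        src = list(self.sequence)
        for pos, frm, _to, _kind in self.changes:
            src[pos - 1] = frm
        return "".join(src)

    def oriented_sequences(self, ref=None):
        """(read, matching reference) both in sequencing orientation."""
        return self.sequence, self.source


@dataclass
class ReadSet:
    reads: list
    source_name: str
    source_length: int
    circular: bool
    params: DamageParams

    def __len__(self):
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)

    def mean_depth(self) -> float:
        return self.total_bases() / self.source_length


# ---------------------------------------------------------------------------
# reference and haplotype generation
# ---------------------------------------------------------------------------

def make_reference(length: int, gc: float, seed: int, name: str = "synthetic_mt",
                   circular: bool = True) -> ReferenceGenome:
    """Random reference with the given GC fraction; reproducible per seed."""
    if length < 1000:
        raise ValueError(f"reference length must be >= 1000, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    gchalf = gc / 2.0
    seq = "".join(rng.choice(list(BASES), size=length, p=[at, gchalf, gchalf, at]))
    return ReferenceGenome(name, seq, circular=circular)


def apply_panel_refs(ref: ReferenceGenome, panels: PanelSet):
    """Rewrite reference positions to the panels' expected ref alleles.

    Returns (possibly new reference, list of (position, old, new) rewrites).
    The generator calls this before building haplotypes so that panel ref
    alleles are guaranteed to match the reference.
    """
    rewrites = []
    seq = list(ref.sequence)
    for panel in panels:
        for v in panel.variants:
            i = (v.position - 1) % len(seq)
            if seq[i] != v.ref:
                rewrites.append((v.position, seq[i], v.ref))
                seq[i] = v.ref
    if not rewrites:
        return ref, []
    return ReferenceGenome(ref.name, "".join(seq), ref.circular), rewrites


def make_haplotype(ref: ReferenceGenome, panel, panels: PanelSet | None = None,
                   n_private: int = 0, seed: int = 0,
                   private_region: tuple | None = None) -> str:
    """Haplotype carrying a panel's derived alleles (plus ancestors) and
    ``n_private`` random non-panel substitutions.

    ``panel`` may be a label resolved in ``panels`` or a DiagnosticPanel.
    Private substitutions are drawn transition:transversion 2:1, restricted to
    ``private_region`` (1-based inclusive interval) when given, and never touch
    a diagnostic position of any loaded panel.
    """
    if isinstance(panel, str):
        if panels is None:
            raise ValueError("panel given as label but no PanelSet supplied")
        chain = panels.chain_variants(panel)
    elif isinstance(panel, DiagnosticPanel):
        chain = (list(panel.variants) + panels.chain_variants(panel.haplogroup)
                 if panels is not None and panel.haplogroup in panels
                 else list(panel.variants))
        # avoid double-count when the panel object is also in the set
        seen = set()
        chain = [v for v in chain if not (v.position in seen or seen.add(v.position))]
    else:
        raise TypeError(f"panel must be a label or DiagnosticPanel, got {type(panel)}")

    seq = list(ref.sequence)
    L = len(seq)
    for v in chain:
        i = (v.position - 1) % L
        if seq[i] != v.ref:
            raise GenerationError(
                f"reference base {seq[i]} at {v.position} does not match panel ref "
                f"{v.ref}; run apply_panel_refs first"
            )
        seq[i] = v.alt

    reserved = panels.all_positions() if panels is not None else {v.position for v in chain}
    reserved = {(p - 1) % L for p in reserved}
    if private_region is not None:
        lo, hi = private_region
        candidates = [i for i in range(lo - 1, hi) if i not in reserved]
    else:
        candidates = [i for i in range(L) if i not in reserved]
    if n_private > len(candidates):
        raise GenerationError(
            f"cannot place {n_private} private mutations in {len(candidates)} free positions"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_private, replace=False)
    for ci in sorted(int(c) for c in chosen):
        i = candidates[ci]
        base = seq[i]
        if rng.random() < 2.0 / 3.0:
            seq[i] = TRANSITION[base]
        else:
            seq[i] = TRANSVERSIONS[base][int(rng.integers(2))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _draw_lengths(rng, n, mu, sd, min_len, max_len):
    out = np.rint(rng.lognormal(mu, sd, n)).astype(np.int64)
    bad = (out < min_len) | (out > max_len)
    while bad.any():
        out[bad] = np.rint(rng.lognormal(mu, sd, int(bad.sum()))).astype(np.int64)
        bad = (out < min_len) | (out > max_len)
    return out


def simulate_reads(hap: str, params: DamageParams, seed: int,
                   circular: bool = True, name_prefix: str = "read",
                   source_name: str = "haplotype") -> ReadSet:
    """Simulate damaged reads from a haplotype at the target coverage.

    Fragments are drawn until the emitted bases reach ``coverage × length``,
    so the realised mean depth is within one fragment of the target.
    """
    L = len(hap)
    if L < MIN_FRAGMENT_LENGTH:
        raise ValueError("haplotype shorter than the minimum fragment length")
    codes = encode(hap)
    rng = np.random.default_rng(seed)
    mu, sd = math.log(params.frag_mean), params.frag_sd
    target = params.coverage * L

    mean_len = params.mean_fragment_length
    lengths = _draw_lengths(rng, max(int(target / mean_len * 1.02) + 8, 8),
                            mu, sd, MIN_FRAGMENT_LENGTH, L)
    while lengths.sum() < target:
        more = _draw_lengths(rng, max(len(lengths) // 10, 8), mu, sd,
                             MIN_FRAGMENT_LENGTH, L)
        lengths = np.concatenate([lengths, more])
    cut = int(np.searchsorted(np.cumsum(lengths), target, side="left"))
    lengths = lengths[:cut + 1]
    n = len(lengths)

    if circular:
        starts = rng.integers(1, L + 1, n)
    else:
        starts = rng.integers(0, L - lengths + 1) + 1
    strands = rng.integers(0, 2, n)          # 0 = plus, 1 = minus
    l5 = np.minimum(rng.geometric(params.overhang_p, n) - 1, lengths)
    l3 = np.minimum(rng.geometric(params.overhang_p, n) - 1, lengths)

    total = int(lengths.sum())
    offsets = np.cumsum(lengths) - lengths
    lens_rep = np.repeat(lengths, lengths)
    intra = np.arange(total, dtype=np.int64) - np.repeat(offsets, lengths)
    starts_rep = np.repeat(starts - 1, lengths)
    minus_rep = np.repeat(strands == 1, lengths)

    pos = starts_rep + np.where(minus_rep, lens_rep - 1 - intra, intra)
    if circular:
        pos %= L
    src = codes[pos]
    src = np.where(minus_rep, _COMP_CODE[src], src).astype(np.uint8)

    frag = src.copy()
    in5 = intra < np.repeat(l5, lengths)
    in3 = (lens_rep - 1 - intra) < np.repeat(l3, lengths)
    u = rng.random(total)
    rate_ct = np.where(in5, params.delta_ss, params.delta_ds)
    rate_ga = np.where(in3, params.delta_ss, params.delta_ds)
    ct = (frag == 1) & (u < rate_ct)   # C -> T
    ga = (frag == 2) & (u < rate_ga)   # G -> A (complementary-strand deamination)
    frag[ct] = 3
    frag[ga] = 0
    u2 = rng.random(total)
    err = u2 < params.seq_error
    n_err = int(err.sum())
    if n_err:
        frag[err] = (frag[err] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4

    diff_idx = np.flatnonzero(frag != src)
    # classify each realised change
    kinds = np.full(len(diff_idx), "", dtype=object)
    for j, i in enumerate(diff_idx):
        if err[i]:
            kinds[j] = "seqerr"
        elif ct[i]:
            kinds[j] = "deam_ss" if in5[i] else "deam_ds"
        else:
            kinds[j] = "deam_ss" if in3[i] else "deam_ds"

    bounds = np.concatenate([[0], np.cumsum(lengths)])
    read_of_change = np.searchsorted(bounds, diff_idx, side="right") - 1
    frag_bytes = decode(frag)
    src_bytes = decode(src)

    reads = []
    ci = 0
    for i in range(n):
        s, e = int(bounds[i]), int(bounds[i + 1])
        changes = []
        while ci < len(diff_idx) and read_of_change[ci] == i:
            gidx = int(diff_idx[ci])
            changes.append((gidx - s + 1, src_bytes[gidx], frag_bytes[gidx], kinds[ci]))
            ci += 1
        reads.append(SimulatedRead(
            name=f"{name_prefix}_{i:06d}",
            sequence=frag_bytes[s:e],
            start=int(starts[i]),
            strand="-" if strands[i] else "+",
            changes=tuple(changes),
            quality=DEFAULT_QUALITY_CHAR * (e - s),
        ))
    return ReadSet(reads=reads, source_name=source_name, source_length=L,
                   circular=circular, params=params)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRow:
    specimen_id: str
    haplogroup: str
    n_private: int = 3
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    rows: tuple

    def __post_init__(self):
        ids = [r.specimen_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("specimen ids must be unique")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


@dataclass
class CohortResult:
    reference: ReferenceGenome
    haplotypes: dict        # specimen_id -> haplotype sequence
    readsets: dict          # specimen_id -> ReadSet
    manifest: "object"      # pandas DataFrame: specimen_id, true_haplogroup, seed


def make_cohort(spec: CohortSpec, ref: ReferenceGenome, panels: PanelSet,
                params: DamageParams, seed: int,
                private_region: tuple | None = None) -> CohortResult:
    """Generate one read set per cohort row plus a truth manifest.

    Per-specimen randomness derives from the cohort seed and the row's own
    seed by stable hashing, so rows with the same haplogroup and row seed
    yield identical haplotypes and read sets, and any single row can be
    regenerated in isolation.
    """
    import pandas as pd

    for row in spec:
        if row.haplogroup not in panels:
            raise GenerationError(f"unknown haplogroup label {row.haplogroup!r} "
                                  f"for specimen {row.specimen_id}")
    ref, _rewrites = apply_panel_refs(ref, panels)
    haplotypes, readsets, rows = {}, {}, []
    for row in spec:
        hs = derive_seed(seed, "hap", row.haplogroup, row.seed, row.n_private)
        rs = derive_seed(seed, "reads", row.haplogroup, row.seed, row.n_private)
        hap = make_haplotype(ref, row.haplogroup, panels, n_private=row.n_private,
                             seed=hs, private_region=private_region)
        haplotypes[row.specimen_id] = hap
        readsets[row.specimen_id] = simulate_reads(
            hap, params, rs, circular=ref.circular,
            name_prefix=row.specimen_id, source_name=row.specimen_id)
        rows.append((row.specimen_id, row.haplogroup, row.seed))
    manifest = pd.DataFrame(rows, columns=["specimen_id", "true_haplogroup", "seed"])
    return CohortResult(reference=ref, haplotypes=haplotypes,
                        readsets=readsets, manifest=manifest)


def colonial_cohort_spec() -> CohortSpec:
    """Default 21-specimen cohort emulating the archaeological roster.

    Composition: 14 × T3, 6 × T1-family (4 T1a, 1 T1b, 1 T1d), 1 × T123.
    Three T3 specimens share one haplotype and two share another (row seeds
    101/102), giving 18 control-region haplotypes with multiplicity profile
    {3, 2, 1×16} among the 21 sequences.  Specimen names echo the
    archaeological sites; the sequences are synthetic.
    """
    rows = [
        CohortRow("PuertoReal2", "T3", 3, 1),
        CohortRow("PuertoReal4", "T3", 3, 2),
        CohortRow("PuertoReal5", "T3", 2, 102),
        CohortRow("PuertoReal6", "T3", 2, 101),
        CohortRow("PuertoReal7", "T3", 3, 3),
        CohortRow("PuertoReal8", "T3", 2, 102),
        CohortRow("PuertoReal9", "T3", 3, 4),
        CohortRow("Merida11", "T3", 2, 101),
        CohortRow("Merida12", "T3", 3, 5),
        CohortRow("Merida13", "T123", 3, 6),
        CohortRow("Merida14", "T1a", 3, 7),
        CohortRow("Merida15", "T1a", 3, 8),
        CohortRow("Merida16", "T1d", 3, 9),
        CohortRow("Xochimilco17", "T3", 2, 101),
        CohortRow("Xochimilco18", "T3", 3, 10),
        CohortRow("JustoSierra19", "T1a", 3, 11),
        CohortRow("JustoSierra20", "T1a", 3, 12),
        CohortRow("JustoSierra21", "T3", 3, 13),
        CohortRow("BellasArtes22", "T3", 3, 14),
        CohortRow("BellasArtes23", "T3", 3, 15),
        CohortRow("BellasArtes24", "T1b", 3, 16),
    ]
    return CohortSpec(tuple(rows))


DEFAULT_REFERENCE_LENGTH = 16338
DEFAULT_GC = 0.4
DLOOP_LENGTH = 700


def dloop_region(ref_length: int = DEFAULT_REFERENCE_LENGTH,
                 length: int = DLOOP_LENGTH) -> tuple:
    """Default control-region window: the last ``length`` bases (1-based)."""
    return (ref_length - length + 1, ref_length)


# ---------------------------------------------------------------------------
# Y-chromosome intron regions (synthetic stand-ins)
# ---------------------------------------------------------------------------

def load_y_config(path: str | Path | None = None) -> dict:
    if path is None:
        path = Path(__file__).parent / "data" / "y_markers.yaml"
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)


def make_y_regions(seed: int = 0, config: dict | None = None) -> dict:
    """Synthetic Y intron references carrying the Y2 allele states.

    The five regions are synthetic stand-ins for the GenBank intron sequences;
    lengths sum to 3,169 bp and the marker anchors sit at the published
    footnote coordinates.  The reference frame carries the Y2 states (SNP
    bases, (AT)×10 microsatellite, GT insertion present).
    """
    cfg = config or load_y_config()
    rng = np.random.default_rng(seed)
    regions = {}
    y2 = cfg["haplogroups"]["Y2"]
    for name, rspec in cfg["regions"].items():
        L = int(rspec["length"])
        seq = list(rng.choice(list(BASES), size=L))
        for mname, m in cfg["markers"].items():
            if m["region"] != name:
                continue
            p = int(m["position"])
            if m["type"] == "snp":
                seq[p - 1] = str(y2[mname])
            elif m["type"] == "microsatellite":
                unit = m["unit"]
                reps = int(y2[mname])
                run = unit * reps
                seq[p - 1:p - 1 + len(run)] = list(run)
                # guard bases so the maximal run is exactly `reps` units
                if p - 2 >= 0:
                    seq[p - 2] = "C"
                if p - 1 + len(run) < L:
                    seq[p - 1 + len(run)] = "C"
                if p + len(run) < L:
                    seq[p + len(run)] = "C"
            elif m["type"] == "indel":
                motif = m["motif"]
                seq[p - 1:p - 1 + len(motif)] = list(motif)
                # guard bases: deletion placement must be unambiguous
                if p - 2 >= 0:
                    seq[p - 2] = "A"
                if p - 1 + len(motif) < L:
                    seq[p - 1 + len(motif)] = "C"
        regions[name] = ReferenceGenome(name, "".join(seq), circular=False)
    return regions


def make_y_haplotype(regions: dict, haplogroup: str,
                     config: dict | None = None) -> dict:
    """Region sequences (actual molecules) for a Y haplogroup.

    Edits relative to the Y2-state reference frame are applied right-to-left
    so earlier coordinates stay valid when the microsatellite contracts or
    the indel is deleted.
    """
    cfg = config or load_y_config()
    if haplogroup not in cfg["haplogroups"]:
        raise GenerationError(f"unknown Y haplogroup {haplogroup!r}")
    states = cfg["haplogroups"][haplogroup]
    out = {}
    for name, ref in regions.items():
        edits = []  # (position, kind, payload)
        for mname, m in cfg["markers"].items():
            if m["region"] != name:
                continue
            p = int(m["position"])
            if m["type"] == "snp":
                edits.append((p, "snp", str(states[mname])))
            elif m["type"] == "microsatellite":
                edits.append((p, "microsat", (m["unit"], int(states[mname]),
                                              int(cfg["haplogroups"]["Y2"][mname]))))
            elif m["type"] == "indel":
                edits.append((p, "indel", (m["motif"], str(states[mname]))))
        seq = list(ref.sequence)
        for p, kind, payload in sorted(edits, reverse=True):
            if kind == "snp":
                seq[p - 1] = payload
            elif kind == "microsat":
                unit, reps, ref_reps = payload
                seq[p - 1:p - 1 + len(unit) * ref_reps] = list(unit * reps)
            elif kind == "indel":
                motif, state = payload
                if state == "absent":
                    del seq[p - 1:p - 1 + len(motif)]
        out[name] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(records: dict, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in readset:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list:
    """Read FASTQ into (name, sequence, quality) tuples via Biopython."""
    from Bio import SeqIO
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def _md_and_nm(read: str, ref: str):
    nm = 0
    md = []
    run = 0
    for rb, fb in zip(read, ref):
        if rb == fb:
            run += 1
        else:
            md.append(str(run))
            md.append(fb)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def write_truth_sam(readset: ReadSet, path: str | Path) -> None:
    """Truth alignments as SAM (soft-clip-free, NM/MD set).

    Reads crossing the circular origin keep their full-length CIGAR with POS
    at the wrap start; a ``ZC:i:1`` tag marks them.  ``ZK`` carries the
    introduced-change records as pos:from:to:kind items.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": readset.source_name, "LN": readset.source_length}],
    })
    L = readset.source_length
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in readset:
            a = pysam.AlignedSegment(header)
            a.query_name = r.name
            minus = r.strand == "-"
            a.flag = 16 if minus else 0
            seq_ref_orient = revcomp(r.sequence) if minus else r.sequence
            src_ref_orient = revcomp(r.source) if minus else r.source
            a.query_sequence = seq_ref_orient
            a.query_qualities = pysam.qualitystring_to_array(r.quality)
            a.reference_id = 0
            a.reference_start = r.start - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(r)}M"
            md, nm = _md_and_nm(seq_ref_orient, src_ref_orient)
            a.set_tag("NM", nm)
            a.set_tag("MD", md)
            if r.start + len(r) - 1 > L:
                a.set_tag("ZC", 1)
            if r.changes:
                a.set_tag("ZK", ";".join(f"{p}:{f}:{t}:{k}" for p, f, t, k in r.changes))
            fh.write(a)


def write_manifest(result: CohortResult, path: str | Path) -> None:
    result.manifest.to_csv(str(path), sep="\t", index=False)
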