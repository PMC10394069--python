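"""Read mapping to a circular reference, filtering, deduplication, pileups.

The mapper is a documented seed-and-extend replacement for the proprietary
mapper used interactively in aDNA workflows: exact k-mer seeding on both
strands against the doubled circular sequence, an ungapped fast path, and a
banded gapped extension (match +1, mismatch -1, gap -2, band 16) when the
ungapped alignment shows two or more mismatches (with at most one mismatch
the ungapped alignment is provably optimal under this scoring, since any
alignment containing a gap column scores at most read_length - 2).
``mapq_proxy`` is an explicit, reproducible stand-in for mapper-specific
mapping quality: 60 for a unique candidate location, otherwise
``min(60, 4 * (best - second_best))``.

Filter defaults keep the published thresholds: mapping quality >= 30, at most
5% mismatched columns and at most 5% gap columns per mapped read, all bounds
inclusive.  Duplicates are alignments sharing start, end and strand; the
highest-scoring one is kept.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from ._util import encode, revcomp
from .reference import ReferenceGenome

_BAND = 16  # total band width for the gapped extension

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=False)
def _banded_dp(read, ref, half):  # pragma: no cover - exercised via wrapper
    """Banded alignment, read global, ref anchored at window start, free ref end.

    Returns (score, end_j, pointer matrix) with pointers 0=diag,1=up(read gap
    consumed, insertion),2=left(deletion).
    """
    n = read.shape[0]
    m = ref.shape[0]
    NEG = -10**9
    width = 2 * half + 1
    # D[i, d] with d = j - i + half, j in [i-half, i+half]
    D = np.full((n + 1, width), NEG, dtype=np.int64)
    P = np.zeros((n + 1, width), dtype=np.uint8)
    for d in range(half, width):        # row 0: leading deletions
        j = d - half
        if j <= m:
            D[0, d] = -2 * j
            P[0, d] = 2
    for i in range(1, n + 1):
        lo = i - half
        if lo < 0:
            lo = 0
        hi = i + half
        if hi > m:
            hi = m
        for j in range(lo, hi + 1):
            d = j - i + half
            best = NEG
            ptr = 0
            if j >= 1:
                diag = D[i - 1, d]
                if diag > NEG:
                    s = diag + (1 if read[i - 1] == ref[j - 1] else -1)
                    if s > best:
                        best = s
                        ptr = 0
            if d + 1 < width:           # up: consume read base, gap in ref
                up = D[i - 1, d + 1]
                if up > NEG and up - 2 > best:
                    best = up - 2
                    ptr = 1
            if d - 1 >= 0 and j >= 1:   # left: consume ref base, gap in read
                left = D[i, d - 1]
                if left > NEG and left - 2 > best:
                    best = left - 2
                    ptr = 2
            D[i, d] = best
            P[i, d] = ptr
    # free ref suffix: best cell in last row
    best = NEG
    bestd = half
    for d in range(width):
        if D[n, d] > best:
            best = D[n, d]
            bestd = d
    return best, bestd - half + n, P


def _banded_align(read_codes: np.ndarray, ref_codes: np.ndarray, band: int = _BAND):
    """Run the banded DP and trace back a CIGAR.

    Returns (score, cigar list of (op,length), n_mismatch, n_gap_columns,
    ref_span).
    """
    half = band // 2
    score, end_j, P = _banded_dp(read_codes.astype(np.int64),
                                 ref_codes.astype(np.int64), half)
    n = len(read_codes)
    ops = []
    i, j = n, end_j
    nm = 0
    gaps = 0
    while i > 0 or j > 0:
        d = j - i + half
        ptr = P[i, d] if 0 <= d < 2 * half + 1 else 0
        if i > 0 and j > 0 and ptr == 0:
            ops.append("M")
            if read_codes[i - 1] != ref_codes[j - 1]:
                nm += 1
            i -= 1
            j -= 1
        elif i > 0 and ptr == 1:
            ops.append("I")
            gaps += 1
            i -= 1
        else:
            ops.append("D")
            gaps += 1
            j -= 1
    ops.reverse()
    cigar = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += 1
        else:
            cigar.append([op, 1])
    return int(score), [(op, ln) for op, ln in cigar], nm, gaps, end_j


def _left_align_gaps(cigar, read_seq, ref, ref_start):
    """Shift gap runs leftward where the alignment score is unchanged.

    Inside tandem repeats the placement of an indel is degenerate; pushing
    every gap as far left as possible makes co-optimal alignments from
    different reads agree, so pileup deletion alleles stack at one position.
    """
    cols = []
    for op, ln in cigar:
        cols.extend(op * ln)
    changed = True
    while changed:
        changed = False
        # per-column read/ref indices (0-based read offset, 1-based ref pos)
        rpos, gpos = 0, ref_start
        coords = []
        for op in cols:
            coords.append((rpos, gpos))
            if op == "M":
                rpos += 1
                gpos += 1
            elif op == "I":
                rpos += 1
            else:
                gpos += 1
        i = 1
        while i < len(cols):
            if cols[i] in "DI" and cols[i - 1] == "M":
                j = i
                while j < len(cols) and cols[j] == cols[i]:
                    j += 1
                d = j - i
                r_prev, g_prev = coords[i - 1]
                if cols[i] == "D":
                    ok = (ref.circular or g_prev + d <= len(ref)) and \
                        ref.base(g_prev) == ref.base(g_prev + d)
                else:
                    ok = (r_prev + d < len(read_seq)
                          and read_seq[r_prev] == read_seq[r_prev + d])
                if ok:
                    cols[i - 1:j] = cols[i:j] + ["M"]
                    changed = True
                    break   # coords are stale after a shift; rescan
                i = j
            else:
                i += 1
    out = []
    for op in cols:
        if out and out[-1][0] == op:
            out[-1][1] += 1
        else:
            out.append([op, 1])
    return [(op, ln) for op, ln in out]


@dataclass
class ReadAlignment:
    """A read placed on the reference (reference orientation).

    ``read_seq`` is the read in reference orientation (reverse-complemented
    for minus-strand alignments); ``ref_start`` is 1-based and alignments may
    run past the circular origin (``ref_end`` > reference length means wrap).
    """

    read_id: str
    ref_start: int
    strand: str
    read_seq: str
    cigar: list
    n_mismatch: int
    n_gap_columns: int
    aln_length: int
    map_score: int
    mapq_proxy: int

    @property
    def ref_span(self) -> int:
        return sum(ln for op, ln in self.cigar if op in ("M", "D"))

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span - 1

    def coordinate_key(self, ref_length: int):
        end = (self.ref_end - 1) % ref_length + 1
        return (self.ref_start, end, self.strand)

    def aligned_pairs(self, ref: ReferenceGenome):
        """Yield (read_base | None, ref_base | None) per alignment column."""
        rpos = 0
        gpos = self.ref_start
        for op, ln in self.cigar:
            for _ in range(ln):
                if op == "M":
                    yield self.read_seq[rpos], ref.base(gpos)
                    rpos += 1
                    gpos += 1
                elif op == "I":
                    yield self.read_seq[rpos], None
                    rpos += 1
                else:
                    yield None, ref.base(gpos)
                    gpos += 1

    def oriented_sequences(self, ref: ReferenceGenome):
        """(read, reference) over match columns, in sequencing orientation.

        Gap columns are skipped; with the short, indel-poor fragments this
        profiler targets, the terminal-distance shift this introduces is
        negligible.
        """
        rs, fs = [], []
        for rb, fb in self.aligned_pairs(ref):
            if rb is not None and fb is not None:
                rs.append(rb)
                fs.append(fb)
        read = "".join(rs)
        refs = "".join(fs)
        if self.strand == "-":
            return revcomp(read), revcomp(refs)
        return read, refs


@dataclass
class MappingResult:
    alignments: list
    unmapped: list          # read ids with no seed hit / no viable candidate

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self):
        return len(self.alignments)


def _normalize_read(item):
    if hasattr(item, "name") and hasattr(item, "sequence"):
        return item.name, item.sequence
    if isinstance(item, (tuple, list)):
        return item[0], item[1]
    raise TypeError(f"cannot interpret read record {item!r}")


def build_kmer_index(ref: ReferenceGenome, k: int) -> dict:
    seq = ref.doubled()
    L = len(ref)
    limit = L if ref.circular else L - k + 1
    index = defaultdict(list)
    for i in range(limit):
        index[seq[i:i + k]].append(i)
    return dict(index)


def map_reads(reads, ref: ReferenceGenome, k: int = 13, band: int = _BAND,
              keep_secondary: bool = False, index: dict | None = None) -> MappingResult:
    """Map reads by exact k-mer seeding plus (banded) extension.

    Reads with no seed hit on either strand are reported in the unmapped set.
    With ``keep_secondary`` every evaluated candidate location is returned
    (secondary alignments carry mapq_proxy 0).
    """
    if k < 8:
        raise ValueError(f"seed length k must be >= 8, got {k}")
    reads = list(reads)
    if not reads:
        raise ValueError("reads must be nonempty")
    L = len(ref)
    if index is None:
        index = build_kmer_index(ref, k)
    dbl = encode(ref.doubled())

    alignments = []
    unmapped = []
    for item in reads:
        name, seq = _normalize_read(item)
        n = len(seq)
        if n < k or n > L:
            unmapped.append(name)
            continue
        offsets = sorted({0, (n - k) // 2, n - k})
        candidates = []     # (start0, strand, oriented read string)
        seen = set()
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for off in offsets:
                for pos in index.get(oriented[off:off + k], ()):
                    s = pos - off
                    if ref.circular:
                        s %= L
                    elif s < 0 or s + n > L:
                        continue
                    if (s, strand) not in seen:
                        seen.add((s, strand))
                        candidates.append((s, strand, oriented))
        if not candidates:
            unmapped.append(name)
            continue

        scored = []
        for s, strand, oriented in candidates:
            rcodes = encode(oriented)
            window = dbl[s:s + n]
            m = int(np.count_nonzero(window != rcodes))
            if m <= 1:
                scored.append((n - 2 * m, s, strand, oriented,
                               [("M", n)], m, 0, n))
            else:
                avail = len(dbl) - s if ref.circular else L - s
                wlen = min(n + band // 2, avail)
                score, cigar, nm, gaps, _span = _banded_align(
                    rcodes, dbl[s:s + wlen], band)
                if gaps:
                    cigar = _left_align_gaps(cigar, oriented, ref, s + 1)
                aln_len = sum(ln for _op, ln in cigar)
                scored.append((score, s, strand, oriented, cigar, nm, gaps, aln_len))

        scored.sort(key=lambda t: (-t[0], t[2] == "-", t[1]))
        best = scored[0]
        if len(scored) == 1:
            mapq = 60
        else:
            mapq = min(60, 4 * (best[0] - scored[1][0]))
        emit = scored if keep_secondary else [best]
        for rank, (score, s, strand, oriented, cigar, nm, gaps, aln_len) in enumerate(emit):
            alignments.append(ReadAlignment(
                read_id=name, ref_start=s + 1, strand=strand, read_seq=oriented,
                cigar=cigar, n_mismatch=nm, n_gap_columns=gaps,
                aln_length=aln_len, map_score=score,
                mapq_proxy=mapq if rank == 0 else 0))
    return MappingResult(alignments=alignments, unmapped=unmapped)


def filter_alignments(alns, max_mismatch_frac: float = 0.05,
                      max_gap_frac: float = 0.05, min_mapq: int = 30) -> list:
    """Apply the published alignment filters (inclusive bounds), preserving order."""
    for frac in (max_mismatch_frac, max_gap_frac):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fractions must be in [0,1], got {frac}")
    out = []
    for a in alns:
        if a.aln_length == 0:
            continue
        if (a.n_mismatch / a.aln_length <= max_mismatch_frac
                and a.n_gap_columns / a.aln_length <= max_gap_frac
                and a.mapq_proxy >= min_mapq):
            out.append(a)
    return out


def deduplicate(alns, ref_length: int | None = None) -> list:
    """Keep one alignment per (start, end, strand); highest score wins, ties
    go to the lexicographically smallest read id.  Order of survivors follows
    first occurrence of each coordinate group."""
    alns = list(alns)
    if not alns:
        return []
    if ref_length is None:
        ref_length = max(a.ref_end for a in alns)
    best = {}
    order = []
    for a in alns:
        key = a.coordinate_key(ref_length)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.map_score, ) > (b.map_score, ) or \
               (a.map_score == b.map_score and a.read_id < b.read_id):
                best[key] = a
    return [best[k] for k in order]


@dataclass
class Pileup:
    """Per-position base/deletion counts over the reference.

    ``counts`` has shape (L, 5) with columns A, C, G, T, deletion; insertions
    are tracked separately, keyed by the 1-based position they follow.
    """

    counts: np.ndarray
    insertions: dict
    ref_name: str
    ref_length: int

    COLUMNS = ("A", "C", "G", "T", "del")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.counts, columns=list(self.COLUMNS))
        df.insert(0, "pos", np.arange(1, self.ref_length + 1))
        df["depth"] = self.depth
        df.to_csv(str(path), sep="\t", index=False)


def build_pileup(alns, ref: ReferenceGenome) -> Pileup:
    L = len(ref)
    counts = np.zeros((L, 5), dtype=np.int32)
    insertions = defaultdict(Counter)
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a in alns:
        rpos = 0
        gpos0 = a.ref_start - 1       # 0-based, may exceed L before wrap
        for op, ln in a.cigar:
            if op == "M":
                idx = (gpos0 + np.arange(ln)) % L
                seg = encode(a.read_seq[rpos:rpos + ln])
                valid = seg < 4
                np.add.at(counts, (idx[valid], seg[valid]), 1)
                rpos += ln
                gpos0 += ln
            elif op == "D":
                idx = (gpos0 + np.arange(ln)) % L
                np.add.at(counts, (idx, np.full(ln, 4)), 1)
                gpos0 += ln
            else:  # insertion: keyed by the position it follows
                key = (gpos0 - 1) % L + 1
                insertions[key][a.read_seq[rpos:rpos + ln]] += 1
                rpos += ln
    return Pileup(counts=counts, insertions=dict(insertions),
                  ref_name=ref.name, ref_length=L)


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def _md_tag(aln: ReadAlignment, ref: ReferenceGenome) -> str:
    md = []
    run = 0
    rpos = 0
    gpos = aln.ref_start
    for op, ln in aln.cigar:
        if op == "M":
            for _ in range(ln):
                rb, fb = aln.read_seq[rpos], ref.base(gpos)
                if rb == fb:
                    run += 1
                else:
                    md.append(str(run))
                    md.append(fb)
                    run = 0
                rpos += 1
                gpos += 1
        elif op == "D":
            md.append(str(run))
            run = 0
            md.append("^" + "".join(ref.base(gpos + i) for i in range(ln)))
            gpos += ln
        else:
            rpos += ln
    md.append(str(run))
    return "".join(md)


def write_sam(alns, ref: ReferenceGenome, path: str | Path) -> None:
    """Write alignments as SAM with NM and MD tags (wrapping reads keep their
    full CIGAR with a ZC:i:1 marker)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alns:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.query_sequence = a.read_seq
            seg.reference_id = 0
            seg.reference_start = a.ref_start - 1
            seg.mapping_quality = a.mapq_proxy
            seg.cigarstring = "".join(f"{ln}{op}" for op, ln in a.cigar)
            seg.set_tag("NM", a.n_mismatch + a.n_gap_columns)
            seg.set_tag("AS", a.map_score)
            if a.ref_end > len(ref):
                seg.set_tag("ZC", 1)
            fh.write(seg)


def read_sam(path: str | Path, ref: ReferenceGenome) -> list:
    """Load alignments from SAM, recomputing per-alignment statistics."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            cigar = []
            for op, ln in seg.cigartuples:
                sym = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}.get(op)
                if sym is None:
                    raise ValueError(f"unsupported CIGAR op {op} in {path}")
                cigar.append((sym, ln))
            a = ReadAlignment(
                read_id=seg.query_name,
                ref_start=seg.reference_start + 1,
                strand="-" if seg.is_reverse else "+",
                read_seq=seg.query_sequence.upper(),
                cigar=cigar, n_mismatch=0, n_gap_columns=0, aln_length=0,
                map_score=seg.get_tag("AS") if seg.has_tag("AS") else 0,
                mapq_proxy=seg.mapping_quality)
            nm = gaps = cols = 0
            for rb, fb in a.aligned_pairs(ref):
                cols += 1
                if rb is None or fb is None:
                    gaps += 1
                elif rb != fb:
                    nm += 1
            a.n_mismatch, a.n_gap_columns, a.aln_length = nm, gaps, cols
            if not seg.has_tag("AS"):
                a.map_score = (cols - gaps - nm) - nm - 2 * gaps
            out.append(a)
    return out
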