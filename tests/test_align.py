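"""Mapper, filters, deduplication and pileup contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taurhap import (DamageParams, ReadAlignment, build_pileup, deduplicate,
                     filter_alignments, map_reads, simulate_reads)
from taurhap._util import revcomp
from taurhap.reference import ReferenceGenome


def _aln(read_id="r", ref_start=1, strand="+", n=100, nm=0, gaps=0,
         mapq=60, score=None):
    return ReadAlignment(
        read_id=read_id, ref_start=ref_start, strand=strand,
        read_seq="A" * n, cigar=[("M", n)], n_mismatch=nm,
        n_gap_columns=gaps, aln_length=n,
        map_score=score if score is not None else n - 2 * nm, mapq_proxy=mapq)


# ---------------------------------------------------------------------------
# independent oracle: full (unbanded) DP, read-global, start-anchored,
# free reference suffix, scored +1/-1/-2, over every offset and strand
# ---------------------------------------------------------------------------

def _oracle_score(read, window):
    n, m = len(read), len(window)
    NEG = -(10 ** 9)
    prev = [0] + [-2 * j for j in range(1, m + 1)]
    for i in range(1, n + 1):
        cur = [NEG] * (m + 1)
        cur[0] = prev[0] - 2
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1 if read[i - 1] == window[j - 1] else -1)
            cur[j] = max(diag, prev[j] - 2, cur[j - 1] - 2)
        prev = cur
    return max(prev)


def _oracle_best(read, ref):
    dbl = ref.doubled()
    L = len(ref)
    best = None
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        for s in range(L):
            window = dbl[s:s + min(len(read) + 8, 2 * L - s)]
            if len(window) < len(read) - 8:
                continue
            sc = _oracle_score(oriented, window)
            if best is None or sc > best[0]:
                best = (sc, s + 1, strand)
    return best


class TestMapReads:
    def test_exact_substring_maps_perfectly(self, mini_ref):
        p = 501
        read = mini_ref.fetch(p, 60)
        res = map_reads([("r1", read)], mini_ref, k=13)
        (a,) = res.alignments
        assert (a.ref_start, a.n_mismatch, a.mapq_proxy) == (p, 0, 60)
        assert a.strand == "+" and a.map_score == 60

    def test_read_spanning_origin_wraps(self, mini_ref):
        # oracle: the same read maps without wrap on a rotated linearisation
        start = len(mini_ref) - 29
        read = mini_ref.fetch(start, 60)
        res = map_reads([("r1", read)], mini_ref, k=13)
        (a,) = res.alignments
        assert a.ref_start == start and a.ref_end == start + 59
        rot = ReferenceGenome("rot", mini_ref.sequence[1000:] +
                              mini_ref.sequence[:1000], circular=False)
        res2 = map_reads([("r1", read)], rot, k=13)
        (b,) = res2.alignments
        assert b.ref_start == start - 1000 and b.n_mismatch == 0

    def test_reverse_complement_maps_minus_same_interval(self, mini_ref):
        read = mini_ref.fetch(700, 60)
        res = map_reads([("f", read), ("r", revcomp(read))], mini_ref, k=13)
        fwd, rev = res.alignments
        assert (fwd.ref_start, fwd.strand) == (700, "+")
        assert (rev.ref_start, rev.strand) == (700, "-")
        assert rev.n_mismatch == 0

    def test_no_seed_hit_reported_unmapped(self, mini_ref):
        res = map_reads([("junk", "ACGT" * 10), ("ok", mini_ref.fetch(5, 40))],
                        mini_ref, k=13)
        assert "ok" not in res.unmapped
        # a random 40-mer almost surely shares no 13-mer with the reference
        assert res.unmapped == ["junk"] or len(res.alignments) == 2

    def test_deletion_read_gets_gapped_cigar(self, mini_ref):
        whole = mini_ref.fetch(301, 63)
        read = whole[:30] + whole[33:]       # 3-base deletion
        res = map_reads([("d", read)], mini_ref, k=13)
        (a,) = res.alignments
        assert a.n_gap_columns == 3
        assert sum(ln for op, ln in a.cigar if op == "D") == 3
        assert a.ref_span == 63

    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=180))
        ref = ReferenceGenome("t", seq, circular=True)
        reads = []
        for i in range(25):
            start = int(rng.integers(0, 180))
            ln = int(rng.integers(30, 45))
            read = (seq * 2)[start:start + ln]
            read = list(read)
            for _ in range(int(rng.integers(0, 3))):   # up to 2 substitutions
                j = int(rng.integers(0, ln))
                read[j] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append((f"r{i}", read))
        res = map_reads(reads, ref, k=8)
        by_id = {a.read_id: a for a in res.alignments}
        for name, read in reads:
            if name not in by_id:
                continue
            oracle_score, _s, _strand = _oracle_best(read, ref)
            assert by_id[name].map_score == oracle_score, name

    def test_short_or_empty_inputs(self, mini_ref):
        with pytest.raises(ValueError):
            map_reads([], mini_ref)
        with pytest.raises(ValueError):
            map_reads([("r", "ACGTACGTAA")], mini_ref, k=7)


class TestFilterAlignments:
    def test_published_thresholds_boundary(self):
        removed = _aln(nm=6)                      # 6% mismatch
        kept = _aln(nm=5)                         # exactly 5%: inclusive
        low_mapq = _aln(mapq=29)                  # below minimum 30
        out = filter_alignments([removed, kept, low_mapq])
        assert out == [kept]

    def test_gap_fraction_boundary(self):
        gap_ok = _aln(gaps=5)
        gap_bad = _aln(gaps=6)
        assert filter_alignments([gap_ok, gap_bad]) == [gap_ok]

    def test_empty_in_empty_out(self):
        assert filter_alignments([]) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10),
                              st.integers(0, 60)), max_size=12))
    def test_idempotent_and_order_preserving(self, rows):
        alns = [_aln(read_id=f"r{i}", nm=nm, gaps=g, mapq=q)
                for i, (nm, g, q) in enumerate(rows)]
        once = filter_alignments(alns)
        assert filter_alignments(once) == once
        ids = [a.read_id for a in alns]
        assert [a.read_id for a in once] == [i for i in ids
                                             if any(a.read_id == i for a in once)]


class TestDeduplicate:
    def test_identical_coordinates_single_survivor(self):
        a, b = _aln("a"), _aln("b")
        assert deduplicate([a, b], ref_length=1000) == [a]

    def test_opposite_strands_both_kept(self):
        a, b = _aln("a", strand="+"), _aln("b", strand="-")
        assert len(deduplicate([a, b], ref_length=1000)) == 2

    def test_five_copies_plus_one_distinct(self):
        copies = [_aln(f"c{i}") for i in range(5)]
        distinct = _aln("d", ref_start=50)
        out = deduplicate(copies + [distinct], ref_length=1000)
        # brute-force grouping: two (start, end, strand) classes
        assert len(out) == 2
        assert distinct in out

    def test_highest_score_then_lexicographic_id(self):
        worse = _aln("a", score=50)
        better = _aln("z", score=55)
        assert deduplicate([worse, better], ref_length=1000) == [better]
        tie1, tie2 = _aln("b", score=50), _aln("a", score=50)
        assert deduplicate([tie1, tie2], ref_length=1000) == [tie2]


class TestPileup:
    def test_single_perfect_read(self, mini_ref):
        res = map_reads([("r", mini_ref.fetch(1, 60))], mini_ref, k=13)
        pu = build_pileup(res.alignments, mini_ref)
        assert pu.depth[:60].tolist() == [1] * 60
        assert pu.depth[60:].sum() == 0

    def test_depth_conservation(self, mini_ref):
        rs = simulate_reads(mini_ref.sequence, DamageParams(coverage=5), seed=4)
        res = map_reads(rs, mini_ref, k=13)
        pu = build_pileup(res.alignments, mini_ref)
        covered = sum(a.ref_span - sum(ln for op, ln in a.cigar if op == "D")
                      for a in res.alignments)
        assert pu.counts[:, :4].sum() == covered

    def test_simulated_30x_mean_depth(self, mini_ref):
        params = DamageParams(delta_ss=0, delta_ds=0, seq_error=0, coverage=30)
        rs = simulate_reads(mini_ref.sequence, params, seed=12)
        res = map_reads(rs, mini_ref, k=13)
        pu = build_pileup(res.alignments, mini_ref)
        assert abs(pu.mean_depth() - 30) <= 3

    def test_mismatch_split_counts(self, mini_ref):
        good = mini_ref.fetch(101, 60)
        bad = list(good)
        idx = 30
        bad[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[idx]]
        res = map_reads([("g", good), ("b", "".join(bad))], mini_ref, k=13)
        pu = build_pileup(res.alignments, mini_ref)
        pos = 101 + idx - 1
        assert pu.depth[pos] == 2
        assert (pu.counts[pos] > 0).sum() == 2
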