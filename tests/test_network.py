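"""Haplotype collapsing, minimum spanning networks, median joining."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taurhap import (collapse_haplotypes, make_haplotype, median_joining,
                     minimum_spanning_network, total_network_length)
from taurhap.network import EmptyAlignmentError, _majority_median


def _ham(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestCollapse:
    def test_multiplicity_profile(self):
        """A 21-sequence alignment built to the {3,2,1x16} profile collapses
        to 18 haplotypes."""
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=50))
        distinct = []
        for i in range(18):
            s = list(base)
            s[2 * i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[2 * i]]
            distinct.append("".join(s))
        seqs = {}
        for rep in range(3):
            seqs[f"trip{rep}"] = distinct[0]
        for rep in range(2):
            seqs[f"pair{rep}"] = distinct[1]
        for i in range(16):
            seqs[f"solo{i}"] = distinct[2 + i]
        table = collapse_haplotypes(seqs)
        assert len(table) == 18
        assert sorted(table.multiplicity, reverse=True) == [3, 2] + [1] * 16
        assert table.n_sequences == 21

    def test_identical_sequences_single_haplotype(self):
        table = collapse_haplotypes({f"s{i}": "ACGTACGT" for i in range(5)})
        assert len(table) == 1 and table.multiplicity == [5]

    def test_n_column_excluded_before_grouping(self):
        seqs = {"a": "ANCG", "b": "AACG", "c": "AACG"}
        table = collapse_haplotypes(seqs)
        assert table.dropped_columns == [2]
        assert len(table) == 1          # differ only at the dropped column

    def test_region_restriction(self):
        seqs = {"a": "AAAATTTT", "b": "CCCCTTTT"}
        table = collapse_haplotypes(seqs, region=(5, 8))
        assert len(table) == 1
        assert table.included_sites == [5, 6, 7, 8]

    def test_all_columns_dropped_raises(self):
        with pytest.raises(EmptyAlignmentError):
            collapse_haplotypes({"a": "NNN", "b": "AAA"})

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6),
                    min_size=1, max_size=10))
    def test_multiplicities_sum_to_input(self, seqs):
        table = collapse_haplotypes({f"s{i}": s for i, s in enumerate(seqs)})
        assert sum(table.multiplicity) == len(seqs)
        assert len(set(table.sequences)) == len(table)


class TestMSN:
    def test_two_haplotypes_single_edge(self):
        t = collapse_haplotypes({"a": "AAAT", "b": "TTTT"})
        G = minimum_spanning_network(t)
        assert [(u, v, d["weight"]) for u, v, d in G.edges(data=True)] == \
            [("H01", "H02", 3)]

    def test_equidistant_triple_keeps_all_tied_edges(self):
        # brute force: all three d=2 edges join distinct components
        t = collapse_haplotypes({"s1": "AAA", "s2": "TTA", "s3": "TAT"})
        G = minimum_spanning_network(t)
        assert G.number_of_edges() == 3
        assert all(d["weight"] == 2 for _u, _v, d in G.edges(data=True))

    def test_tree_like_data_matches_mst_oracle(self):
        """Without ties or homoplasy the MSN is a tree of the same total
        weight as a standard MST."""
        seqs = {"a": "AAAAAAAAAA", "b": "TAAAAAAAAA",
                "c": "TTTAAAAAAA", "d": "TTTTTTAAAA"}
        t = collapse_haplotypes(seqs)
        G = minimum_spanning_network(t)
        K = nx.Graph()
        names = list(seqs)
        for i, j in itertools.combinations(range(len(names)), 2):
            K.add_edge(i, j, weight=_ham(seqs[names[i]], seqs[names[j]]))
        mst_total = sum(d["weight"] for _u, _v, d in
                        nx.minimum_spanning_tree(K).edges(data=True))
        assert total_network_length(G) == mst_total
        assert G.number_of_edges() == len(seqs) - 1

    def test_connects_all_observed_haplotypes(self):
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=12))
                for i in range(7)}
        G = minimum_spanning_network(collapse_haplotypes(seqs))
        assert nx.is_connected(G)


class TestMedianJoining:
    def test_binary_worked_example_exact(self):
        """s1=000, s2=110, s3=101 (A=0, T=1): exactly one median 100 is
        added, giving a 4-node star with three weight-1 edges, total 3 —
        verified below against exhaustive Steiner-vector search."""
        t = collapse_haplotypes({"s1": "AAA", "s2": "TTA", "s3": "TAT"})
        G = median_joining(t)
        medians = [n for n, d in G.nodes(data=True) if d["inferred"]]
        assert len(medians) == 1
        assert G.nodes[medians[0]]["sequence"] == "TAA"
        assert G.number_of_nodes() == 4 and G.number_of_edges() == 3
        assert total_network_length(G) == 3

        # exhaustive Steiner oracle over all 8 binary vectors, <=2 added
        observed = ["AAA", "TTA", "TAT"]
        vectors = ["".join(p) for p in itertools.product("AT", repeat=3)]
        def msn_total(nodes):
            from taurhap.network import _msn_edges
            edges, _ = _msn_edges(list(nodes))
            return sum(w for _i, _j, w in edges)
        best = min(msn_total(observed + list(extra))
                   for r in range(3)
                   for extra in itertools.combinations(
                       [v for v in vectors if v not in observed], r))
        assert total_network_length(G) == best == 3

    def test_two_haplotypes_no_medians(self):
        t = collapse_haplotypes({"a": "AAAT", "b": "TTTT"})
        G = median_joining(t)
        assert G.number_of_nodes() == 2 and G.number_of_edges() == 1
        assert not any(d["inferred"] for _n, d in G.nodes(data=True))

    def test_median_never_lengthens_network(self):
        rng = np.random.default_rng(11)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=10))
                for i in range(6)}
        t = collapse_haplotypes(seqs)
        msn_total = total_network_length(minimum_spanning_network(t))
        assert total_network_length(median_joining(t)) <= msn_total

    def test_family_structure_separates(self, ref16k, panels):
        """Synthetic T1-family and T3 haplotypes: intra-family distances stay
        below the between-family panel separation."""
        haps = {lab: make_haplotype(ref16k, lab, panels, n_private=0, seed=1)
                for lab in ("T1", "T1a", "T1b", "T3")}
        d_t1 = {_ham(haps["T1"], haps[x]) for x in ("T1a", "T1b")}
        cross = {_ham(haps["T3"], haps[x]) for x in ("T1", "T1a", "T1b")}
        assert max(d_t1) < min(cross)

    def test_majority_median_tie_lexicographic(self):
        assert _majority_median("A", "C", "G") == "A"
        assert _majority_median("AC", "AC", "GT") == "AC"

    def test_converged_flag(self):
        t = collapse_haplotypes({"s1": "AAA", "s2": "TTA", "s3": "TAT"})
        assert median_joining(t).graph["converged"] is True
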