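"""Generator contracts: references, haplotypes, damaged reads, cohorts."""

import numpy as np
import pytest

from taurhap import (CohortRow, CohortSpec, DamageParams, GenerationError,
                     colonial_cohort_spec, make_cohort, make_haplotype,
                     make_reference, simulate_reads)
from taurhap._util import revcomp


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestMakeReference:
    def test_length_and_alphabet(self):
        ref = make_reference(16338, 0.4, 7)
        assert len(ref) == 16338
        assert set(ref.sequence) <= set("ACGT")
        assert ref.circular

    def test_deterministic(self):
        assert make_reference(2000, 0.5, 3).sequence == \
            make_reference(2000, 0.5, 3).sequence

    def test_gc_fraction_within_binomial_tolerance(self):
        ref = make_reference(16338, 0.4, 7)
        gc = (ref.sequence.count("G") + ref.sequence.count("C")) / len(ref)
        assert abs(gc - 0.4) < 0.02

    @pytest.mark.parametrize("length,gc", [(999, 0.4), (5000, 0.0), (5000, 1.0)])
    def test_invalid_parameters(self, length, gc):
        with pytest.raises(ValueError):
            make_reference(length, gc, 1)


class TestMakeHaplotype:
    def test_distance_equals_panel_chain(self, mini_ref, mini_panels):
        hap = make_haplotype(mini_ref, "root", mini_panels, n_private=0, seed=1)
        assert hamming(hap, mini_ref.sequence) == 2
        hap = make_haplotype(mini_ref, "A1", mini_panels, n_private=0, seed=1)
        assert hamming(hap, mini_ref.sequence) == 4   # A1 chain includes root

    def test_derived_alleles_at_diagnostic_positions(self, ref16k, panels):
        hap = make_haplotype(ref16k, "T1b", panels, n_private=0, seed=1)
        for v in panels.chain_variants("T1b"):
            assert hap[v.position - 1] == v.alt
        # the T1b pair of control/coding-region transitions
        assert hap[7541] != ref16k.sequence[7541]
        assert hap[16021] != ref16k.sequence[16021]

    def test_private_mutations_reproducible_and_counted(self, mini_ref, mini_panels):
        h1 = make_haplotype(mini_ref, "A1", mini_panels, n_private=5, seed=42)
        h2 = make_haplotype(mini_ref, "A1", mini_panels, n_private=5, seed=42)
        assert h1 == h2
        assert hamming(h1, mini_ref.sequence) == 4 + 5

    def test_privates_avoid_all_panel_positions(self, mini_ref, mini_panels):
        reserved = mini_panels.all_positions()
        hap = make_haplotype(mini_ref, "A1", mini_panels, n_private=50, seed=9)
        chain_pos = {v.position for v in mini_panels.chain_variants("A1")}
        for pos in reserved - chain_pos:
            assert hap[pos - 1] == mini_ref.sequence[pos - 1]

    def test_impossible_placement_raises(self, mini_ref, mini_panels):
        with pytest.raises(GenerationError):
            make_haplotype(mini_ref, "A1", mini_panels, n_private=50, seed=1,
                           private_region=(1, 40))


class TestSimulateReads:
    def test_noise_free_reads_are_circular_substrings(self, mini_ref):
        params = DamageParams(delta_ss=0, delta_ds=0, seq_error=0, coverage=10)
        rs = simulate_reads(mini_ref.sequence, params, seed=5)
        dbl = mini_ref.sequence * 2
        for r in rs:
            assert not r.changes
            probe = r.sequence if r.strand == "+" else revcomp(r.sequence)
            assert probe == dbl[r.start - 1:r.start - 1 + len(r)]

    def test_truth_records_reproduce_every_mismatch(self, mini_ref):
        rs = simulate_reads(mini_ref.sequence, DamageParams(coverage=10), seed=8)
        for r in rs:
            observed = [(i + 1, s, q) for i, (s, q) in
                        enumerate(zip(r.source, r.sequence)) if s != q]
            assert observed == [(p, f, t) for p, f, t, _k in r.changes]

    def test_depth_within_ten_percent_of_target(self, mini_ref):
        rs = simulate_reads(mini_ref.sequence, DamageParams(coverage=30), seed=2)
        assert 27 <= rs.mean_depth() <= 33

    def test_fragment_length_mean_converges(self):
        ref = make_reference(16338, 0.4, 7)
        params = DamageParams(coverage=50)        # >10k fragments
        rs = simulate_reads(ref.sequence, params, seed=3)
        assert len(rs) >= 10000
        observed = np.mean([len(r) for r in rs])
        assert abs(observed - params.mean_fragment_length) \
            / params.mean_fragment_length < 0.05

    def test_terminal_ct_rate_matches_closed_form(self):
        ref = make_reference(16338, 0.4, 7)
        params = DamageParams(delta_ss=0.5, seq_error=0.0, coverage=120)
        rs = simulate_reads(ref.sequence, params, seed=6)
        num = den = 0
        for r in rs:
            if r.source[0] == "C":
                den += 1
                num += r.sequence[0] == "T"
        expected = params.expected_terminal_ct()
        se = (expected * (1 - expected) / den) ** 0.5
        assert abs(num / den - expected) < 1.96 * se

    def test_deterministic(self, mini_ref):
        a = simulate_reads(mini_ref.sequence, DamageParams(coverage=5), seed=9)
        b = simulate_reads(mini_ref.sequence, DamageParams(coverage=5), seed=9)
        assert [(r.sequence, r.start, r.strand) for r in a] == \
            [(r.sequence, r.start, r.strand) for r in b]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DamageParams(delta_ss=1.5)
        with pytest.raises(ValueError):
            DamageParams(coverage=0)


class TestCohorts:
    def test_colonial_roster_counts(self, ref16k, panels):
        spec = colonial_cohort_spec()
        result = make_cohort(spec, ref16k, panels,
                             DamageParams(coverage=0.5), seed=1)
        labels = result.manifest["true_haplogroup"]
        assert len(result.manifest) == 21
        assert (labels == "T3").sum() == 14
        assert labels.isin(["T1a", "T1b", "T1d"]).sum() == 6
        assert (labels == "T123").sum() == 1

    def test_empty_spec_gives_empty_outputs(self, ref16k, panels):
        result = make_cohort(CohortSpec(()), ref16k, panels,
                             DamageParams(coverage=1), seed=1)
        assert len(result.manifest) == 0
        assert result.readsets == {}

    def test_same_label_and_seed_rows_identical(self, mini_ref, mini_panels):
        spec = CohortSpec((CohortRow("x", "A1", 2, 7), CohortRow("y", "A1", 2, 7)))
        result = make_cohort(spec, mini_ref, mini_panels,
                             DamageParams(coverage=3), seed=5)
        assert result.haplotypes["x"] == result.haplotypes["y"]
        assert [r.sequence for r in result.readsets["x"]] == \
            [r.sequence for r in result.readsets["y"]]

    def test_unknown_label_rejected(self, mini_ref, mini_panels):
        spec = CohortSpec((CohortRow("x", "nope", 2, 1),))
        with pytest.raises(GenerationError):
            make_cohort(spec, mini_ref, mini_panels, DamageParams(), seed=1)
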