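# taurhap

Ancient-DNA haplotyping of post-Columbian cattle, as a tested, fully
synthetic-data-verifiable pipeline.

Colonial-era cattle remains carry short, damaged DNA fragments.  From
sequencing reads of such specimens one wants to know: which maternal lineage
(mitochondrial haplogroup — the European-prevalent T3, the African-prevalent
T1 and its sub-clades T1a/T1b/T1d, the ancestral T123, or the indicine I
clades) and which paternal lineage (Y haplogroups Y1/Y2 taurine, Y3
indicine) each specimen belongs to; whether the damage pattern authenticates
the DNA as ancient; and how diverse the sampled population was.  `taurhap`
implements that entire chain for a circular mitogenome and five Y-intron
regions, together with a read simulator that generates ancient-looking data
with *known* haplogroup structure, so every stage can be verified in a
closed loop without any external downloads.

## What it computes

- **Read simulation** — log-normal fragment lengths, uniform circular
  placement, and the two-rate deamination model: geometric single-stranded
  overhangs in which C→T occurs with probability δ_ss, versus δ_ds in the
  double-stranded core (G→A appearing at 3' ends via the complementary
  strand), plus uniform sequencing error; exact truth records.
- **Mapping** — k-mer seed-and-extend against the doubled circular
  reference, banded gapped extension (+1 match, −1 mismatch, −2 gap),
  filters: mapping quality ≥ 30, ≤ 5% mismatches, ≤ 5% gap columns per
  read; coordinate-duplicate removal.
- **Damage profiling** — per-distance terminal C→T / G→A misincorporation
  fractions and an explicit authenticity rule (terminal rate ≥ 0.05 at both
  ends, significant rank decay over the first 5 positions).
- **Consensus** — per-position majority call requiring ≥ 75% allele support
  and depth ≥ 3, N otherwise; deletions compete as alleles.
- **Haplogroup assignment** — hierarchical diagnostic-SNP panels for mtDNA
  (including the published T1b pair of transitions at positions 7,542 and
  16,022); the seven-marker Y matrix (five SNPs, the DDX3Y (AT)n
  microsatellite, the ZFY GT indel).
- **Median-joining networks** — the minimum spanning network (all tied
  Kruskal edges kept) plus per-site majority median vectors admitted while
  they shorten the network; inferred nodes of degree < 3 pruned.
- **Diversity** — Nei's unbiased haplotype diversity
  H = n(1 − Σᵢ pᵢ²)/(n − 1), segregating sites S, nucleotide diversity π,
  and haplogroup frequency tables with sub-clade rollup.

## Worked example

```python
from taurhap import (DamageParams, apply_panel_refs, assign_mt_haplogroup,
                     authenticity_check, build_pileup, call_consensus,
                     deduplicate, default_panels, filter_alignments,
                     make_haplotype, make_reference, map_reads,
                     misincorporation_profile, simulate_reads)

panels = default_panels()
ref, _ = apply_panel_refs(make_reference(16338, 0.4, seed=7), panels)
hap = make_haplotype(ref, "T1b", panels, n_private=3, seed=42)

reads = simulate_reads(hap, DamageParams(coverage=30), seed=42)
result = map_reads(reads, ref, k=13)
kept = deduplicate(filter_alignments(result.alignments), ref_length=len(ref))
cons = call_consensus(build_pileup(kept, ref))
profile = misincorporation_profile(kept, ref)

print(f"{len(reads)} reads, mean depth {reads.mean_depth():.1f}x")
print(f"{len(result.alignments)} mapped, {len(kept)} after filter+dedup")
print(f"consensus N fraction {cons.n_fraction:.4f}")
print(f"terminal C->T {profile.f_ct_5p[0]:.3f}, G->A {profile.f_ga_3p[0]:.3f}")
print(authenticity_check(profile).verdict)
call = assign_mt_haplogroup(cons, ref, panels)
print(f"haplogroup: {call.haplogroup} ({call.status})")
```

prints

```
6702 reads, mean depth 30.0x
6654 mapped, 6457 after filter+dedup
consensus N fraction 0.0000
terminal C->T 0.273, G->A 0.260
authentic
haplogroup: T1b (assigned)
```

6,702 damaged ~73 bp fragments give 30× depth; after the published filters
6,457 alignments remain; the consensus has no ambiguous positions; the
terminal misincorporation rates (~0.27) sit just under the damage model's
closed-form expectation of 0.286 for δ_ss = 0.4, δ_ds = 0.02 and overhang
parameter 0.3 (the mismatch filter trims the most heavily damaged reads,
slightly attenuating the post-filter rate), and
the profile passes the authenticity rule; the specimen is correctly typed as
the T1b sub-clade it was simulated from.

The same stages are available as subcommands (`taurhap simulate | map |
damage | consensus | type-mt | type-y | network | diversity | run-all`);
`taurhap run-all --out RUN --seed 1` runs the default 21-specimen cohort
end to end and writes per-specimen consensi, calls, damage profiles, the
median-joining network and the diversity report.

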