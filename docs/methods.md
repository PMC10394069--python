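# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `taurhap`.  It is written for users who need to judge
what the package's closed-loop verification does and does not establish
about real ancient-DNA data.

## Coordinates and references

All coordinates are 1-based and inclusive.  Mitochondrial references are
circular: position `L+1` wraps to 1, fragments and alignments may cross the
origin, and mapping works against the doubled sequence.  The synthetic
reference is 16,338 bp at GC 0.40, i.i.d. bases — the length keeps published
diagnostic coordinates (7,542; 16,022) valid on the same frame as a bovine
mitogenome; the base composition is realistic in aggregate but has no gene
structure, no strand asymmetry and no hypervariable mutation-rate profile.
The five Y-intron references (700 + 650 + 620 + 500 + 699 = 3,169 bp) are
synthetic stand-ins for the GenBank intron sequences, carrying the Y2 allele
states as the reference frame with marker anchors at the published footnote
coordinates.

## Damage model (simulator) and profiler

Fragments follow a log-normal length distribution with location
`log(frag_mean)` and scale `frag_sd` (defaults 70 bp, 0.3), truncated to
[20, L]; fragments longer than the genome are resampled, never emitted.
Starts are uniform on the circle, strands fair.  Fragments are drawn until
emitted bases reach `coverage × L`, so realised depth is within one
fragment of target.

Deamination follows the standard two-rate overhang model.  Each terminus
receives a single-stranded overhang of length `geometric(overhang_p) − 1`
(default p = 0.3, mean ≈ 2.3 bases).  Within the 5' overhang C→T occurs
with probability `delta_ss` (default 0.4); within the 3' overhang the
complementary-strand deamination appears as G→A at the same rate; in the
double-stranded core both occur at `delta_ds` (default 0.02).  A uniform
per-base sequencing error (default 0.001) follows.  Published descriptions
of this damage signature in colonial-era cattle are qualitative, so these
defaults are conventional ancient-DNA values, all overridable; the closed form for the expected terminal C→T rate,

    E[f_CT(1)] = (1−p)·δ_ss + p·δ_ds, then perturbed by sequencing error,

is exposed as `DamageParams.expected_terminal_ct()` and is what the
profiler is tested against.

The profiler counts, per distance i from each terminus, reference-C columns
read as T (5') and reference-G columns read as A (3'), in sequencing
orientation with minus-strand reads complemented (the biochemical
convention).  Zero-denominator positions are reported missing (NaN), never
as rate 0.  The authenticity rule — both terminal rates ≥ 0.05 and a
negative Spearman rank correlation against distance (one-sided p < 0.05)
over the first 5 positions at both termini — is this package's explicit
formalisation of the usual visual inspection of damage plots; both numbers
are configurable and should be treated as a convention, not a community
standard.  Depurination signals in flanking genomic context are not
modelled and not tested.  Single-strand-friendly library preparations can
distort damage symmetry between termini; this is not modelled.

## Mapper

Exact k-mer seeding (default k = 13, three seed offsets per strand) against
the doubled circular reference, then extension at each candidate
start.  Scoring is +1 match, −1 mismatch, −2 per gap column, band 16.
When the ungapped comparison at a candidate shows ≤ 1 mismatch the ungapped
alignment is provably optimal under this scoring (any alignment with a gap
column scores ≤ n − 2), so the banded DP runs only otherwise.  Gap runs are
left-aligned afterwards so that co-optimal indel placements inside tandem
repeats agree across reads.  `mapq_proxy` is 60 for a unique candidate
location, else `min(60, 4 × (best − second best))` — a documented,
reproducible stand-in for proprietary mapping-quality definitions, with the
published threshold (≥ 30) kept as the filter default.  The mismatch and
gap filters (≤ 5% each) are inclusive bounds.  Filtering precedes
duplicate removal; duplicates are alignments sharing (start, end, strand),
resolved by score then lexicographic read id.  Only the best location is
reported by default (`keep_secondary` emits the rest); for a single-copy
circular mitogenome multi-mapping adds nothing.

## Consensus

Raw-count majority per position: the winning allele (base or deletion) is
emitted iff support ≥ 75% of depth (inclusive — an exact tie at the
threshold is a call) and depth ≥ `min_depth` (default 3, this package's
stand-in for an interactive assembler's unspecified quality setting);
otherwise N.  Insertions are keyed by the position they follow and must
clear the same support rule against the depth at that position.  Counts are
never quality-weighted.

## Haplogroup assignment

mtDNA: a clade matches when every callable variant of its panel and of all
loaded ancestors' panels is derived, with ≥ 80% of each panel's positions
callable; N never counts for or against a panel.  The most-derived matching
clade is assigned; several maximal matches give `ambiguous`, none
`unassigned`.  A panel whose parent is not loaded acts as a root, so the
published T1b pair can be used stand-alone for a family-level call.  Panels
are configuration, not code: apart from the published T1b transitions at
7,542 and 16,022, the shipped panel file is synthetic and labelled as such.

Y: the seven marker states are read from per-region consensi in reference
coordinates — SNP base at the anchor; microsatellite as the repeat-unit
count of the maximal uninterrupted (AT)n run containing the anchor after
removing consensus deletions (N in or flanking the run makes it
uncallable); indel as motif present / deleted at the anchor.  Assignment
requires ≥ 4 callable markers consistent with exactly one haplogroup row.
A contracted microsatellite may be uncallable from damaged reads when
partial-overlap alignments blur the deletion boundary; assignment then
falls back to the remaining markers.  Marker ids follow the published
table header (zfy9/zfy10) even though its footnote uses ZFY4/ZFY5; the
UTY19 anchor is cited under two GenBank ids in the source and both are
carried in the config without choosing.

## Networks

Haplotype collapsing uses complete-column deletion (any column with a gap
or N in any sequence is dropped and recorded) before grouping.  The
minimum spanning network keeps every edge of a weight class that joins two
components as of the start of that class — the union of all minimum
spanning trees; with relaxation ε, classes up to the connecting weight + ε
are admitted (ε defaults to 0, the common network-software default).
Median joining iterates: build the MSN, form per-site majority medians of
all same-component triples (exhaustive triples by default at this scale),
add the candidate that most reduces total network length, stop when none
does; finally inferred nodes of degree < 3 are pruned repeatedly.
Three-way site ties and candidate ties resolve lexicographically, making
the construction deterministic for a given input order.  The worked
3-haplotype example is verified against an exhaustive Steiner-vector
search; in general the heuristic is not guaranteed to reach the Steiner
optimum.

## Diversity

Nei's unbiased estimator H = n(1 − Σ pᵢ²)/(n − 1) (for i.i.d. draws from h
equifrequent haplotypes E[H] = 1 − 1/h exactly, which the Monte-Carlo test
uses as its oracle); S counts columns with ≥ 2 observed alleles; π is the
mean pairwise difference per included site over all n(n−1)/2 sequence
pairs.  The control-region window defaults to the last 700 bases of the
circular reference — the published analyses use a 700 bp D-loop window
whose exact coordinates are not printed, so the window is a required,
documented configuration choice.  Reports round H to 3 decimals and
frequencies to 2 (matching the published presentation); machine outputs
keep full precision.  Sub-clades roll up for reporting (T1a/T1b/T1d → T1,
T123 → T) via a configurable map.

## Default cohort

The shipped 21-row cohort emulates the archaeological roster: 14 × T3,
6 × T1-family (4 T1a, 1 T1b, 1 T1d), 1 × T123, with specimen names echoing
the source sites.  Three T3 rows share one haplotype and two share another
(same row seed ⇒ identical specimen), and per-specimen private mutations
are placed in the control-region window — emulating D-loop
hypervariability — so the cohort collapses to 18 control-region haplotypes
with multiplicity profile {3, 2, 1×16}, the unique 18-part partition of 21
consistent with the published diversity value.  Per-specimen randomness
derives from the cohort seed and row seed by stable hashing, so any row
regenerates in isolation.

## Problem sizes used in verification

The end-to-end checks run the full 21-specimen cohort at 30× on the
16,338 bp reference; the damage closed loop uses ~250k reads (≥ 50k
terminal reference-C columns); read-level consensus-recovery replicates run
on a 3 kb mini-reference with a 3-clade panel set at 8 seeded replicates,
and per-clade closed loops on the full reference run once per clade — these
are deliberate scaled-down renderings of the corresponding statistical
claims (the estimator properties they probe do not change with replicate
count, only the power of the check does).  Byte-level determinism is
checked on a 3-specimen cohort at 10×.

## What passing tests do and do not show

The simulator is also the oracle: closed-loop success shows the analysis
stages correctly invert the generative model this package defines (uniform
fragment placement, i.i.d. reference, substitution-only damage, fixed base
qualities).  Real ancient libraries violate several of these assumptions —
coverage is biased by fragmentation hotspots and bait design, damage varies
by library preparation, contamination and indicine introgression are not
modelled (no contamination mixtures, no paired-end geometry, no quality
recalibration).  Passing here certifies the implementation, not the
field-readiness of any particular threshold on real material.
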