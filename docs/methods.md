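# Methods

## Coordinates and data model

All positions are 0-based; intervals are half-open, BED-style. A
recombination breakpoint at integer position `b` lies between alignment
columns `b − 1` and `b`, with `1 ≤ b ≤ L − 1`. A c-gene map is a sorted set
of unique breakpoints partitioning `[0, L)` into `B + 1` c-genes; lengths
always sum to `L`.

Alignments are rectangular over {A, C, G, T, N, -}. On input, case is folded,
U maps to T, and IUPAC ambiguity codes collapse to N: the four-gamete test
consumes only unambiguous biallelic patterns, and a partially ambiguous code
cannot be assigned to a gamete. Gaps are retained in the alignment (keeping
column coordinates stable) but any column containing N or a gap among the
four focal taxa is skipped entirely — no pairwise deletion — so the
four-gamete matrix is always fully defined.

## Four-gamete breakpoint detection

For one subclade (three ingroup taxa plus an outgroup) the detector:

1. **Scans for parsimony-informative sites**: biallelic columns with a 2+2
   allele split over the four taxa. Each is labelled by the ingroup pair it
   unites (`T1T2`, `T1T3`, `T2T3`); the half containing the outgroup
   determines the label by complementation. Singleton (1+3), invariant,
   >2-allele and N/gap-containing columns carry no four-gamete information
   and are excluded.
2. **Tests pairs for incompatibility** by explicit gamete enumeration: two
   sites are incompatible iff all four allele combinations occur among the
   haplotypes. For 2+2 sites this is provably equivalent to the split labels
   differing (property-tested).
3. **Localizes events with the Hudson–Kaplan minimal-interval procedure**:
   for each site, the open interval back to its nearest incompatible
   predecessor is collected (every incompatible pair contains such an
   interval); intervals containing another interval are discarded in a single
   left-to-right pass; surviving intervals are selected greedily by right
   endpoint. The selected intervals are pairwise disjoint, each contains at
   least one recombination event, and their count is R_min — verified against
   a brute-force exhaustive minimum on small instances.

The outgroup participates as a fourth haplotype (the test is unrooted), not
for polarization. The test is combinatorial; no multiple-testing correction
applies. It is conservative by construction — only breakpoints flanked by
informative sites supporting different splits are detectable, and boundaries
that alter only branch lengths (deep-coalescence-only state changes) are
invisible — and, conversely, under high divergence homoplasy is conflated
with recombination, inflating counts (demonstrated on simulated data).

**Representative breakpoint position.** Each interval `(l, r)` between
informative sites is reported with one deterministic point: the feasible
breakpoint range is `[l+1, r]`, and the point is its floor midpoint,
`(l + r + 1) // 2`. Adjacent-column conflicts `(p, p+1)` — a zero-width
uncertainty region — give point `p + 1`.

## Overlay (the recombination ratchet)

Breakpoint sets from taxon-disjoint subclades are pooled as the sorted union
of their representative points. Coincident points from different subclades
collapse to a single breakpoint: two recurrent breakpoints at the exact same
position cannot be distinguished from one, so they are counted once and
logged with their contributors. Overlay is commutative and associative; the
composite c-gene count is (unique points) + 1, and the mean c-gene length is
strictly decreasing as non-duplicate sets are added.

Overlay uses points rather than uncertainty intervals because the counts of
interest are point-based; interval-aware overlay (refusing ambiguous
orderings) was considered and deferred — for the clean simulated regime and
the desk-scale arithmetic reproduced here, points suffice.

The geometric fit in the c-gene statistics is descriptive: the parameter is
the moment/ML estimate p = 1/mean on support {1, 2, ...}, and goodness of fit
uses a chi-square test on geometric-quantile bins with expected counts ≥ 5
(one degree of freedom deducted for the fitted parameter; NaN when fewer than
four usable bins exist).

No rule is provided for choosing one c-gene per linkage block for downstream
coalescent analysis: adjacent c-genes violate the free-recombination-between-
loci assumption, but preferring (say) the longer one could bias topology
frequencies, since c-gene length and topology are correlated. The choice is
left to the analyst.

## Composite genealogies and restricted RF

Variation is confined to the k trichotomies; the backbone is fixed (its
branches are assumed long enough to escape ILS). The composite topology space
is the 3^k product of local resolutions (enumeration guarded at k ≤ 12).
Restricted RF — the count of differing trichotomy resolutions — equals half
the bipartition symmetric difference between the fully resolved trees; the
test suite verifies this exhaustively for k ≤ 3 against an independent
clade-set comparison on emitted Newick strings. Expected pairwise RF between
independent uniform-random genealogies is 2k/3 exactly.

Adjacency profiles report RF-to-species per c-gene and the deltas between
neighbours. When every breakpoint flips exactly one trichotomy, |ΔRF| ∈
{0, 1}; neighbours whose labels differ at ≥ 2 trichotomies (possible only at
coincident, collapsed breakpoints) are flagged rather than forbidden.

## Mosaic simulator

Each trichotomy's history along the segment is an alternating renewal
process over four genealogical states — concordant without deep coalescence,
concordant with deep coalescence, and the two discordant topologies — with
geometric segment lengths (support {1, 2, ...}, p = 1/mean).

**Parameter conventions.** `stationary_freq[s]` is the expected *fraction of
sequence* (bp occupancy) in state s, the quantity empirical segmentations
report; the long-run fraction of *segments* in state s is then proportional
to freq/mean. Because consecutive segments must differ in state, sampling
segment states naively from freq/mean biases the realized chain; the sampler
therefore solves (by fixed-point iteration) for weights w such that the
no-repeat chain with P(i→j) = w_j/(1 − w_i) has stationary segment
distribution exactly freq/mean. Realized occupancy then matches the
configured frequencies in expectation; `expected_occupancy` recomputes the
chain's stationary occupancy independently for verification. A target
segment frequency above 1/2 is rejected (no alternating sequence can realize
it); a single-state model yields one segment spanning the whole length.

**Defaults.** The default model uses a 532 bp mean for the concordant-
without-deep-coalescence state (the low end of coalescent-HMM estimates for
hominid autosomal targets, where concordant-shallow fragment means span
roughly 530–2700 bp) and 60.6 bp for the three other states (within the
empirical 41–81 bp range), with occupancies 0.50 / 0.20 / 0.15 / 0.15. The
combined mean c-gene length, 1 / Σ(freq/mean), is ≈ 108.8 bp — the empirical
scale of the most fragmented hominid target region.

**Truth composition.** Per-track *topology* changes (state changes that alter
the local resolution) become breakpoints of the truth map; deep-coalescence-
only changes are recorded as annotations, not breakpoints, since no
topology-based detector can see them. C-gene labels are tuples of local
resolutions, one per trichotomy.

**Alignment emission** is pattern-based, not a substitution-model simulation:
per column, with configured probabilities, an invariant pattern, a singleton
(one random taxon mutated), or a 2+2 informative pattern for one trichotomy
(probability split evenly across trichotomies) is emitted. An informative
column gives the derived base to the pair united by the local topology of the
enclosing c-gene; with probability `homoplasy_rate` a uniformly random wrong
split is supported instead. Ancestral and derived bases are drawn per column.
Because the four-gamete test consumes only site patterns, this keeps ground
truth exactly controllable; a full sequence simulator can be substituted
upstream if realistic substitution processes are needed.

**What the simulator does not emulate:** substitution-model heterogeneity,
recurrent mutation structure beyond the flat homoplasy rate, indels/missing
data, mutation-rate variation along the segment, intra-state branch-length
variation, and recombination that re-enters a previous genealogy at the same
position. Passing tests on simulated data therefore demonstrate correctness
of the delimitation machinery under the stated model, not detector
performance on real, homoplasy-rich divergent sequences — on such data the
FGT is conservative relative to model-based segmentation (it needs flanking
informative support) while homoplasy pushes counts the other way.

## Extrapolation arithmetic

With per-trichotomy mean c-gene length m on a segment of length L, each
trichotomy carries L/m − 1 breakpoints; k trichotomies give the composite
mean L / (k(L/m − 1) + 1), reported alongside the m/k limit (they differ by
<1% once L/m > 1000; both are returned since either may be quoted). Event
counts scale as E·k, and fold-ratios between recombination-rate estimates
rescale events or lengths exactly (rational arithmetic for rational inputs,
so printed-precision figures carry no float drift). The distinction between
recombination *events* and *distinct breakpoints* (recurrent events at one
position) is carried by the caller; no derivation of distinct-breakpoint
counts from event counts is attempted here.

## Problem sizes and determinism

All worked examples and tests run at desk scale: simulated segments of
10–30 kb for end-to-end detection, 0.4–10 Mb single tracks for renewal and
occupancy checks, 10,000 Monte-Carlo pairs for the expected-RF estimate,
exhaustive enumeration only for k ≤ 3 (RF cross-checks) and ≤ 12 informative
sites (R_min brute force). Every stochastic path takes an explicit seed or
`numpy` Generator; CLI outputs embed tool version, seed and config hash, and
identical inputs reproduce byte-identical outputs.

## Known limitations

- Detection requires ≥ 1 informative site per c-gene per flanking state;
  short c-genes between sparse sites are undetectable by construction.
- Representative points, not full uncertainty intervals, enter the overlay;
  closely spaced breakpoints from different subclades may be ordered
  incorrectly within their shared uncertainty region.
- The restricted-RF machinery assumes discordance confined to the specified
  trichotomies; general gene-tree discordance outside them is out of scope.
- The geometric length fit is descriptive; c-gene lengths under superposition
  are not exactly geometric even when per-state lengths are.
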