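# Methods

## Coordinate model and distance definition

Every coding region is stored as `(start, stop, strand)` with
`start < stop` regardless of strand. On the forward strand `start` is the
first base of the start codon and `stop` the last base of the stop codon;
on the reverse strand `start` is the last base of the stop codon and `stop`
the first base of the start codon. All coordinates are 1-based inclusive
(the GFF3 convention); any half-open arithmetic is internal.

Genes are sorted per replicon by `(start, stop, locus_tag)` — the tie-break
makes the sort deterministic — and each consecutive pair forms a gene pair;
pairs never span replicons, and replicons are treated as linear (no pair is
formed across a circular origin; annotations rarely place the origin inside
a gene pair of interest, and forming such a pair would require knowing the
replicon length). Pairs are serial when strands are equal, convergent for
(+,−), divergent for (−,+). Only serial pairs carry a distance:

    k = second.start − first.stop − 1

This single expression is strand-independent under the coordinate model
above. The verbal definition "position difference between stop codon and
start codon" is ambiguous by ±1; the formula is anchored instead by the
canonical boundary motifs: ATGA (start ATG overlapping stop TGA) must give
−4, TAATG must give −1, abutting genes give 0, and one spacer nucleotide
gives +1.

Cleanup before pairing: non-protein-coding (stable-RNA) genes are excluded —
so some distances are larger than the true neighbour distance, a known and
accepted distortion given how few stable-RNA genes there are; gene-internal
transposase genes (flagged in the input) are removed so a transposon-split
gene does not contribute spurious pairs; serial pairs whose
*distance-defining* termini are truncated (upstream gene lacking its stop
codon, downstream gene lacking its start codon) are dropped — truncation of
the far termini is irrelevant to the distance and does not drop the pair.
Curation flags are caller-supplied inputs: the package does not attempt to
re-derive pseudogene or transposase annotations.

Overlaps deeper than −60 nt are flagged `anomalous_overlap` in output
(experience with microbial annotations says such overlaps are virtually
always gene-start misannotations) but are never silently dropped.

## Overlap phase and codon-level feasibility

The phase of a distance k is its nonnegative residue mod 3, implemented by
the piecewise formula `p = k − 3⌊k/3⌋` for k ≥ 0 and `p = k + 3⌈−k/3⌉` for
k < 0 (the two-branch form mirrors how the quantity is usually written;
a property test confirms it equals `((k % 3) + 3) % 3` on [−1000, 1000]).
Phase-1 overlaps are −8, −11, −14, …; phase-2 overlaps are −7, −10, −13, …
(−4 and −1 are phase 2).

For overlaps of −5 ≤ k ≤ −1 the downstream start codon and the upstream
stop codon share bases. Placing the stop codon's last base at position s,
the start codon's first base sits at s + k + 1; `overlap_feasibility`
builds the joint motif and keeps every (stop, start) codon combination that
agrees on the shared bases. With canonical codons (starts ATG/GTG/TTG,
stops TAA/TAG/TGA):

| k  | feasible motifs                 |
|----|---------------------------------|
| −1 | TAATG, TGATG, TAGTG             |
| −2 | none (an NTG start implies a nonexistent NNT stop) |
| −3 | none (start codon would have to *be* the stop codon) |
| −4 | ATGA, GTGA, TTGA                |
| −5 | none (starts end in G, stops begin with T); ATT extension allows ATTGA/ATTAG/ATTAA |

For k ≥ 0 or k ≤ −6 the codons occupy disjoint bases and a sentinel
"unconstrained" is returned rather than an (infinite-motif-context) set.
The implementation is verified in tests against brute-force enumeration of
all 4^L strings at each constrained layout. The −3 infeasibility is a
geometric corollary worth noting explicitly: it means *no* phase-0 short
overlap exists, which together with the asymmetric reachability of −4/−1
(phase 2) vs −8 (phase 1) shapes the phase composition of overlap
distributions.

## Distance distributions

Histograms count per-integer distances over a closed window; out-of-window
pairs are tallied, not discarded, so the total is always auditable.
Phase-split histograms partition the plain histogram exactly (asserted as a
conservation property). `window_fraction` reports the count and fraction of
pairs inside a window, typically −8..+6 (the range over which
termination–reinitiation is efficient). No smoothing or peak calling is
done; plotting support is limited to per-bin TSV output.

## Two-factor distance decomposition

Cross-species observations (COG-pair id, phylum, distance) are modeled as

    d_k[i, j] = C_i + P_j + e_k

with the reference phylum's effect pinned to exactly 0 — the model is
otherwise invariant to shifting all C up and all P down by a constant.
Observations are first restricted to widespread COG pairs (present in ≥ 25
distinct phyla by default; the threshold is a parameter). The default
reference phylum is the one with the most observations, which generalizes
the conventional choice of the largest taxon.

The default solver is alternating minimization with exact coordinate
updates: each sweep sets every `C_i` to the mean of `d − P_j` over its
observations, then every `P_j` to the mean of `d − C_i`, then shifts along
the gauge direction (loss-invariant) to restore `P[ref] = 0`. The loss is
therefore non-increasing sweep to sweep (asserted on the recorded trace);
convergence is declared when the per-sweep improvement falls below 1e−10
relative (absolute near zero), with a 10,000-sweep cap. A direct sparse
least-squares path (dummy-coded design, LSQR at atol=btol=1e−14) serves as
an independent cross-check; the two agree to ≤1e−6 in tests. Effects are
identifiable only if the COG-pair/phylum incidence graph is connected; a
disconnected design raises an error listing the components
(scipy's connected-components on the bipartite incidence matrix).

Taxonomic adjustment subtracts `P[phylum]` from each observed distance;
reference-phylum distances are unchanged. Per-COG-pair summaries support
both mean and median; the enrichment analysis consumes medians by default
(medians are robust to the long right tail of distances). Dispersions
`sd_C`, `sd_P` are sample standard deviations (ddof=1) of the effect
vectors, reference included as 0.

## Complex enrichment

Complex membership per pair comes from an explicit curation flag when
available, else optionally from the shared-name-stem heuristic: true iff
both gene names end in a distinct single uppercase letter over an equal
non-empty stem (hyfH/hyfI). The heuristic is deliberately simple and
knowingly imperfect in both directions (menD/menH are consecutive enzymes,
not complex subunits; many true complexes violate the naming convention).

Distances (or COG-pair medians) are binned: short = [−8, +10] (predictive
of coupling), long = (+20, ∞) (predictive of independent translation),
excluded = everything else — including the +11..+20 band, where coupling
efficiency is highly gene-specific, *and* distances below −8. The 2×2
table (complex × bin) yields the enrichment ratio
`(a/(a+b)) / (c/(c+d))` and a Pearson χ² test (df=1). No Yates correction
is applied: at the table magnitudes of interest the correction is
negligible and the uncorrected statistic is the conventional choice.

The double-resampling bootstrap quantifies robustness of the enrichment to
both the COG-pair inventory and gene-pair sampling: each of n_reps
(default 1,000) replicates keeps every COG pair independently with
probability 1 − e⁻¹ ≈ 0.63, then draws the original total number of gene
pairs with replacement from the retained COG pairs weighted by their
gene-pair counts (implemented as a multinomial over the five resampling
cells: short/long × flag plus the excluded mass), and recomputes the
ratio. Replicates with an empty long bin, or zero complex pairs in either
bin, would put ±∞ into the log-ratio distribution; they are dropped and
counted instead, with a warning past 10% degeneracy. The summary is
`z = mean(ln ratio) / sd(ln ratio)` (the log base cancels) with a
one-sided upper-tail standard-normal p — one-sided because the hypothesis
is directional (enrichment, not depletion). Approximate log-normality of
the replicate ratios is an empirical observation, not a gated assumption.

## Reporter translational efficiencies

Per replicate, efficiency = (specific activity − mean empty-vector control
activity) / relative transcript level; control subtraction applies to
activities only (transcript levels are already relative quantities).
Values below control stay negative — clipping would bias means. Construct
means over ≥3 biological replicates are divided by the wildtype mean;
reported SDs are over the normalized replicate values. Normalization is a
constant rescaling, so averaging before or after normalizing gives the
same means (asserted). Enzyme kinetics (extinction-coefficient arithmetic)
and densitometry are upstream of this module and out of scope.

## Synthetic data

`simulate_genome_annotation` places genes of uniform length 300–3,000 nt
(multiples of 3) along replicons with a Markov strand process
(switch probability 0.2 by default, so serial, convergent and divergent
pairs all occur). Each same-strand boundary's distance is an i.i.d. draw
from a configurable mixture; the default mixture mimics the empirical
shape of prokaryotic distance distributions — point masses at −4 (0.14),
−1 (0.05) and −8 (0.03), a 0..+6 band, a narrow +9..+12 component (0.07),
a broad +50..+150 component (0.35), thin long-overlap tails in phase 1 and
phase 2 (0.03/0.01, phase 1 heavier), and filler mass at +13..+49 and
+151..+300. Opposite-strand boundaries redraw until nonnegative, since
antiparallel codon overlaps are not modeled. Gene lengths are irrelevant to
distance statistics; they only keep coordinates realistic.

When sequences are emitted, every gene gets a start and stop codon stamped
strand-appropriately, and every serial boundary with −5 ≤ k ≤ −1 is
overwritten with a motif drawn uniformly from `overlap_feasibility(k)` —
spec validation rejects mixtures putting mass on −2, −3 or −5 (with
canonical codons) when sequences are requested, since no motif exists.
Sequence consistency is guaranteed at serial boundaries only.

Shared-stem complex name pairs (cx0012A upstream / cx0012B downstream) are
planted with probability 0.355 at short-bin boundaries and 0.225 at
long-bin ones — the complex fractions the enrichment analysis should
recover (planted ratio ≈ 1.6). Planting is restricted to alternating
(even-indexed) boundaries: adjacent pairs share a gene, and naming both
members of overlapping pairs would couple the flags; alternation halves
both realized fractions equally, preserving the planted ratio while keeping
pair-level flags independent. Half of the remaining genes get unrelated
names, the rest none.

`simulate_multi_phylum_dataset` draws `C_i ~ N(15, 38.2)` nt,
`P_j ~ N(0, 2.9)` nt with the reference pinned to 0, and observations
`round(C_i + P_j + N(0, 10))` at 25 per cell by default (214 COG pairs ×
49 phyla), returning the truth for recovery tests. Rounding happens after
adding noise, because annotated distances are integral; this slightly
inflates recovered noise and biases dispersion recovery at very small
noise_sd (documented, not corrected). COG-pair complex flags are Bernoulli
with bin-dependent probability, the bin taken from the planted `C_i`.

What the generators do *not* emulate: codon usage and GC content, operon
length structure, gene-content phylogenetics, annotation error, or the
correlation of distances along a replicon (boundaries are independent).
Passing closed-loop tests therefore demonstrates correctness of the
machinery, not fidelity of any real genome's distance distribution, and
genome-scale published counts that depend on real annotations are
deliberately not reproduced.

## Problem sizes in the test suite

The suite exercises the factor model at 200 COG pairs × 30 phyla × 20
observations per cell (120,000 observations), the bootstrap at 1,000
replicates over 600 COG pairs, null calibration over 20 seeded runs of 200
replicates, and mixture recovery at 10,000 simulated pairs — sizes chosen
so the whole suite runs in seconds while keeping sampling error far below
the asserted tolerances (e.g. 4 binomial SDs at n = 10,000).

## Known limitations

* Circular replicons: the origin-spanning pair is never formed.
* The shared-stem heuristic's error rates are unknown and organism-specific.
* The bootstrap's degenerate-replicate policy (drop and count) slightly
  biases z upward when degeneracy is common; the warning threshold makes
  this visible.
* The factor model is purely additive — no interaction terms and no
  tree-aware (phylogenetically correlated) error structure.
* Multi-exon (joined) CDS annotations are rejected rather than handled.
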