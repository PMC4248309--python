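# Methods

This note records the models, parameters, numerical choices and known
limitations of loopscape, in the order the pipeline runs.

## PET filtering and anchoring

Coordinates are 0-based half-open throughout; a mate's position is the
midpoint floor((start+end)/2), and PETs are canonically ordered so
(chrom1, start1) ≤ (chrom2, start2).

* **Duplicates** are PETs identical on both mates' coordinates and
  strands; one copy is kept. They arise from PCR amplification of a
  single ligation product.
* **Self-circularization** PETs come from a fragment ligating to itself:
  operationalized as same chromosome, convergent orientation (+/− after
  canonical ordering) and span ≤ 3,000 bp. The cutoff is on the order of
  the sheared-fragment size (~500 bp) times a safety factor and is
  configurable. These PETs still carry binding information, so they are
  diverted to a separate stream usable for peak calling, never for
  interaction calling.
* **Anchoring**: binding peaks are extended ±1,500 bp symmetrically; a
  mate belongs to the anchor whose extended interval contains its
  midpoint. Midpoint containment (not any-overlap) guarantees a single
  assignment; when extensions overlap, the anchor with the nearest
  (un-extended) midpoint wins, ties going to the lexicographically
  smaller id — deterministic and order-independent. PETs with an
  unassigned mate, mates on two chromosomes, or both mates on one anchor
  are dropped, each counted once in the filter report, whose class counts
  must sum to the input count (asserted on every run).

Replicates are concatenated before calling; per-replicate calling is
available by running the caller per input.

## The distance-matched rewired (DMR) null and local Z-scores

Random ligation joins loci on the same fibre at a rate decaying with
genomic distance, so significance must be judged against pairs at the
same distance. The null is built by rewiring: for each anchored PET with
anchor-midpoint separation d, draw a uniformly random anchor on the same
chromosome, then a uniformly random partner among anchors whose
separation from it falls in the same distance bin as d (left or right).
Anchors with no in-bin partner are redrawn; an in-bin partner always
exists because the observed pair itself lies in the bin. By construction
the per-bin histogram of rewired PET distances equals the observed
histogram exactly, which `rewire` asserts on every run. Chromosomes with
fewer than two anchors pass their PETs through unrewired.

"Local" is operationalized as log2-spaced distance bins (default one bin
per octave) covering the observed PET distance range, since contact
frequency decays roughly log-linearly with distance. For bin b,

    Z = (n − μ_b) / max(σ_b, σ_min)

with μ_b, σ_b the mean/SD of rewired pair counts over *all*
same-chromosome anchor pairs whose separation lies in b — structural
zeros included: excluding never-rewired pairs inflates μ_b and destroys
FDR control (`include_structural_zeros` exposes the alternative for
sensitivity analysis). Bins whose pair universe holds fewer than
`min_pairs_per_bin` (default 20) pairs are pooled with neighbours,
widening one bin per side until the minimum is met. `sd_floor` (default
0.5) prevents division blow-ups in sparse bins. One rewired copy is the
default (`n_rewires = 1`); more copies reduce null variance and are
scaled by 1/R in the FDR ratio.

The empirical FDR of threshold t is (#rewired pairs with Z ≥ t / R) /
(#observed pairs with Z ≥ t); the emitted threshold is the smallest
observed Z value satisfying the bound (α = 0.10 default), ties at the
threshold are called, and if no threshold qualifies nothing is called.
Interchromosomal PETs are excluded from calling: the distance-matched
construction is undefined across chromosomes.

Calls from different factor data sets are equated when both anchor
intervals reciprocally overlap (any-overlap on original peak
coordinates); merged components list their supporting factors, and
single-factor interactions are flagged specific.

## Differential calling

Candidates are the union of both conditions' calls. The binding control
excludes candidates whose anchors are not RAD21-bound (±1,500 bp) in
*both* conditions — their interaction difference could merely reflect
binding loss; they are reported in a side table. Each remaining candidate
is tested with Fisher's exact test on (n_A, N_A−n_A; n_B, N_B−n_B), where
N is the condition's total anchored intrachromosomal PET count, followed
by Benjamini–Hochberg (q ≤ 0.05 default); direction follows the larger
normalized count. Fisher-on-normalized-counts was chosen for desk-scale
determinism; the test sits behind a narrow interface so a dispersion-aware
test could be slotted in. Both conditions must be anchored on a shared
peak set (the generator provides one; for real data, merge peak sets
before anchoring). No replicate-aware dispersion modeling is attempted.

## Annotation

Regulatory elements are DHSs labeled by the chromatin state with maximal
overlap bp; zero-overlap DHSs are labeled "undefined" and excluded from
state-specific statistics. Ties — and the reduction of an anchor's
element set to one label — use the fixed priority TSS > PF > E > WE >
CTCF > T > R > undefined, promoter identity dominating because the
promoter-centric analyses depend on it.

TAD classes: with borders padded ±20 kb, an interaction is *intra* when
both anchor midpoints share a TAD away from padded borders, *inter* when
they occupy two TADs, *border* when it stays within one TAD but touches a
padded border, *unassigned* when an anchor lies outside every TAD.

5C comparison: call ends are padded ±10 kb, calls fully inside the tested
region are scored, and the expected overlap redraws random pairs inside
the tested region with the observed interaction-distance multiset
(1,000 permutations default); p = (1 + #perms ≥ observed)/(1 + n_perm).

## Enrichment, SOM, HOT

TF enrichment compares the fraction of interacting loci overlapping a TF
peak with a size-matched random subset of the locus universe (one seeded
draw by default; a multi-draw averaged mode exists), Fisher's exact test,
Bonferroni across TFs. Categories: *high* when adjusted p ≤ 0.01,
log2(obs/exp) > 0.35 and presence ≥ 35% of interacting loci; *weak* when
only the p criterion holds; *none* otherwise.

The SOM is a batch fit on a toroidal hexagonal grid (Euclidean distance
on binary co-binding rows; Gaussian neighbourhood whose radius shrinks
geometrically from half the grid diagonal to 0.5 over 15 epochs — logged
in the model metadata). Ten restarts are fitted and the model minimizing
the mean site-to-codebook distance kept, with per-restart metrics
retained. Neuron-level interaction enrichment is Fisher + BH (q < 0.01)
with fold > 2; Bonferroni is available as an option.

HOT analysis: locus-level Fisher as for TFs; pair-level significance
permutes which end-2 goes with which end-1 (10,000 rewires default), the
permutation mean serving as the expected HOT–HOT count.

## Loop domains

Each intrachromosomal interaction yields a marks × 30-bin profile: ten
equal bins between the anchors' inner edges and ten per flank, each flank
one inner-span wide — so all thirty bins share one width ("equally
sized"). Loops with inner span < 30 bp are flagged degenerate and
excluded. Normalization divides each mark by its total signal, then
z-transforms every interaction × mark row across the 30 bins (constant
rows become zeros); the z-step is idempotent. The recipe is
reconstructed — divide-by-depth then per-row z — and pluggable.

k-means with k = 8 clusters the flattened profiles; since a loop has no
intrinsic orientation, clusters whose centroid correlates > 0.7 with
another's left-right mirror are merged greedily (best pair first), and
final groups are renumbered by increasing median loop length. The 0.7
cutoff is a design choice; the merge rule is exposed.

## Networks and hierarchy

Proximal edges: TF peak inside a symmetric promoter (TSS ± 5 kb). Distal
edges: TF peak at one anchor, promoter at the other, promoter–promoter
interactions excluded. The combined network is the exact edge union;
multiple peaks collapse to one unweighted edge. Promoter definitions are
module-local: networks use ±5 kb, expression analyses use the 2 kb
upstream strand-aware window.

The TF-only hierarchy assigns each node a tier in {1, 2, 3}; the
objective counts downward edges (tier(u) < tier(v)); lateral edges are
ignored, not penalized. Annealing: initial temperature calibrated so
~80% of sampled random moves would be accepted, 3 × |nodes| single-node
moves per level, geometric cooling at 0.95, stop after three levels with
no acceptance; each run tracks its best-seen state, five independent runs
are built and the best kept. On networks of ≤ 7 nodes this matches the
exhaustive 3^n optimum in ≥ 95% of seeded runs (regression-tested).

## Expression and GO

Cell-specific genes: strictly > 10 RPKM in the focal line and ≤ 10
everywhere else; broad: > 10 in all lines (threshold configurable, the
boundary is strict). A gene looping to several distal elements appears in
every corresponding state set. Pairwise state comparisons use two-sided
Wilcoxon rank-sum tests.

GO enrichment is classic per-term Fisher (one-sided, enrichment) with BH;
default filter q < 0.05 and fold > 1.2. The proximal-vs-distal comparison
reports log2(p_proximal / p_distal) per TF × term with p floored at 1e-300,
restricted to TFs with targets in both networks: negative = stronger
proximal enrichment, positive = stronger distal enrichment (the sign
convention is a one-line flip).

## Synthetic data: what it emulates, and what not

The generator reproduces the statistical structure the analyses assume:

* background PETs start at a random peak and jump a distance drawn by
  inverse CDF from p(d) ∝ d^(−α) truncated to [10 kb, 5 Mb], α = 1.2 —
  matching the heavy-tailed contact decay; verified by KS test against an
  independent sampler;
* planted loops are Poisson(λ) PETs per pair, λ = 10 by default, between
  anchors sampled uniformly among eligible same-chromosome pairs;
* duplicates (exact copies, 5%) and self-circularization PETs (both mates
  in one peak, convergent, 5%) exercise the filters;
* companion tracks carry planted, recoverable signal: promoter anchors
  alternate E/R distal partners with an 8-fold expression boost for
  E-looped genes; architectural factors (RAD21, CTCF, ZNF143, SMC3) are
  planted at 90% of loop anchors; HOT regions are anchors bound by ≥ 4
  factors; histone coverage is 5-fold elevated inside half the loops; the
  first promoter genes carry the TF names so TF→TF edges exist;
* the two-condition design gives shared loops equal rates, specific loops
  a fold-change excess (4× default) in their condition, and removes RAD21
  at 10% of anchors (outside specific loops) in condition B.

Defaults are the desk-scale study conditions used throughout the tests
and the acceptance script: a 10 Mb single-chromosome genome, 300 peaks of
2 kb, 150 planted loops, 100,000 background PETs. The two-condition runs
use 200 shared + 50 specific loops at these defaults.

The generator does *not* emulate read-level artifacts (linkers,
alignment, mappability), inter-chromosomal contacts, peak-calling noise
(peaks are known), overdispersed loop counts, or genome-scale anchor
numbers. Passing tests therefore demonstrate correctness of the
algorithms and their statistical calibration under the stated model — not
robustness to misaligned reads, copy-number artifacts or the full
distance dynamics of a mammalian genome.

## Numerical and degenerate-input choices

* All randomness flows from one integer seed through named, CRC-derived
  substreams, so stage order never perturbs another stage's draws and
  every output file is byte-identical across runs.
* Distance bins are recomputed per data set from the observed range;
  pairs outside the binned range belong to no bin's universe.
* Bin SDs are population SDs; pooled bins aggregate sums and sums of
  squares, not per-bin averages.
* Empty inputs return empty tables rather than erroring wherever the
  semantics are clear (no calls inside the 5C tested region reports NaN,
  not an error); genuinely unusable inputs (empty anchor set, zero
  library size, grid larger than the data) raise with the remedy named.
* Permutation p-values use the (1 + k)/(1 + n) estimator and so never
  return zero.
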