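# Methods

## Scope and data model

`nipkit` operates on three objects: a protein universe 𝒫 (id → amino-acid
sequence over the 20 standard residues), an undirected positive
interaction set ℰ over 𝒫, and optional per-protein subcellular
compartment labels. Pairs are always stored canonically (lexicographic id
order), with self-pairs and duplicates rejected at the boundary. Proteins
containing ambiguous residue codes (B, J, O, U, X, Z) are rejected at
load with a warning rather than silently assigned invented property
values, and proteins shorter than 50 residues are filtered by default:
they carry little interaction-relevant signal and break the encoder's
lag-30 precondition (minimum usable length is 31; the default filter at
50 is deliberately stricter).

## Sequence similarity

The raw similarity `bl(i,j)` is the optimal global (Needleman–Wunsch)
alignment score under BLOSUM50 with affine gaps, gap open 10, gap extend
0.5 (a gap of length L costs `open + (L−1)·extend`; end gaps are
penalized like internal ones). Global rather than local alignment was
chosen because the downstream descriptor summarizes whole sequences, and
the penalties are the standard protein defaults; both the matrix and the
penalties are configurable, and matrices in NCBI text format can be
loaded from disk. Scores are normalized row-wise,

    bl~(i,j) = (bl(i,j) − min_k bl(i,k)) / max_k bl(i,k),

with min and max over the full row including the self-score. This form
is applied literally: because the denominator is the row maximum rather
than the max–min range, normalized values are only guaranteed to lie in
[0,1] when the row maximum is positive and dominates; rows whose maximum
is 0 are rejected as degenerate. The row-wise form is asymmetric, so pair
ranking uses the symmetrized mean `s(i,j) = (bl~(i,j) + bl~(j,i))/2`.
The full table for k proteins costs k(k+1)/2 alignments (symmetry
exploited, self-scores computed once).

## Degree profiles

The degree profile of any pair set records the per-protein degrees, the
maximum degree, the average repeatability `r = Σᵢ(d(i)−1)/n` (lower r =
broader protein coverage = better generalization), and two histograms
over the nine half-open degree bins (0,10], (10,20], (20,30], (30,50],
(50,70], (70,80], (80,100], (100,150], (150,∞): the fraction of
*proteins* per bin and the fraction of *pair endpoints* per bin. The
half-open convention partitions all positive degrees without gaps.
Negative-set quality is judged by the absolute per-bin difference of the
pair-endpoint proportions from the positive profile, the max-degree cap,
and r.

## NIP-SS: low-similarity negatives under degree control

Candidates are all non-positive pairs over the universe, sorted by
ascending s (ties broken by canonical pair order); the `m` lowest form
the pre-selection (`m = 5 × target` by default — large enough to leave
room for degree adjustment). Selecting the `target` lowest-s pairs
outright concentrates on a few extremely dissimilar hubs, which inflates
apparent accuracy; degree control removes that artifact. The selection
works in three stages:

1. **Quota assignment.** The positive degree multiset is rescaled so it
   sums to `2 × target` and assigned largest-first to candidate proteins
   ordered by their incidence in the pre-selection (ties shuffled by the
   seed), each quota capped at the positive maximum degree. Using the
   positive degree multiset itself (rather than sampling from it) makes
   the target degree distribution exact by construction; assigning large
   quotas to high-incidence proteins makes them realizable.
2. **Selection.** An ascending-similarity scan accepts pairs whose
   endpoints are under quota, incrementing all quotas by one (still
   capped) and rescanning on shortfall. If the scan's realized bin
   profile deviates from the positive profile by more than the tolerance
   (default 0.05 absolute per bin), a quota-first pass is tried instead:
   repeatedly serve the protein with the largest remaining quota and pair
   it with its lowest-s unused partner; this realizes hub quotas that the
   plain scan starves. The better-matching result is kept.
3. **Repair.** While any bin still deviates beyond tolerance, a bounded
   local search exchanges one selected pair for one unused candidate pair
   whenever the exchange strictly reduces the L1 distance between
   realized and expected per-bin endpoint counts (at most `2 × target`
   swaps; swap candidates ranked by individual error reduction, with
   low-s additions and high-s removals preferred). Residual deviations
   are logged in the provenance record, not fatal.

With `tolerance = ∞` the whole mechanism is bypassed and the result is
the pure ascending-s ranking — the uncontrolled variant, useful for
quantifying the bias that degree control removes. The output is sorted
by ascending s, disjoint from the positives by construction, and
deterministic given the seed. Class ratios other than 1:1 (e.g. 1:2,
1:3) are supported via `target_count`/`--ratio`; note that matching the
positive degree distribution becomes intrinsically harder as the
negative set outgrows the positive one (the quotas are scaled up, which
shifts the achievable bins), so larger ratios log larger residual
deviations.

## NIP-RW: random-walk negatives

Within-k-step reachability is computed on the full positive network by
iterated boolean matrix products (`R_k = sign(Σ_{t=1..k} Eᵗ)`), which is
overflow-free for any k and makes every positive pair reachable at k ≥ 1
by construction. "Within k" rather than "exactly k" matches the
motivating intuition that only pairs *not connected by any short walk*
are credible negatives. Because E is sparse, raw `R_k = 0` pairs are
biased toward low-degree proteins; the sub-matrix restricted to the `p`
highest-degree proteins counteracts this (how the sub-matrix proteins
are chosen is this package's convention; ties break lexicographically so
the choice is deterministic). Candidates — zero entries of the
sub-matrix — are sampled uniformly without replacement with the given
seed. Defaults `k = 3` and `p = ⌈n/2⌉`. When k approaches the graph
diameter the candidate set empties; the error message reports the
achievable candidate count.

## Baselines

Random pairing samples uniform non-positive pairs over the proteins of
the positive set. Subcellular negatives sample uniform pairs whose
proteins carry different compartment labels (at least two compartments
required), excluding positives. Both share the same determinism and
disjointness contracts.

## Auto-covariance encoding

The seven residue properties ship as a versioned TSV (a test pins its
checksum). Columns are standardized with the *population* standard
deviation (divide by 20): the 20 standard residues are the complete
alphabet, not a sample. A sequence of length l maps to the 210-vector
`AC(lag, j)`, lag 1..30, property 1..7, laid out lag-major
((lag1, prop1..7), (lag2, …), …) so serialized features are comparable
across runs. Sequences must satisfy l ≥ lg + 1. Pairs are encoded in
canonical id order by default; an augmentation flag emits both
orientations (2N rows from N pairs), which removes the classifier's
dependence on the arbitrary canonical orientation.

## Classifier

The two-tower network processes each protein's 210-vector through
identical fully connected ReLU towers (widths 128–64–32), concatenates
the two 32-unit outputs, applies one fused ReLU layer of 32 and a
logistic output unit, and minimizes binary cross-entropy with mini-batch
Adam (learning rate 0.002, batch 1024 — auto-reduced to the dataset
size, dropout 0.6, glorot-normal initialization, optional batch
normalization). These defaults follow the recommended configuration; the
implementation is plain numpy (forward and backward passes written out),
so training is CPU-only and bit-reproducible given the seed. Epoch count
and early stopping (default: up to 100 epochs, patience 10 on a 10%
validation split) are this package's choices. The decision threshold is
0.5. A single-network preset (`concatenated_config`, hidden layers
420–256–32 on the concatenated 420-vector) is provided for
architecture comparisons. `train_linear_fallback` fits scikit-learn
logistic regression on the concatenated features under the same
`predict` contract; it is the default for cross-validation at test
scale.

## Evaluation

ACC, SEN (recall), SPE, PE, MCC and F1 follow the standard
confusion-matrix formulas; `GM = √(SEN·SPE)` summarizes imbalanced
performance; AUC is the Mann–Whitney concordance probability with ties
counted ½ (scikit-learn's `roc_auc_score`). Degenerate cases: precision
with no predicted positives is 0 (with a warning); MCC with a zero
denominator factor is 0; F1 with an empty numerator and denominator
is 0. Cross-validation is stratified and seeded; per-fold metrics are
summarized as mean ± sample standard deviation, and GM is computed per
fold then averaged (computing it from averaged SEN/SPE gives slightly
different numbers; the per-fold convention is the default). A paired
t-test utility over per-fold values supports model comparisons.

## Synthetic worlds

The generator realizes exactly the assumptions the strategies exploit,
nothing more: (1) sequence families — `n_families` random ancestors,
members by seeded point substitution at rate 0.05, ancestor lengths
uniform in 60–400 (≥ 51 so the length filter and encoder precondition
always hold); (2) a planted interactome sampled edge-by-edge with
probability ∝ `(dᵢ+1)(dⱼ+1)·exp(coupling·s(i,j))` — preferential
attachment for degree skew, the exponential term for the planted
similarity→interaction dependence (default coupling 4.0, strong enough
that similarity carries real signal); (3) roughly balanced seven-way
compartment labels; (4) partial observation — the "observed" positive
set is a seeded 70% subsample of the planted interactome, which is what
makes random-pairing contamination by true-but-unobserved interactions
measurable. Defaults: 120 proteins, 6 families, 500 planted edges.

What the generator does **not** emulate: biophysically realistic
sequence evolution (indels, domain architecture, conservation
gradients), assortativity and clustering of real interactomes, noisy or
confidence-weighted edges, and compartment-correlated interaction
propensity. Passing tests therefore demonstrate the pipeline's internal
correctness and that it recovers a planted similarity signal — not
field performance on curated interactome data.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately compact scales
chosen to exercise every property at negligible cost: degree control is
measured on a 200-protein / 600-positive world over 100 selection seeds;
the end-to-end signal check cross-validates five default worlds with the
linear fallback; alignment and encoder oracles use 100 random instances
each. Similarity tables are the only quadratic cost (a 200-protein table
is ~20k alignments, a few seconds); they can be cached to TSV via
`--similarity-cache`. Ties are always broken lexicographically and all
randomness flows through seeded numpy generators, so every artifact is
byte-reproducible. Known limitations: the quota realization is a greedy
heuristic (no optimality guarantee on the total selected similarity
under the degree constraints, though it coincides with the exhaustive
optimum on small instances), the swap repair is bounded rather than
exhaustive, and NIP-RW's candidate space collapses on dense networks or
large k — the error message reports the shortfall rather than silently
relaxing the constraint.
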