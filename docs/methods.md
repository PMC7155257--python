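# Methods

`lintrace` infers maximum-parsimony phylogenies from CRISPR/Cas9 lineage
recorder data: each cell is a row of integer character states (one character
per target cut site, state 0 = uncut, `-` = dropout), mutations are
irreversible (0 → s, at most once per character per lineage), and the founder
is unedited. This note records the models, conventions and numerical choices
the package makes, including the points where the underlying method
description is ambiguous and a convention had to be fixed.

## Character matrices and missing data

Missing entries are a first-class state (`MISSING = -1` internally, `-` in
files; `NA` and `?` accepted on input). State labels are per-character
namespaces. One-hot binarization expands each observed (character, nonzero
state) pair into one binary column; a missing entry expands to missing across
all of that character's columns.

Character compatibility follows the classic perfect-phylogeny criterion: two
binary characters are compatible iff their mutated-cell sets nest or are
disjoint. Cells missing a character are excluded from its set; this is a
convention, not a claim about the data. The multi-state minimum
compatibility distance (cells to remove until every state-pair is
compatible) is solved exactly by subset enumeration up to 12 involved cells
and by a greedy most-violations heuristic above that; the report labels which
path was taken.

## Greedy solver

The greedy solver recursively partitions the cells on the (character, state)
pair carried by the most cells, or, with indel priors q, on
argmin q^(n) evaluated as n·log q to avoid underflow. Mutations carried by
every non-missing cell of a subset are absorbed into the subset's ancestral
string instead of producing a degenerate split, so recursion always makes
progress; subsets with no informative character become polytomies. Cells
missing the split character join the side sharing, on average, the larger
fraction of their mutated states (computed against the observed members of
each side; characters missing in either cell are excluded from the
denominator; a cell with no comparable characters scores 0). All
tie-breaks are deterministic: lowest (character, state) index for splits,
larger subset (then the carrier side) for missing-data assignment.

On data admitting a perfect phylogeny the greedy solver recovers it. The
package tests this in its sharp form: the reconstruction must agree with
every *mutation-witnessed* branching of the generating tree (the truth with
zero-mutation internal edges collapsed, unresolved reference triplets
excluded). Branchings no mutation witnesses are not identifiable from the
matrix by any method, and the simulator produces such edges with
non-negligible probability at realistic character counts, so the raw
uncollapsed comparison is not a meaningful test of the algorithm.

## Potential graph and Steiner ILP

The exact solver embeds the cells in a directed potential graph: layer by
layer, every pair of current source nodes at edit distance strictly below a
threshold d is joined through its latest common ancestor (per character:
agreement keeps the state, disagreement yields 0), with edges weighted by
edit distance; remaining sources are finally connected to the root (all-zero,
or the clade's ancestral string in hybrid subproblems). Missing entries act
as wildcards: they match any state in the LCA (the ancestor inherits the
partner's state) and contribute nothing to edit distance. This approximates
imputation over all possible indels, which is exponential; a variant in which
missing absorbs into the ancestor was evaluated and rejected — it makes the
graph explode combinatorially in the dropout masks at even the smallest
threshold.

The neighborhood optimization raises d from 1 and returns the largest-d
graph whose node count fits the user's cap (default 10,000); if even d=1
overflows, the trivial star graph is returned with a warning. Under the
default simulation regime this selects a mean threshold of about 4 (the
figure depends on whether one reports the threshold of the returned graph or
the first overflowing one; the package reports the former, the smaller of
the two).

The minimum Steiner arborescence is solved as a network-flow integer linear
program (HiGHS backend through `scipy.optimize.milp`): integer flow
variables f_uv in {0..|S|}, binary selection variables b_uv ≥ f_uv/|S|,
flow conservation at Steiner nodes, |S| units leaving the root, and **net**
absorption of one unit per target (in − out = 1). The net form matters: with
gross in-flow pinned to 1, flow cannot route through a target whose state is
ancestral to other cells, and the ILP then provably misses optima (observed
against the oracle on about half of random small instances). The solution
tree is extracted from the *flow-positive* edges — selection variables can
sit at 1 on unused zero-weight edges — with multi-parent ties broken by
smallest weight, then lexicographically smallest parent string, and
duplicate cells attached as polytomies under their shared state node. An
independent Dreyfus–Wagner dynamic program over terminal subsets provides
exact optima for test instances (≤ ~10 targets).

## Hybrid solver

Greedy recursion stops at subsets of at most `cutoff` cells (default 200;
benchmarks here use 50 with small neighborhood caps and per-subproblem time
limits). Each stopped subset becomes an independent Steiner instance rooted
at its accumulated ancestral string, and the resulting subtree is grafted in
place of the placeholder node; merging is order-independent. If a
subproblem's ILP fails, or its tree scores worse than plain greedy on the
same subset (possible when a small neighborhood cap truncates the potential
graph), the greedy subtree is kept and the event logged. A corollary is that
the hybrid tree is never less parsimonious than the greedy tree.

## Simulator

A full binary tree of `depth` divisions is grown from an unedited founder;
after each division, each still-uncut character of each daughter mutates
with its per-generation probability (scalar or per-character), drawing the
new state from the character's state distribution; `round(2^depth ·
subsample)` terminal cells are sampled uniformly without replacement; each
entry then drops out independently with its character's rate. Per-character
dropout rates are Beta-distributed around the requested mean (concentration
10) when only a mean is given. All randomness flows from one seed. The true
tree is returned pruned to the sampled cells with single-child chains kept,
so node depth equals generation.

State distributions: raw value = θ·Unif(0,1) + (1−θ)·F', normalized to sum
to the mutation probability p. The skewed family F' is the NB(5, 0.5)
probability mass over randomly permuted state labels (rescaled to mean 1/2
so the mixture components share a scale): like empirical indel-formation
spectra it is heavy-tailed — a few outcomes dominate, most are rare — and
its normalized draws carry visibly less entropy than uniform ones. It
replaces a spline fit to real indel frequencies that cannot be reproduced
without the original dataset; this is the main respect in which simulated
data are cleaner than real data, along with i.i.d. per-entry dropout (no
heritable resection signal) and strictly synchronous divisions.

Default regime (the benchmarking conditions): 40 characters, 40 states,
depth 11, p = 2.5%/character/generation, mean dropout 17%, 400 sampled
cells. Presets: base editor (characters × states = 400, p = 1.04%, 10%
dropout, depth 10) and phased recorder (50 characters in blocks of five with
m_i = p0(1 + e·⌊i/5⌋), characters counted from 1 so the max/min rate ratio
is 1 + 10e). Infinite-alleles mode (`unique_states`) gives every mutation
event a fresh state, guaranteeing a perfect phylogeny; near-perfect
phylogenies are made by injecting k parallel events at a chosen depth (the
same new-character mutation on two cousin edges).

## Evaluation statistics

*Parsimony.* Arbitrary topologies are scored by first computing the minimal
irreversible ancestral labeling: per character an internal node is labeled s
iff every non-missing leaf below carries s (missing leaves never break a
subtree), else 0; a state shared by all leaves labels the root and its
origin is counted on an explicit unedited founder edge grafted above. This
labeling attains the true minimum (verified exhaustively on small trees);
parsimony is the total mutation count over edges.

*Triplets correct.* A triplet is correct when its outgroup matches between
trees; depth is the true-tree root-to-LCA distance. Triplets are sampled
per depth (the budget split evenly across depths, nodes weighted by the
number of triplets they anchor) rather than uniformly: uniform sampling
leaves single-digit counts at the deep strata, which the thresholded
statistic then averages as pure noise. The thresholded score averages
depths where the true tree has at least 20 nodes; the unthresholded score
averages all sampled depths. Polytomies: strict mode requires matching
unresolved verdicts; skip mode (used against mutation-collapsed references)
excludes reference-unresolved triplets.

*Clade statistics.* A horizontal cut at the shallowest depth yielding the
requested clade count (leaves above the cut count as their own clades)
feeds a clade × label contingency table; meta purity is its chi-squared
statistic (no p-value), and mean majority vote is the mean majority-label
fraction, ranging from 1/|labels| to 1.

*Distances.* Allelic distance per character: equal adds 0; differing with a
0 or missing on either side adds 1; two different nonzero states add 2;
normalized by 2m. Phylogenetic distance is the mutation-weighted path
length between leaves, normalized by the tree diameter.

*Bootstrap.* Characters are resampled with replacement per replicate;
downstream trees should have single-child nodes collapsed
(`collapse_singles`, branch lengths add, mutation sets union).

*Neighbor joining baseline.* Dissimilarity = identity mismatch fraction
over all one-hot binarized columns, with the missing marker treated as an
ordinary symbol (missing == missing is a match) — the dialect of the
published baseline; note this makes dropout patterns contribute to the
distance. An all-zero pseudo-cell is appended, the tree is rooted at its
attachment point and the pseudo-cell removed. The joining itself uses
scikit-bio.

## Parallel-evolution theory

For a full binary tree of height h with per-generation mutation probability
p and conditional state probability q, X counts the independent origins of a
particular mutation and Y its leaf frequency. All moments are evaluated as
exact finite geometric sums over depth indices (not the expanded closed
forms, whose printed versions contain typos and a removable p = 1/2
singularity): a mutation on the edge ending at depth t contributes 2^(−t)
to Y, and two edges below a depth-d ancestor co-mutate with probability
p²q²(1−p)^(d+l+k). E(X) agrees with the printed special case 2pqh at
p = 1/2; E(Y) = q(1−(1−p)^h). The Var(X) bound applies the one inequality
of the published chain to the exact pair sum, reading the base as the
positive 2−2p. The Markov-chain validator tracks unmutated cell counts
(N_{t+1} = 2N_t − A_t, A_t ~ Bin(2N_t, p), B_t ~ Bin(A_t, q)) with
Y = Σ 2^(−t) B_t — the exponent convention fixed by matching E(Y) on small
trees by enumeration (the alternative 2^(t−h) weighting gives Y > 1).
Cov(X, Y) diverges to −∞ with h exactly when p < 1 − 1/√2 ≈ 0.29 and
converges to a positive constant above it; the numerical scan classifies a
rate as divergent when the covariance is negative at the tallest heights
with growing magnitude.

## Allele tables

Indel priors: q_s = (#intBCs where s was seen in ≥1 cell) / (#intBCs).
Mutation rate: p = 1 − (1 − K/n)^(1/d) with K the mean mutated-character
count per cell scaled from the *observed* (non-missing) entries — using the
raw count would bias the rate down under dropout — and the exponent is the
inversion 1/d (the printed d does not invert the stated model). Clone
calling iteratively seeds clones with the intBC shared by the most
unassigned cells (lexicographic ties) until ≤ 0.5% of cells remain (junk),
then drops intBCs below 10% prevalence per clone. Intra-doublet score:
fraction of UMIs on non-plurality alleles per intBC. Inter-doublet
membership: prevalence-weighted intBC overlap with each clone, normalized
across clones. The decision rule is grid-searched over thresholds 0, 0.05,
…, 1.0 maximizing the F-measure of dataset-averaged precision and recall;
score orientation is "larger = more doublet-like" (pass 1 − m' for the
membership statistic). The synthetic allele-table generator uses clones
with disjoint intBC sets (optional leak), per-(clone, intBC, site) indels
that are clonally fixed with probability 1/2 and cell-private otherwise
(so merged same-clone cells do conflict), geometric-decay state
probabilities, 5% detection dropout and log-normal UMI counts.

## Problem sizes and limitations

Benchmark-style checks run at the regimes above with 10 replicates for the
method-ordering comparison (hybrid at cutoff 50, 200-node caps, 5 s ILP
limits), 2–5 replicates for the neighborhood-stability scan, and 1e5
Monte-Carlo replicates for the theory validation; these sizes are the
package's chosen trade-off between statistical resolution and runtime.
Known limitations: the ILP tolerates, but does not enumerate, co-optimal
trees (extraction tie-breaks are deterministic but arbitrary); the wildcard
treatment of missing data is an imputation heuristic, not marginalization;
the simulator's synchronous binary divisions ignore cell death and
asynchrony, so absolute accuracy numbers on simulation should be read as
upper bounds relative to real experiments.
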