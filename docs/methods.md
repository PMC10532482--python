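# Methods

This note documents the models and numerical conventions implemented in
`its2delimit`, the choices made where the design was genuinely open, and
what the synthetic data does and does not establish.

## Secondary-structure prediction (`folding`)

Structures are predicted by exact dynamic programming over nested
canonical pairings ({AU, UA, GC, CG, GU, UG}), maximising a simplified
nearest-neighbour objective: pair rewards GC = 3, AU = 2, GU = 1, a +1
bonus for each stacked pair (both (i,j) and (i+1,j−1) paired), hairpin
loops of at least `min_loop = 3` unpaired bases, no dangles and no
Turner free-energy tables. IUPAC ambiguity codes are unpairable.
Ties are broken deterministically in the traceback (pair the leftmost
base, to its furthest partner first; prefer stacked continuations), so
output is bit-stable across platforms. `brute_force_fold` enumerates
every nested canonical structure for sequences up to 18 nt and is the
independent oracle: the DP provably attains the same optimum score; on
co-optimal structures the enumerator returns the lexicographically
smallest dot-bracket, which may differ from the DP traceback.

This model is intentionally not a thermodynamic predictor. Its optima
are structurally sensible (GC-rich stems, open loops) but an energy
model with a rich co-optimal landscape responds discontinuously to
single substitutions. Workflows that need stable, thermodynamically
grounded structures should supply them in Vienna format
(`read_vienna`, `PipelineConfig.structures`), exactly as the original
workflow treated externally folded structures as inputs.

## Distance tables (`distances`)

**AF (structure) distances.** Default is the global edit distance
between dot-bracket strings (match 0 / substitution 1 / indel 1;
arbitrary costs supported), which handles unequal lengths; unit costs
are computed with edlib, other costs with an explicit dynamic program
cross-checked against it. The base-pair set distance |P_a Δ P_b| is
available for equal-length structures.

**AB (model) distances.** Computed on MSA columns with pairwise
deletion (sites with a gap or ambiguity in either row are excluded —
preserving signal in length-variable ITS2). JC69 and K80 use their
closed forms. F84 follows the DNADIST convention: pairwise maximum
likelihood under the F84 model with empirical base frequencies and a
*fixed* expected transition/transversion ratio (default 2.0). The F84
transition probabilities use the exact two-process closed form (a
general replacement process plus a within-purine/pyrimidine process),
with rates solved from the requested ratio and scaled to one expected
substitution per site per unit branch length. With uniform frequencies
and ratio 0.5 the within-group process vanishes and the estimator
reduces exactly to JC69, which the tests exploit as an oracle alongside
an independent grid search of the same likelihood. Saturated pairs
raise an error naming the pair, or are truncated when a cap is given.

## DISTATIS integration (`distatis`)

Each table is double-centered, `S = −1/2 Ξ Δ Ξᵀ` with
`Ξ = I − 1 mᵀ` (uniform masses by default), normalised to unit first
eigenvalue (MFA norm), and weighted by the Perron eigenvector of the
RV-coefficient matrix, rescaled to sum one. Conventions worth noting:

- `compute_compromise` defaults to the Torgerson convention (squaring
  distances before centering). The *pipeline* defaults to Gower-style
  centering of the raw dissimilarities instead: model and edit
  distances are not Euclidean, and squaring lets the deepest,
  highest-variance entries (near-saturated outgroup and cross-clade
  distances) dominate the compromise quadratically, drowning the fine
  within/between-species contrast. Both conventions are available
  everywhere via `square_first`.
- Because double-centering followed by
  `d⁺_ij = s⁺_ii + s⁺_jj − 2 s⁺_ij` is the identity on the (optionally
  squared) dissimilarities, the compromise distance is exactly the
  α-weighted mean of the normalised input dissimilarities and is
  non-negative even when non-Euclidean inputs make `S⁺` indefinite. The
  negative eigenmass is reported (`negative_eigenmass`); eigenvalue
  clipping is applied only when computing factor scores. For Euclidean
  inputs the compromise is PSD to 1e−8 and the tests assert it.
- With exactly two tables the RV matrix is 2×2 with unit diagonal, so
  α = (1/2, 1/2) always; α becomes informative with three or more
  tables.

## Trees (`trees`)

Neighbor joining is the standard Saitou–Nei agglomeration (Q criterion,
deterministic row-major tie-break); negative branch lengths are clamped
to zero with a warning. On additive matrices it reproduces the
generating tree exactly (tested against path-length matrices of random
trees, and cross-checked against scikit-bio's implementation).

The compromise tree treats each taxon's row of the compromise distance
table as its feature vector, computes Minkowski-p distances between
rows (default p = 2; the exponent is a parameter because only the
metric family is documented for the original run) and applies
single-linkage agglomeration; merge heights become node heights, so
the dendrogram's cophenetic matrix equals scipy's. Supports are plain
bootstrap proportions over column resampling (percent of replicate
dendrograms containing the same leaf set); approximately-unbiased
p-values are deliberately not implemented. The pipeline clusters the
ingroup block only: the dendrogram is rooted by construction, and an
outgroup's large, high-variance distance column would otherwise
dominate every feature profile.

`make_ultrametric` linearly rescales an existing dendrogram to the
target interval (default root height 10, leaves at 0). A
non-ultrametric tree (e.g. NJ output) is first rooted — on the declared
outgroup if given — and each internal node's height is set to the mean
path length to its descendant leaves, clamped to be at least its
children's heights, then rescaled. This is a declared stand-in for the
branching-time assignment of the original workflow, whose exact
semantics are not documented.

## GMYC (`gmyc`)

A delimitation assigns every tip to a cluster; nodes inside clusters
are coalescent events, nodes above them diversification events. During
the interval ending (rootward) at the k-th node age the mixture
intensity is

    b_k = λ_div · s_k^p_div + λ_coal · Σ_j [n_jk (n_jk − 1)]^p_coal

with s_k the number of species lineages and n_jk cluster j's lineage
count, both counted on the tipward side of the interval (backward /
Kingman convention). The log-likelihood is the classical waiting-time
product Σ_k [ln b_k − b_k x_k]: the marginal likelihood of the event
times, in which the tree enters only through the candidate
lineage-count trajectories. This keeps candidate delimitations on a
common footing: a likelihood that additionally models which lineages
merged (the labeled-history density) always rewards splitting — zeroing
cross-cluster coalescent exposure is an unpenalisable gain, the known
pathology of maximum-likelihood delimitation under the multispecies
coalescent — while attributing each event to its own component's rate
alone penalises mixed models by the event-label entropy. Both variants
were implemented and rejected on planted-truth simulations.

Conventions: the root event contributes exposure but is never a
realized event, so every candidate realizes n−2 events and the LR
statistic is invariant to rescaling node heights. Rates and exponents
are optimised jointly (L-BFGS-B with analytic gradients, exponents
bounded to [0.1, 5] for numerical stability) from a closed-form
separable initialisation. Single-threshold candidates place the
threshold at every observed branching time, including the two
single-process extremes (everything coalescent / everything
diversification); the null model is the better of those two, which
also guarantees `best_loglik ≥ null_loglik`. The LR test uses the
upper tail of χ² with df = 3 by default (threshold, extra rate, extra
exponent).

Identical tips (joined at zero age) are collapsed to one representative
before fitting and restored to its cluster afterwards: a point mass of
zero waiting times would let the coalescent rate diverge on zero
exposure — the reason GMYC is conventionally run on unique haplotypes.

Multiple-threshold search hill-climbs from the single-threshold
optimum with split/merge moves on the cluster-root antichain, accepting
moves that improve AIC; each accepted deviation adds one
lineage-specific threshold parameter (k = 5 + deviations). The visited
candidate set feeds the node supports: the support of a node is the sum
of Akaike weights of the candidates in which it lies inside a delimited
entity.

Reporting: `n_ml_clusters` counts clusters with at least
`min_cluster_size` tips. The gmyc functions default to 2; the
pipeline's summary table counts groups with more than two sequences
(threshold 3), matching how the method's delimitation tables are
conventionally captioned. The full partition is always reported.

## CBC analysis (`cbc`)

Structures are projected through each row's gap pattern onto alignment
columns (simultaneous alignment-folding is out of scope). For each row
pair, homologous paired columns in scope (default: the intersection of
the two rows' projected pairs; consensus-structure scope available) are
classified: CBC if both sides differ and both pairs are canonical,
hemi-CBC if exactly one side differs, not-comparable if either side has
a gap, ambiguity code or non-canonical pair. The CBC-zero partition is
the set of connected components of the graph joining pairs with zero
CBCs *and at least one comparable paired column* — a pair with nothing
to compare (e.g. an unstructured outgroup) carries no evidence and is
never "same species" glue. The literature probabilities attached to
verdicts (~0.93 that a CBC pair is heterospecific, ~0.76 that a
CBC-free pair is conspecific) are annotations only, never computed
with. Species-level ranges over sequence pairs are exposed as
min/max/mean without privileging one aggregation.

The consensus structure ranks candidate column pairs by support
(fraction of rows projecting the pair) and accepts greedily subject to
non-crossing, ties broken by higher support, shorter span, leftmost;
default inclusion threshold 0.5. Domains are maximal helices whose
closing pair sits on the exterior loop; subdomains are helices opening
from internal multiloops (a stem whose parent stem has two or more
child stems); an interior-loop continuation is not a subdomain.

## Synthetic data (`synthetic`)

The generator emulates what the pipeline needs from ITS2 families, not
ITS2 biochemistry: a conserved multi-helix scaffold whose stems are
designed GC-rich with A/C loops and linkers (A and C cannot pair, so
designed stems are the dominant fold); a Yule-like species history with
within-species Kingman genealogies; and planted CBCs. Between-species
stems evolve at paired sites under the canonical-pairing constraint
(half compensatory double changes, half single-side changes), at
unpaired sites by JC-style substitution; within-species variation
touches unpaired sites only, which makes "zero CBCs within species"
exact by construction. Planted compensatory events are placed at
species-unique pair positions that are reserved from random stem
evolution, so per-pair planted counts are guaranteed minima.

Defaults (chosen once as realistic for a divergent fungal ITS2 group):
sequence length 260 nt, within-species substitution probability
0.01/site, between-species stems 0.10/site, clade stems 0.15/site, two
planted CBCs per species. The `tulasnella-like` preset has 142 ingroup
sequences in 7 species (30, 24, 22, 20, 18, 16, 12) across two clades
with 4- vs 6-helix scaffolds; clade B shares clade A's four helices and
adds two in regions that are unpairable linkers in clade A, species
additionally differ by helix-length variation on two designated stems,
and one heavily diverged but alignable outgroup is appended. The
GMYC simulation batteries use species depth 10 with within-species
coalescent scale ne = 0.05 (tree depth ≈ 0.1, a deep/shallow contrast
around 50–100×).

Not emulated: indels and alignment uncertainty (rows are generated
pre-aligned), thermodynamic energy landscapes, intragenomic ribotype
variation, and base-composition heterogeneity across lineages. Passing
tests therefore demonstrate correctness of the computations and
recovery under clean, well-separated histories — not robustness to
alignment error or to weak species boundaries.

## Degenerate inputs and numeric details

- Distance matrices must be symmetric (asymmetry ≤ 1e−8 is averaged
  away), finite, non-negative, zero-diagonal.
- Ultrametricity is checked to 1e−6 of tree height; tied node ages are
  ordered deepest-first so threshold prefixes are ancestor-closed.
- GMYC requires a binary tree with ≥ 3 tips (the pipeline resolves
  polytomies with zero-length edges first).
- Saturated model distances raise by default; `--cap` truncates.
- All stochastic stages (bootstrap, simulations) take explicit seeds;
  the pipeline is byte-deterministic given its seed.
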