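# Methods

## Substitution model

The state space is the 61 sense codons of the standard genetic code
(stop codons excluded; other NCBI tables are supported through the
`genetic_code` field). Instantaneous rates follow the Goldman–Yang
parameterization: q_ij = 0 for multi-nucleotide changes, and otherwise
q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]. The chain is
reversible with stationary distribution π, so likelihoods are invariant
to root placement and unrooted trees are represented as rooted trees
with a basal polytomy.

Codon frequencies default to F3x4 — products of the per-codon-position
nucleotide frequencies observed in the data, renormalized over sense
codons, with a half-count pseudocount and a 1e-10 floor so every sense
codon keeps positive mass. Equal frequencies and user-supplied vectors
are also accepted. κ is a free parameter of every fit (bounds 0.2–99,
started at 2).

**Branch-length units.** A branch length is the expected number of
substitutions per codon. For site-class mixtures all classes share one
normalization c = Σ_k p_k μ_k, where μ_k is class k's mean rate at
stationarity, so fast classes genuinely evolve faster than slow ones on
the same branch. Branch models instead normalize each branch's
generator by its own μ(ω_b), so a branch's length keeps the same meaning
whatever ω it carries. dN and dS per branch divide the expected
nonsynonymous and synonymous substitution counts by mutational-
opportunity site counts N and S (N + S = 3 per codon, split in
proportion to the neutral ω = 1 fluxes), which makes dN/dS = ω an
identity rather than an approximation.

## Likelihood computation

Felsenstein pruning over site patterns (identical columns are collapsed
and weighted). Tip states are partial-likelihood indicator vectors: a
plain codon is a one-hot vector, a masked or gapped codon is all ones,
and an IUPAC-ambiguous codon is an indicator over its compatible sense
codons. Per-node rescaling by the maximum partial likelihood guards
against underflow, so any valid input yields a finite lnL.

Transition matrices are computed two ways, selectable per evaluator:

* `eigen` (default, used inside optimization): spectral decomposition of
  the symmetrized generator, cached per (κ, ω), with all branch lengths
  exponentiated in one batched operation. Absolute error is ~1e-14 per
  entry, but entries of order 1e-10 (nearly-impossible changes on short
  branches) lose relative accuracy to cancellation.
* `expm` (used by `alignment_log_likelihood` for direct evaluation):
  scipy's scaling-and-squaring per unique branch length, which preserves
  small entries; direct evaluations agree with exhaustive enumeration
  over internal-node states to ~1e-12 in total lnL.

The two backends agree far beyond optimizer tolerance, so fits may use
the fast path while reported likelihood evaluations use the precise one.

## Site-model fitting

Model definitions: M0 (one ω); M1a (ω₀ ∈ (0,1), ω₁ = 1); M2a (adds
ω₂ ≥ 1); M7 (ω ~ Beta(p, q)); M8 (proportion p₀ beta, p₁ at ωs ≥ 1);
M8a (M8 with ωs ≡ 1). The beta is discretized into K = 10 equal-weight
classes whose ω values are the conditional class means (a median rule is
available); class means integrate exactly to p/(p+q), and values are
clipped to [1e-8, 1−1e-8], which perturbs extreme U-shaped betas by at
most ~1e-5.

The outer optimizer is bounded L-BFGS-B over (κ, the model's ω or beta
shape parameters, and a global branch-length scale), run from a small
set of deterministic starting points; models with a positive class start
the extra ω at 1.05, 2 and 5, so a near-boundary start always brackets
the nested null. Mixture proportions are not outer parameters: at every
objective evaluation they are profiled out by EM, which is exact because
the log-likelihood is concave in the weights (M8's constraint that the
K beta categories share p₀ equally is handled by grouping them as one
EM component). Callers can supply extra starting points; the pipeline
warm-starts each alternative (M2a, M8) from its fitted null's optimum
(M1a, M8a), which guarantees the LRT statistic is nonnegative up to
optimizer noise. Non-convergence flags the result instead of raising.

**Branch lengths.** Within a fit, input-tree branch lengths are scaled
by a single fitted factor (reported, after normalization, in expected
substitutions per codon). Relative branch lengths are treated as part
of the tree input, which every analysis here receives as fixed; the
scientific quantities are the mixture parameters and per-class ω
values. Each model still fits its own scale, so scales are not shared
across models. Full per-branch re-optimization is deliberately not
implemented: it multiplies fit cost by roughly the branch count while
leaving the mixture estimates essentially unchanged when the input tree
was estimated from the same or closely related data.

Parameter counts: M0 3, M1a 4, M2a 6, M7 4, M8 6, M8a 5 (κ and the
scale included; degrees of freedom for tests are always supplied
explicitly by the caller).

The reported "average ω" of a fit is the mixture-weighted mean
Σ_k p_k ω_k.

## Posterior probabilities of positive selection

NEB evaluates P(site ∈ ω>1 class) at the MLEs: p_k L_k(site) / Σ_j p_j
L_j(site). BEB averages that posterior over a uniform discrete prior on
the mixture parameters, with κ and branch lengths fixed at their MLEs:

* M2a: (p₀, p₁) on a 10-point-per-dimension triangle grid,
  ω₀ ~ U(0,1) and ω₂ ~ U(1,11) on 10-point midpoint grids — the full
  published construction.
* M8: p₀ ~ U(0,1) and ωs ~ U(1,11) on 10-point grids, with the beta
  shape parameters held at their MLEs. This is a reduced grid relative
  to the full construction (which also integrates over p and q); the
  beta shapes are typically well determined by the several hundred
  sites that inform them, and the reduction keeps the grid at 100
  rather than 10⁴ likelihood-table combinations.

Sites are called positively selected at posterior ≥ 0.95 (inclusive),
reported as 1-based indices on the analyzed alignment. Site numbering
always refers to the alignment actually analyzed; mapping to a
reference protein's coordinates is left to the user.

## Branch models and root-to-tip statistics

Foreground selection modes: `stem` labels the branch subtending the
target clade's MRCA; `clade` labels the stem plus every branch inside;
`terminal` labels one tip branch. Non-monophyletic targets are rejected
with the intruding tips named. The free-ratio model labels every branch
distinctly; its LRT against M0 uses (#branches − 1) degrees of freedom
(21 branches, hence 20 df, for a 12-taxon tree with a basal trichotomy).
Branch fits share κ and the scale across label classes; free-ratio fits
use a single neutral-ish start (the objective is smooth and
high-dimensional), two-ratio fits use two.

Root-to-tip statistics fit a two-ratio model whose foreground is every
branch on the path from a designated ancestor to one tip, with all other
branches — including any outgroups — as a single background class. The
path ω is the fitted foreground ratio; path dN and dS are per-site rates
summed over path branches. A path with no synonymous opportunity (e.g.
zero length) is flagged undefined rather than yielding an infinite ω.
An alternative branch-length-weighted mean of per-branch ω values is
available in the simulator's truth accounting
(`root_to_tip_true_omega`) and serves as the generative counterpart.

## Model comparison

The LRT statistic is 2·(−lnL_null − (−lnL_alt)) with a χ² upper tail at
the caller's df. Negative statistics within 1e-3 (optimizer noise) are
clamped to zero with a flag; larger negatives raise an error that
prompts refitting — the nesting inequality must hold mathematically.
The halved-p boundary convention applies only where the null pins a
parameter at the alternative's boundary (M8a inside M8); at df = 2 the
tail has the closed form p = exp(−x/2), which the tests use as an
internal oracle. Bonferroni control returns α/m and the significance
flag uses p ≤ α/m.

## Comparative regression

EQ = brain / (0.12 · body^0.67), masses in grams. PGLS is generalized
least squares with residual covariance C[i,j] = depth of the MRCA of
species i and j on the time tree (pure Brownian motion, Pagel's λ = 1;
λ estimation is out of scope). Log transforms are base 10 throughout
and are applied by the battery code, not by `pgls_fit`. One-tailed
p-values use the t distribution with n − k − 1 df in the stated
direction; positive and negative one-tailed p-values of the same fit
sum to 1 by construction. With an identity covariance (star tree with
equal depths) the estimates reduce to OLS at machine precision. A
constant response is handled as a degenerate case (all slopes 0, t = 0,
R² = 0) rather than dividing by a zero variance. R² values outside
[0, 1] (possible in GLS) are clipped.

The association battery's panel A regresses log₁₀ root-to-tip ω on each
of four log₁₀ traits (brain, EQ, body, maximum body mass), one-tailed
positive, per scope (all species / a configured subset such as toothed
whales). Panel B regresses log₁₀ body and brain mass on log₁₀ dN and
log₁₀ dS jointly, testing dN one-tailed positive and dS one-tailed
negative; the reported df makes the predictor count explicit. Species
with undefined root-to-tip ω or missing phenotypes are dropped with a
record; scopes below 4 species are errors.

## Within-species variation

Heterozygote calls are two-base IUPAC codes; codes resolving to three
or four bases are excluded with a warning. Each distinct (site, allele
pair) becomes a presence/absence character optimized on the gene tree by
a Sankoff dynamic program (unit cost per state change; exact on any
tree including polytomies), so an allele pair shared by sister species
costs one origin on their stem. The ancestral base of a pair is the one
observed in homozygous form in the rest of the alignment column (ties
fall to the alphabetically first). Changes are classified by codon
position, transition/transversion, and effect via translation of the
ancestral and derived codons; changes creating a stop are flagged
`nonsense`. Species with two sequenced individuals contribute each
distinct allele pair once.

The divergence side of the contrast takes expected per-branch
nonsynonymous and synonymous counts from an M0 (or any branch-model)
fit, summed over the clade of interest. The output reports both raw
proportions and whole-percent roundings, plus a two-sided Fisher exact
test on the rounded 2×2 table — explicitly labeled an extension beyond
the descriptive proportion contrast.

## Synthetic data

The fixture tree has 38 tips in seven family-level groups (4 baleen
whales; 23 dolphins, 3 porpoises, 2 monodontids, sperm + dwarf sperm
whale, 2 beaked whales, 2 river dolphins), matching a realistic
cetacean sampling design; branch lengths are fixed, in expected
substitutions per codon (total tree length ≈ 1.6), with an
ultrametricized variant (root age 35) for phenotype covariances.
Clade definitions (Cetacea, Odontoceti, Delphinoidea, Delphinidae,
Mysticeti) are exported as tip sets.

Sequences evolve by exact CTMC sampling — exponential waiting times and
categorical jumps per site per branch — rather than endpoint sampling
through a matrix exponential, so every substitution event is logged and
classifiable; realized nonsynonymous/synonymous event ratios converge
on ω·F_N/F_S and provide an engine-independent oracle. Site classes,
per-branch ω values, event counts and seeds are stored in a truth
record alongside every dataset. Lineage ω heterogeneity evolves as
Brownian motion of log ω along the tree (branch ω = geometric mean of
its endpoint values). Phenotypes are log₁₀ body mass = intercept +
slope·log₁₀(root-to-tip ω) + BM noise on the time tree, with brain mass
generated from body via the EQ allometry times a species EQ deviation —
so the generated EQ column reproduces the EQ operation exactly, and
body, brain and EQ targets are all independently testable. Heterozygote
injection replaces bases with two-base IUPAC codes at a per-codon hit
rate of 1 − (1 − rate)³, never creates a stop-only resolution, and can
bias the synonymous/nonsynonymous mix toward a target fraction where the
codon offers a choice.

What the generator does *not* emulate: indels and alignment error,
sequencing error, intron evolution, selection on synonymous codon
usage, and non-stationary codon frequencies. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators
under their own assumptions, not robustness to real-data artifacts.

## Test problem sizes

Chosen as the package's standard verification workloads: site-model
parameter recovery uses 10 replicates of 38 taxa × 400 codons under
M2a with ω = (0.1, 1, 3) and p = (0.7, 0.2, 0.1); type-I calibration
uses 30 nearly-neutral replicates of 20 taxa × 300 codons for the
M1a/M2a test and 6 replicates of 12 taxa × 150 codons for the boundary
M8a/M8 test, each judged against 0.05 plus twice the Monte-Carlo
standard error of the replicate count; the exhaustive likelihood oracle
runs 100 random instances of ≤ 5 taxa × ≤ 25 codons (≤ 3 internal
nodes, so full enumeration stays tractable); PGLS slope recovery uses
20 Brownian datasets of 27 species with true slope 0.5.

## Known limitations

* No branch-site or clade models, no gamma rate variation on the
  synonymous rate, no λ/κ/δ branch-length transformations in PGLS.
* Branch lengths are optimized only through a global scale per model.
* The M8 BEB grid holds the beta shapes at their MLEs (see above).
* Posterior-informed (rather than stationary-expectation) per-branch
  substitution counts are not implemented; expected counts condition on
  the fitted rates, not on the observed site patterns.
* The chromatogram side of heterozygote calling is upstream of this
  package: inputs are the resulting ambiguity codes.
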