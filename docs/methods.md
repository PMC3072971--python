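# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `spiculevo`, in the spirit of the methods documentation of
mature statistical packages.

## The Mk model and its use here

Each spicule character is a binary presence/absence trait evolving along a
fixed, rooted molecular tree whose branch lengths are expected
substitutions per site. The model is the symmetric k-state Markov chain
("Mk" with a single rate): every state flips to every other state at rate
α, the stationary distribution is uniform, and the transition matrix over
a branch of length t has the closed form

    P_ii(t) = 1/k + (k−1)/k · e^(−kαt),   P_ij(t) = (1 − e^(−kαt))/k.

Assumptions worth stating explicitly:

- **Branch lengths are the time axis.** The character chain runs on the
  molecular branch lengths as-is; zero-length branches give identity
  transitions. No attempt is made to re-scale morphological rates per
  lineage.
- **Symmetry.** Gain and loss rates are equal. This is the model's defining
  simplification; its consequences for loss counting are discussed under
  Limitations.
- **Root prior.** Uniform (1/k), the Mk convention. It is exposed as a
  constructor argument but uniform is the tested default.
- **One rate per character.** Each of the characters is fitted
  independently; no rate sharing across characters.
- **Missing states** (`?`) contribute all-ones partial vectors (summed
  over, the standard treatment).

### Likelihood and reconstruction

The column likelihood is computed by Felsenstein's pruning algorithm.
Partial vectors are rescaled at every internal node by their maximum, with
the log scalers accumulated, so the log-likelihood is exact and does not
underflow on trees of hundreds of tips. Because the transition matrix is
`a·I + b·11ᵀ`, each child message is evaluated in closed form without
matrix products.

The rate MLE maximizes the column log-likelihood by bounded scalar search
on log α over [1e−8, 100] with convergence tolerance 1e−8. A constant
column (≤ 1 observed state) has its likelihood maximized as α → 0 and is
returned at the lower bound with a `constant_character` flag. The rate's
standard error is the inverse square root of the observed information
(central second difference); it is NaN at the bounds or under flat
curvature, which for desk-scale trees is common and honest — a 13 × 89
matrix carries little information about per-character rates.

Marginal posteriors at every node are computed by an outside (root-to-tip)
pass: for node v and state s, P(v = s | data) equals the likelihood with v
constrained to s divided by the total likelihood, which the up-down
recursion evaluates for all nodes in one sweep (equivalent to re-rooting
at every node; the symmetric P makes the reverse propagation identical to
the forward one). Outside vectors are normalized per node, which cancels
in the posterior ratio. Tips are reported as indicators of their observed
state (uniform when missing). Correctness is asserted against brute-force
enumeration over all internal-node state assignments on hundreds of random
small trees at relative tolerance 1e−10.

## Confidence calls and event counting

Posteriors are mapped to tiered calls: `HIGH` when max posterior > 0.95,
`MODERATE` when > 0.65, ambiguous otherwise (thresholds configurable;
the moderate band is read as 0.65 < p ≤ 0.95). With k = 2 and thresholds
above 0.5 at most one state can qualify.

Event semantics are a deliberate formalization of what is usually done by
visual inspection of reconstruction figures:

- a **loss** at tier θ is an edge whose parent is called present and whose
  child called absent, both at tier θ or better; a **gain** is the reverse;
- events are **maximal**: edges deeper inside an already-absent
  (already-present) clade cannot re-qualify because their parent already
  carries the derived call;
- **ambiguous nodes break chains**: no event is counted through them, so a
  present → ambiguous → absent path contributes nothing at either tier;
- the **root** never counts as a gain or loss; when tallying independent
  origins of a state, a root confidently in that state counts as one
  "root origin";
- each event is attributed the **habitat** shared by the descendant tips
  of its edge (shallow / deep), `mixed` when they disagree; species
  recorded in both depth zones are excluded from the attribution and
  `unknown` marks events whose descendants are all such species.

The report also flags edges where one character's loss coincides with
another character's gain (candidate spicule replacements — a "semantic"
rather than "true" loss); no conclusion is drawn from the flag.

## Synthetic data

The generator produces data with the statistical structure the analyses
assume, sized to the study system by default: ~89 species, 13 binary
characters split into 5 megasclere and 8 microsclere types, depth labels
drawn in proportion 43:46 shallow:deep with two dual-zone species, and two
marker partitions of 660 and 864 sites.

- **Trees**: birth–death (default pure-birth, λ = 1) conditioned on the
  tip count by stop-at-n simulation (dendropy's sampler; documented as
  non-uniform over labeled histories), ultrametric, optionally rescaled to
  a root-to-tip height of 0.3 substitutions/site — a typical height for a
  two-marker ribosomal/mitochondrial tree. Randomness: Python's Mersenne
  Twister inside dendropy; everything else uses numpy PCG64. All
  generators are bit-reproducible given (seed, config).
- **Free Mk characters** evolve at rate 1.0 by default (≈ 0.3 expected
  flips per root-to-tip path on the default tree), enough to produce the
  occasional homoplasy without saturating.
- **Planted-loss characters** model rare irreversible losses: a loss lands
  on an internal edge with probability proportional to its branch length
  (the placement distribution of a rare Poisson event), restricted to
  clades of at least `min_clade` tips, disjoint, with each stem's parent
  retaining a present descendant. A selection is accepted only when the
  planted events are the *unique* most-parsimonious explanation of the
  resulting column (Sankoff score and solution count): without this, two
  losses separated by a small present clade are indistinguishable from one
  loss plus one gain and the planted count would not be a well-defined
  ground truth.
- **Alignments** evolve under HKY (κ = 4, base frequencies
  0.192/0.248/0.291/0.270) with a proportion of invariant sites
  (0.367474) and 4-category discrete gamma rates (shape 0.557592,
  equal-probability categories with conditional-mean rates). Variable-site
  rates are scaled by 1/(1 − p_inv) so the overall expected rate is 1 and
  branch lengths keep their substitutions-per-site meaning. Per-branch,
  per-category transition matrices come from `scipy.linalg.expm`.

What the synthetic data does *not* emulate: real spicule characters are
correlated (a sterraster is a kind of euaster), loss may be biologically
irreversible where the Mk model is not, alignments have no indels or
alignment error, and depth habit is drawn independently of the characters
(the clustered mode exists but is not calibrated to any empirical
association). Passing tests therefore demonstrate the correctness of the
machinery under its own assumptions, not the field accuracy of the
biological conclusions.

## The planted-truth experiment

The end-to-end check plants 3 losses (clades ≥ 3 tips) on fresh 64-tip
trees and asks the full call/count chain to recover exactly 3 HIGH-tier
losses. Reconstruction runs at the rare generating rate, 0.01 per unit
tree height — the regime the planted process defines (loss rate ≪ 1/tree
height). Under it, recovery is ≈ 97% over 200 replicates.

With per-character *refitted* rates instead, recovery at the HIGH tier
drops to roughly a quarter of replicates: the symmetric-rate MLE is about
(number of losses)/(total tree length), large enough that alternative
single-change placements (a loss on the parent's own edge plus a
compensating gain) retain posterior weight, pulling stem-parent posteriors
to ~0.85–0.95. This is a real property of symmetric-Mk reconstruction, not
an artifact: confident loss counts from fitted Mk reconstructions are
conservative. Fixture-level checks with fitted rates therefore use the
MODERATE-or-better tier (≈ 93% recovery).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
statistical checks sharp while keeping the whole suite fast: enumeration
oracles on ≤ 6-tip trees (the largest size where brute force is exact and
instant), rate recovery from 500 characters on a 64-tip tree (pooled MLE
SE ≈ 2%, far inside the 10% check), 200 replicates for the planted-loss
and consistency experiments, and the 89-species fixture for end-to-end
runs.

## Other numerical and design choices

- **RF distance** is computed on the unrooted topology (root edge
  collapsed), the standard convention; polytomies simply contribute fewer
  splits. Splits are canonicalized as the block not containing the
  lexicographically smallest tip.
- **Missing branch lengths** parse as 0 with a warning (real trees always
  have lengths; hand-written fixtures may not).
- **Internal node labels** are support annotations, never taxa.
- **Site classification** treats gaps, `?` and IUPAC ambiguity codes as
  missing in all statistics while preserving them in I/O.
- **K2P** uses pairwise deletion (the least destructive option for
  matrices with scattered missing data) and raises a saturation error when
  a log argument is non-positive rather than returning infinity. The
  between-group distance is the arithmetic mean over all cross-group
  pairs — an assumption, since group-distance conventions differ.
- **Concatenation** maps specimen labels to species through an explicit
  merge key, errors when two specimens of one species collide within a
  partition (the caller must pre-select), fills absent species with `?`,
  and records 1-based partition boundaries emitted as a NEXUS sets block.
- **Node ids** are stable postorder integers, so event edges are
  referenceable across runs of the same inputs.

## Known limitations

- Symmetric rates make confident HIGH-tier loss counts conservative (see
  above); an asymmetric or irreversible-loss model is out of scope.
- The rate SE is a curvature estimate and frequently undefined at the
  search bounds; profile or bootstrap intervals are not provided.
- The tree simulator's stop-at-n conditioning slightly biases deep branch
  lengths relative to proper conditioned samplers; for fixture purposes
  this is immaterial and it is documented here for honesty.
- Depth-habit attribution of internal events follows descendant-tip
  consensus; other conventions (e.g. parent-state-weighted) would shift
  `mixed` counts.
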