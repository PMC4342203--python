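# Methods

This note records the models implemented, the estimator and numerical
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trees, ages and conventions

Trees are rooted, with branch lengths in arbitrary units (Myr for dated
trees). Ages are measured backward from the present: age(node) = (maximum
root-to-tip depth) − (root-to-node distance), so tips of an ultrametric
tree sit at age 0 and the root is deepest. There is no calendar anchoring.
Ultrametricity is a flag, not an assumption, except where stated (event
classification requires a dated tree). Polytomies are preserved everywhere;
no operation silently resolves them. Zero-length branches are permitted and
contribute zero to ages and to Brownian variance. All parsing and writing
of Newick and NEXUS (including MrBayes-style translate tables and quoted
labels) is delegated to dendropy; labels are normalised to underscores.

## The D statistic

For a binary trait, nodal values are computed tips-to-root as the
arithmetic mean of child values (tips carry 0/1; polytomies enter the same
recursion), and d_obs = Σ |value(node) − value(parent)| over all non-root
nodes. D rescales d_obs between the mean d under two simulated nulls at the
observed prevalence k: uniformly random placement of the k ones, and a
threshold model in which unit-rate Brownian motion is simulated from root
value 0 (per-branch variance = branch length) and the k largest tip values
receive state 1.

The published description of the statistic leaves the nodal estimator
implicit; the child-mean recursion used here is one consistent choice.
Because D rescales d_obs between null means computed with the *same*
estimator, the calibration endpoints — E[D] = 1 for randomly scattered
traits, E[D] = 0 for Brownian-threshold traits — hold for any consistent
estimator; this is verified directly by the calibration tests rather than
assumed. d_obs itself may therefore differ numerically from other
implementations even where D does not, which is documented here
prominently.

Choices:

- **p-values.** p_vs_random = (1 + #{d_rand ≤ d_obs}) / (1 + n_sim)
  (departure from randomness toward conservation), p_vs_brownian
  symmetric in the other tail. The pseudocount keeps a finite simulation
  from reporting p = 0; the floor at n_sim = 1000 is ~0.001.
- **n_sim defaults to 1000** per null scenario.
- **D is unclamped**: over-dispersed traits give D > 1, extreme clumping
  D < 0 (a trait filling exactly one half of a balanced 16-tip tree gives
  D < −1); both are reported as computed.
- **Thresholding ties** are broken uniformly at random from the
  operation's seed stream so prevalence is always exact (ties have
  probability zero for continuous Brownian values but the rule is defined).
- **Degenerate inputs**: constant traits are rejected (signal undefined at
  prevalence 0 or n); when |mean d_random − mean d_brownian| falls below
  1e-9 × mean d_random (e.g. on a 2-tip tree, where both nulls force
  d = 1) the scaling is refused with a suggestion to use a larger tree.
- **Missing states**: `missing_policy` selects erroring (default), pruning
  unscored tips, or scoring them 0 — the latter matching a "0 = no
  reported use" reading; which is appropriate depends on whether absence
  of data means absence of the trait.
- **Branch-length scale invariance**: multiplying all branch lengths by a
  constant rescales Brownian values by a rank-preserving factor, so D is
  unchanged (tested exactly under a shared seed).

Over a posterior tree sample, per-tree D and p are summarised by medians
and 2.5/97.5 percentiles; trees on which the computation fails are counted
and excluded.

## Parsimony

The bottom-up pass is the multifurcating extension of Fitch's method: a
node's state set contains the states occurring in the maximum number of
child sets; the cost increment is the number of children whose set lacks
such a state. The minimum change count is cross-checked internally against
a unit-cost Sankoff dynamic program (and externally, in the tests, against
exhaustive enumeration over all ancestral assignments on trees ≤ 10 tips).

Change polarity depends on the reconstruction, so gains and losses are
reported as min/max over all most-parsimonious reconstructions, computed by
carrying (min, max) gain counts through the Sankoff recursion over optimal
child choices; losses follow as min_changes − gains. Committing to a single
resolution was deliberately avoided as the default because the polarity of
ambiguous changes is not identifiable; an ACCTRAN-style resolution
(ambiguities resolved toward change, i.e. transformations accelerated
rootward; ambiguous root resolved to state 1) is available for users who
need one concrete history. Parsimony minima are lower bounds: the Mk
simulator's realised change counts always weakly exceed them, which is
tested per replicate.

## Pairwise comparisons

Pair selection is a greedy postorder sweep: at each internal node, tips
still unpaired in different child subtrees with contrasting predictor
states are matched, chosen uniformly at random among all available
cross-child matches; a child subtree that contributes a tip has its stem
edge consumed, so its remaining tips are excluded from pairing above the
node. This yields edge-disjoint connecting paths (asserted structurally on
every selection), linear-time maximality for the greedy order, and full
seedability. The selection rule is not uniquely determined by the
published description ("randomly selected sets of pairwise comparisons");
greedy-with-random-matching was chosen as the simplest seedable scheme
that is maximal for binary contrasts.

The sign test uses informative pairs only (dependent states differ and are
both scored): one-tailed p = Σ_{i=k}^{n} C(n,i) 2^{−n} with n informative
pairs and k concordant in the tested direction (default: the dependent
trait follows the predictor; direction −1 flips the tail, which equals
testing n−k). Zero informative pairs yields a flagged result, not an
exception. Aggregation over n_sets random pair sets (default 100) and over
a tree sample reports medians; the mean and full per-set distribution are
retained. The sign test is discrete and therefore conservative: its
realised size at α = 0.05 is below α, which the size simulation verifies.

A variant anchoring pairs specifically on parsimony-inferred predictor
transitions was considered and not implemented: every edge-disjoint
contrasting pair already spans at least one predictor change on its path,
and the exact historical procedure such a variant would need to reproduce
is not recoverable; the uncertainty is instead propagated by randomising
pair sets.

## Exact 2×2 test

Fisher's exact test is computed by full enumeration of the hypergeometric
support in exact rational arithmetic, with the conventional
minimum-likelihood two-sided rule (sum of the probabilities of all tables,
margins fixed, whose point probability does not exceed the observed
table's). Rational arithmetic makes tie handling exact and the returned
p-value correct to full floating precision; the tests cross-check against
an independent implementation (scipy's) to 1e-12 on a thousand random
tables. The odds ratio reported is the sample odds ratio ad/bc. Two-sided
was chosen because the source analyses do not state sidedness; this is
flagged in the API documentation. Missing trait values are excluded
pairwise from cross-tabulations, with the excluded count reported.

## Biogeographic event classification

Cladogenetic rules, applied at each internal node of a dated bifurcating
tree: a single-area ancestor copied to both descendants is within-area
speciation; descendant ranges that are disjoint and union to the ancestor
are vicariance; one descendant keeping the full ancestral range while the
other is restricted to a single ancestral area is peripheral isolation;
anything else is counted as unclassified, never silently dropped.
Anagenetic events are read off each branch by comparing the range inherited
at the top of the branch with the range at its bottom: each net gained area
is one dispersal, each net lost area one extinction, timed at the branch
midpoint (uniform placement within the branch would be an easy extension;
midpoint is the default because the reconstruction only localises events to
a branch).

**Identifiability.** From node ranges alone, the split into cladogenetic
inheritance plus anagenetic change is not unique — a vicariance followed by
a single dispersal can exactly mimic a peripheral isolation. DEC
implementations report the ranges inherited by each descendant branch at
every split, so `RangeAssignment` carries an optional `splits` map and
classification is exact when it is present (the synthetic simulator always
provides it). Without splits, the classifier resolves each node by
minimum-total-event parsimony over all legal scenarios, with deterministic
tie-breaking (peripheral isolation preferred over vicariance, then
lexicographic); this is exact whenever branches carry no anagenetic noise
and a good approximation otherwise.

Consistently, the forward simulator's truth log records the *net* realised
history per branch — one dispersal per area present at the child node but
absent from its inherited range, one extinction per net loss, timed at the
simulated transition that fixed it. An area gained and lost again between
two nodes is invisible at node resolution and no classifier could recover
it; the raw anagenetic event count is kept on the log
(`n_raw_anagenetic`) so the size of that censoring is always visible.
With-in-branch flicker is the one feature of the continuous-time process
the round-trip validation deliberately does not cover.

Polytomies carry no two-way split and are counted as unclassified, with
children inheriting the full parental range. Time bins run right-open from
the root age down to 0 (an event at exactly the root age falls in the
first bin, at 0 in the last, truncated at the present); per-type bin totals
always equal log totals. Within-area events are excluded from the default
four-category histogram but stay in the log. Range-probability tables are
condensed by taking the single most probable range per node (ties: smaller
range, then lexicographic), with a configurable probability floor below
which a node is left unassigned — probabilities are relative and cannot
exceed 1, so a literal "probability > 1" selection rule would select
nothing.

## Indel coding

Simple indel coding: every distinct internal maximal gap run, keyed by its
exact 1-based inclusive (start, end) span, becomes one character. A taxon
scores 1 when its own gap run is exactly the span, `?` when one of its
runs strictly contains the span (it cannot witness that indel) or missing
data covers the span, and 0 otherwise — including partial overlap with
residues inside the span. Terminal runs (touching the first or last
column) are missing data, not indel events, and are not coded. Columns
gapped in every taxon are kept by default so that coordinates always refer
to the input matrix (a shared internal run is then a coded character, all
1); deletion of such columns is available behind a flag with a warning.
Coding is idempotent on a matrix already augmented with its own indel
characters, since appended 0/1/? columns contain no gap symbol.
Concatenation unions taxon sets, fills absences with `?`, and records
NEXUS-style charset boundaries per partition and per indel block.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume:
ultrametric pure-birth trees (default 197 tips, birth rate 1 — the scale of
the pruned ingroup the methods are aimed at); binary traits at fixed
prevalence (default 81, the scale of a medicinal-use character) under
random scatter, Brownian threshold, and 2-state Markov evolution; a
dependent 4-state model over joint trait states with eight single-change
rates (the `strong_dependence` preset makes trait B gainable only while A
is present and losable only while A is absent); and a forward
dispersal–extinction–cladogenesis history over eight areas (defaults
d = 0.08, e = 0.04 per area, vicariance probability 0.25 at multi-area
splits — a regime leaving a few dozen events on a ~200-tip tree, with
peripheral isolation the commoner split type). All area pairs are treated
as adjacent; an adjacency constraint would be a straightforward extension
but is not modelled.

Not emulated: diversification rate variation, extinction of lineages
(trees are pure-birth), trait-dependent diversification, sampling biases
in use records, sequence evolution beyond uniform random nucleotides, and
overlapping indel events (the toy alignment places non-overlapping
internal spans so truth recovery is well-defined). Passing tests therefore
show the estimators are correct and calibrated under their stated models,
not that real data satisfy those models.

Every generator takes one explicit seed and uses a single numpy Generator
per call; there is no hidden global RNG state, distinct seeds give
distinct outputs, and identical seeds reproduce byte-identical results.

## Problem sizes in the validation suite

The statistical validation uses sizes chosen to keep each property in its
informative regime: D calibration on 100 trees of 128 tips at prevalence
32 with 1000 null replicates per scenario (both endpoints within ±0.05);
parsimony against exhaustive enumeration on 500 instances of ≤ 10 tips;
pairwise size on 400 independent-trait replicates (64-tip trees) and power
on 100 strong-dependence replicates (100-tip trees, median over 25 pair
sets); event recovery on 200 simulated histories (64-tip trees); exact
test agreement on 1000 random tables with margins ≤ 30; and the
end-to-end demo (96 tips, 25 trees) run twice for byte-identical output.

## Known limitations

- d_obs uses the child-mean nodal estimator; only D, not d_obs, is
  directly comparable across implementations.
- The pairwise-pair selection is maximal for its greedy order, not a
  maximum matching; the randomised sets quantify, rather than remove, the
  residual arbitrariness.
- Event classification without split annotations is a parsimony heuristic
  with the mimicry ambiguity described above.
- The exact test's rational enumeration is exact but O(min margin) per
  table with big-integer arithmetic; for tables with margins in the
  millions a normal approximation would be preferable (far beyond the
  intended species-count scale).
- `habit_to_succulence` refuses to guess for variably succulent scramblers
  rather than defaulting; this is a deliberate friction.
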