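# Methods

This note records the model, the algorithmic and numerical choices, and
the known limits of `saltcross`, in the order data flows through the
package.

## The trait model

Habitat preference is a binary character (marine / non-marine) evolving
along a rooted phylogeny under a continuous-time Markov chain with rates
q_MN (marine → non-marine) and q_NM (non-marine → marine), both in
transitions per unit branch length (expected substitutions/site for real
trees, time units for simulated ones). Because any 2-state chain is
reversible, detailed balance π_M·q_MN = π_NM·q_NM holds exactly, and the
transition probabilities have the closed form
P_ij(t) = π_j + (δ_ij − π_j)e^(−st) with s = q_MN + q_NM — no matrix
exponentials are computed numerically. The degenerate s = 0 chain is
handled exactly: P(t) is the identity for every t, and normalization of
the zero matrix is refused.

The four-state field vocabulary (soil, freshwater, marine euphotic,
marine aphotic) enters only through a fixed, idempotent collapse to the
binary states; all rate inference is binary. Community-level analyses
(UniFrac) may keep the four categories as sample groupings.

**Global rate.** For cross-clade comparison the rate matrix is normalized
so that one transition is expected per unit branch length at stationarity:
Q = r·Q̂ with r = π_M·q_MN + π_NM·q_NM. r is the clade's transition speed
regardless of direction; Q̂ retains the direction asymmetry.

**Regimes.** A heterogeneous model paints named, monophyletic clades with
their own rate matrices. A clade's regime covers every branch inside it
*and its stem branch*: the transition into a clade is governed by that
clade's rates. This is a modelling choice (the alternative — stem in the
background regime — is a one-line change in the painting), made so that
"colonization events at the origin of a clade" are attributed to the
clade. Nested clades resolve to the smallest containing clade.

**Root state.** The prior on the root state is configurable: equal
(default, 0.5/0.5), stationary, or fixed. Equal is the neutral choice for
asymmetric chains; under the stationary policy the likelihood is provably
invariant to root placement (used as a correctness check). Deep-node
analyses should be repeated under alternative rootings (`reroot` +
`root_state_summary`) rather than trusting any single root prior.

## Likelihood

Felsenstein pruning over a post-order traversal, with per-node scaling
accumulated in log space so that trees with tens of thousands of tips do
not underflow. The tree is flattened once into index arrays
(`TreeLikelihood`); each evaluation performs one vectorized P(t)
computation per regime and a single Python sweep with two floats per node,
which keeps a 200-tip evaluation under a millisecond — the property that
makes the MCMC affordable. Zero-length branches use the identity matrix
exactly (no epsilon). Missing branch lengths are a parse error unless a
default of 0 is explicitly requested; negative lengths are always
rejected.

## Priors and MCMC

The prior is hierarchical: a rate-mean hyperparameter m ~ Uniform(0, 2)
and rates q_i | m ~ Exponential(mean m) i.i.d.; the equal-rates and
unequal-rates models have prior probability 1/2 each. m may be fixed, in
which case the rate prior is a plain exponential (used by the quadrature
cross-check).

One generation of the sampler performs, in order: a tree move, a sliding
window move on m (accepted on the prior ratio of the current rates — the
likelihood does not involve m), one log-scale sliding-window move per free
rate (Jacobian q′/q), and one reversible-jump attempt on a randomly chosen
regime. The RJ pair is: merge — both rates set to their geometric mean;
split — q·e^{±u} with u ~ Normal(0, σ), σ = 0.5; the Jacobian of
(q, u) ↦ (qe^u, qe^{−u}) is 2q. Within a regime the move proposed is
determined by the current state (equal → split, unequal → merge), so the
proposal probabilities cancel.

Phylogenetic uncertainty enters through a tree index over the supplied
tree set with a uniform prior. Two schedules are offered: "mixed"
(default) proposes a uniform tree swap every 10 generations, accepted on
the likelihood ratio — a valid joint sampler over (parameters, tree
index); "cycle" spends a fixed block of generations on each tree in turn,
reproducing the fixed per-tree schedule common in practice. Proposal
widths are auto-tuned toward 20–40% acceptance during burn-in only, then
frozen (tuning during sampling would break detailed balance). Burn-in
defaults to half the run. Given a seed, traces are bit-reproducible.

Prior-only sampling (`power=0`) reproduces Uniform(0, 2) for m, Exp(m)
for rates and the 50/50 model indicator (Kolmogorov–Smirnov checks in the
test suite), which validates the acceptance ratios end to end.

## Marginal likelihoods and model comparison

Stepping-stone sampling along the ladder β_k = (k/K)^(1/α) with α = 0.4
(the standard Beta-quantile spacing that concentrates stones near the
prior, where the integrand varies fastest). Defaults: K = 50 stones,
5,000 generations per stone, first half of each stone discarded; the
chain state carries over between stones (warm starts up the ladder). The
estimator is log Z = Σ_k log-mean-exp((β_k − β_{k−1})·ℓ_i) over the
retained samples of stone k−1, with a per-stone delta-method standard
error combined in quadrature — an i.i.d. approximation that understates
the error of a correlated chain; the K-vs-2K self-consistency test bounds
the practical effect. Models are compared as log BF = 2·(log Z_A −
log Z_B) with ≥ 10 treated as decisive.

The estimator is validated against 1-D adaptive quadrature of
∫ L(q)·p(q) dq on a 4-tip, fixed-hyperparameter, equal-rates model.

## Ancestral reconstruction

Marginal per-node posteriors use the standard up-down (inside-outside)
algorithm; per-node normalization makes the scaling constants cancel.
Pooling over a tree set and over model draws is an equally weighted mean
of root posteriors, reported per rooting.

The single history consumed by event counting is the *exact joint* ML
assignment (Pupko dynamic programme in log space), not a per-node max of
marginals and not MPPA-style multi-state sets: event counting needs one
concrete history, and the exact joint optimum is reproducible and
testable against exhaustive search. Ties (exactly equal DP scores, which
arise under symmetric rates) are broken deterministically — higher
marginal posterior first, then marine — and tie-flagged nodes propagate a
flag to the events derived from them, so downstream counts can be read as
ranges.

## Events, persistence and timing

Every branch whose endpoints differ in state yields a transition event.
An event is *counted* only if at least `min_clade_size` (default 2) tips
are reachable from the transition without a further state change — the
conservative rule that separates established colonizations from
singletons that may be wind-blown cells, resting spores or extracellular
DNA. "Reachable without a further state change" resolves nested
back-transitions: a reversal inside the colonized clade blocks the tips
below it from supporting the outer event. Setting `min_clade_size=1`
recovers the unfiltered total, and tallies report both populations.

Relative timing uses mean-path-length chronograms: each node's age is the
mean path length to its descendant tips (the calibration-free core of
Pathd8-style smoothing; the full calibrated algorithm is deliberately not
reproduced since only relative dates are needed). Monotonicity is
enforced by raising an offending parent to max(child ages) + ε with
ε = 10⁻⁹ × root age, then ages are normalized to root = 1, tips = 0. An
event is placed at its branch midpoint — unbiased under a uniform prior
on the event's position along the branch — and reported as time from the
root (0 = root, 1 = present); parent- and child-endpoint placements are
available to bracket the midpoint convention.

## Community analyses

Unweighted UniFrac is the unique fraction of the branch length leading to
either community; branches leading to neither are excluded. Significance
is Monte-Carlo: tip–community assignments are shuffled across the union
of the two communities only (community sizes preserved, shared tips kept
shared), p = (1 + #{null ≥ observed})/(1 + n_perm), Bonferroni-adjusted
across pairs. The implementation is cross-checked against scikit-bio's
UniFrac in the test suite. UPGMA clustering of the distance matrix is
provided for habitat dendrograms.

Similarity networks are built from 12-column tabular hit tables at given
identity and query-coverage thresholds (coverage = alignment length /
query length × 100, so query lengths must be supplied; the largest
observed query coordinate is used as a proxy otherwise). Self-hits are
dropped and duplicate pairs collapse to the maximum-identity hit. Raising
the identity threshold only removes edges, so assortativity profiles are
computed on nested graphs. Assortativity is Newman's categorical
coefficient (via networkx) over the habitat mixing matrix.

## Synthetic data

The generator produces the statistical structure the inference assumes,
with recorded truth:

- **Trees**: birth–death (default pure-birth, λ = 1) conditioned on the
  tip count, ultrametric in time units, optionally rescaled to a
  substitutions/site regime by a logged factor. Total extinction triggers
  an internal resample (capped).
- **Histories**: exact Gillespie simulation down each branch at the
  branch regime's rates; every event is stored with its branch and
  fractional position, so the midpoint-timing convention is testable
  directly. Each true event carries the number of extant tips reachable
  from it through event-free edges — the simulation-truth counterpart of
  the persistence rule.
- **Tree sets**: i.i.d. log-normal branch-length jitter (mean-corrected
  by default so expected lengths match the source tree), topology fixed —
  a stand-in for posterior sets of alternative phylogenies. Jitter does
  not vary topology, so analyses of topological uncertainty are outside
  what these replicates can probe.
- **Study bundles**: per-clade tree sets, habitat tables, true event
  tables and a checksummed manifest; clade regimes are chosen to span the
  fast, non-marine-biased to slow, symmetric range so that heterogeneity
  is detectable by the inference modules.

What passing on synthetic data does **not** show: robustness to
misspecified trees (wrong topology, placement error), to habitat
mislabelling, to diversification rates that differ between habitats
(which biases both rate and timing estimates), or to sampling that is
uneven between habitats — the latter is what the subsampling sensitivity
grid in `run_clade_analysis` probes empirically.

## Problem sizes and defaults

The test suite and the acceptance script run everything at desk scale,
chosen so the full stack is exercised in minutes on one CPU: simulated
clades of 50–240 tips, tree sets of 5–10 replicates, MCMC runs of a few
thousand generations, stepping-stone ladders of 14–30 stones × 0.8–2k
generations. Library defaults are larger (50 stones × 5,000; 1,000
generations per tree) and scale linearly; the likelihood engine has been
checked for numerical stability on 2,000-tip trees and uses per-node
scaling sized for much larger ones. Posterior summaries from a single
simulated dataset are seed-dependent in the usual way — calibration
statements in the tests are made over replicate ensembles, not single
draws.

## Known limitations

- Two states only; no covarion/hidden-rate expansions, no >2-state
  analyses (the 4-state vocabulary exists only to be collapsed).
- Trait inference conditions on the supplied trees; there is no joint
  tree+trait estimation.
- The equal-rates/unequal-rates RJ operates within each regime
  independently; there is no move that merges regimes across clades.
- Counted-event totals inherit the biases of joint ML reconstruction:
  under high rates or weak signal, singleton switches are systematically
  pruned away and counts are conservative.
- Stepping-stone standard errors assume independent samples within each
  stone and are best treated as lower bounds.
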