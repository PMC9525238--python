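# saltcross

Inference of marine/non-marine habitat transitions on phylogenies.

Salinity is among the hardest environmental barriers for organisms to
cross, and microbial eukaryote communities on either side of it are
phylogenetically distinct. `saltcross` implements the analysis stack used
to study how lineages nevertheless cross this "salt barrier": given
environmental-sequencing phylogenies (branch lengths in expected
substitutions/site) with each tip labelled marine or non-marine, it
estimates how often, in which direction, and when during a clade's history
habitat transitions occurred, and what habitat ancestral nodes — up to the
last eukaryotic common ancestor — most likely occupied.

## The model

Habitat preference evolves along the tree as a two-state continuous-time
Markov chain (an Mk2 model) with instantaneous rates q_M–NM (marine →
non-marine) and q_NM–M (non-marine → marine), in transitions per
substitution/site. With s = q_M–NM + q_NM–M, the chain has stationary
frequencies π = (q_NM–M/s, q_M–NM/s) and closed-form transition
probabilities P_ij(t) = π_j + (δ_ij − π_j)·e^(−st). The *global rate*
r = π_M·q_M–NM + π_NM·q_NM–M is the expected number of transitions per
unit branch length at stationarity (obtained by normalizing the Q matrix
so Q = r·Q̂); it summarizes a clade's overall transition speed regardless
of direction. Major clades may be painted with their own rate matrices
(stem branch included), giving a heterogeneous model over one tree.

On top of this model the package provides:

- **Bayesian rate estimation** over sets of alternative trees, under a
  hierarchical prior (rate mean m ~ U(0, 2), rates ~ Exp(m)) with a
  reversible-jump move between equal- and unequal-rates models;
- **stepping-stone marginal likelihoods** and model comparison on the
  scale log BF = 2·(log Z₁ − log Z₂), with ≥ 10 read as decisive;
- **ancestral reconstruction**: marginal per-node posteriors (poolable
  over tree sets and alternative rootings) and exact joint ML histories;
- **event counting with a persistence rule**: a reconstructed switch is
  counted only if it founds a clade with ≥ 2 tips still in the new
  habitat, filtering out non-establishing colonists;
- **relative timing** on mean-path-length chronograms (root age 1, tips
  0), with events placed at branch midpoints;
- **community analyses**: unweighted UniFrac with Monte-Carlo
  significance, and habitat assortativity of sequence-similarity networks;
- **a synthetic-data generator** (birth–death trees, exact Gillespie
  trait histories with recorded truth, jittered tree sets, multi-clade
  study bundles) so every stage is testable without external data.

## Worked example

```python
import saltcross as sc
from saltcross.ctmc import RateModel

# simulate a 150-tip clade whose lineages cross the salt barrier
tree = sc.simulate_tree(sc.SimulationConfig(num_tips=150, seed=1))
truth = RateModel(q_mn=0.3, q_nm=0.3)
atree, history = sc.simulate_history(tree, truth, seed=51)
trees = sc.make_tree_set(atree, n=10, jitter_sd=0.05, seed=9)

# posterior over rates (reversible-jump between equal/unequal rates)
post = sc.sample_posterior(trees, gens_per_tree=500, seed=10)
s = post.summary()
print(f"q_MN        = {s['q_mn_mean']:.3f} +/- {s['q_mn_sd']:.3f}")
print(f"q_NM        = {s['q_nm_mean']:.3f} +/- {s['q_nm_sd']:.3f}")
print(f"global rate = {s['global_rate_mean']:.3f}")
print(f"P(equal rates model) = {s['p_equal_rates']:.2f}")

# reconstruct a habitat history and count established transitions
fitted = RateModel(s["q_mn_mean"], s["q_nm_mean"])
hist = sc.joint_ml_states(atree, fitted)
events = sc.event_times(sc.count_transitions(hist), sc.mpl_chronogram(atree.tree))
counted = [e for e in events if e.counted]
to_nm = sum(e.direction == "M->NM" for e in counted)
print(f"counted transitions: {len(counted)} "
      f"({to_nm} to non-marine, {len(counted) - to_nm} to marine)")
times = sorted(e.relative_time for e in counted)
print(f"median relative event time = {times[len(times) // 2]:.2f}")
```

Output:

```
q_MN        = 0.282 +/- 0.071
q_NM        = 0.248 +/- 0.083
global rate = 0.257
P(equal rates model) = 0.68
counted transitions: 16 (4 to non-marine, 12 to marine)
median relative event time = 0.77
```

The posterior recovers the simulating rates (0.3 each) within one
standard deviation, assigns most probability to the equal-rates model, as
it should for symmetric truth, and the counted (established) transitions
concentrate toward the present (relative time 1 = today) — as expected on
birth–death trees, where most branch length lies near the tips.

For a multi-clade workflow — eligibility filtering (≥ 50 tips, both
habitats present), per-clade rate summaries, equal- vs unequal-rates model
comparison and sampling-effort sensitivity — see
`saltcross.run_clade_analysis`, which consumes a YAML/dict config over
bundles written by `saltcross.study_like_bundle`.

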