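"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's pruning/DP code paths:
likelihoods are computed by exhaustive enumeration over internal-state
assignments, and joint reconstructions by brute-force search, so that the
fast implementations can be checked against them on small trees.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import saltcross as sc
from saltcross.ctmc import STATE_INDEX, RateModel, RootPolicy
from saltcross.synth import SimulationConfig


def enum_loglik(
    atree: sc.AnnotatedTree,
    model: RateModel,
    root: RootPolicy = RootPolicy.equal(),
) -> float:
    """Brute-force log-likelihood: sum over all internal-state assignments."""
    tree = atree.tree
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    tip_state = {
        id(nd): STATE_INDEX[atree.labels[nd.taxon.label]]
        for nd in tree.leaf_node_iter()
    }
    weights = root.probs(model)
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(tip_state)
        for nd, s in zip(internals, combo):
            assign[id(nd)] = s
        p = weights[assign[id(tree.seed_node)]]
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            P = sc.transition_matrix(model, nd.edge.length or 0.0)
            p *= P[assign[id(nd.parent_node)], assign[id(nd)]]
        total += p
    return math.log(total)


def exhaustive_joint(
    atree: sc.AnnotatedTree,
    model: RateModel,
    root: RootPolicy = RootPolicy.equal(),
) -> tuple[float, list[dict]]:
    """Max joint log-probability over internal assignments, with argmaxes."""
    tree = atree.tree
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    tip_state = {
        id(nd): STATE_INDEX[atree.labels[nd.taxon.label]]
        for nd in tree.leaf_node_iter()
    }
    weights = root.probs(model)
    best = -math.inf
    argmaxes: list[dict] = []
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(tip_state)
        for nd, s in zip(internals, combo):
            assign[id(nd)] = s
        p = weights[assign[id(tree.seed_node)]]
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            P = sc.transition_matrix(model, nd.edge.length or 0.0)
            p *= P[assign[id(nd.parent_node)], assign[id(nd)]]
        lp = math.log(p) if p > 0 else -math.inf
        if lp > best + 1e-12:
            best = lp
            argmaxes = [dict(assign)]
        elif abs(lp - best) <= 1e-12:
            argmaxes.append(dict(assign))
    return best, argmaxes


def random_annotated_tree(
    seed: int,
    n_tips: int | None = None,
    max_tips: int = 6,
    rate_hi: float = 5.0,
) -> tuple[sc.AnnotatedTree, RateModel]:
    """A random birth-death tree with random rates and simulated labels."""
    rng = np.random.default_rng(seed)
    n = n_tips or int(rng.integers(2, max_tips + 1))
    tree = sc.simulate_tree(
        SimulationConfig(num_tips=n, seed=int(rng.integers(1, 2**31 - 1)))
    )
    model = RateModel(
        float(rng.uniform(0.01, rate_hi)), float(rng.uniform(0.01, rate_hi))
    )
    atree, _ = sc.simulate_history(
        tree, model, seed=int(rng.integers(1, 2**31 - 1))
    )
    return atree, model


@pytest.fixture
def cherry_mm() -> sc.AnnotatedTree:
    """Two marine tips on unit branches."""
    return sc.annotate(
        sc.read_tree("(A:1.0,B:1.0);"), {"A": "marine", "B": "marine"}
    )


@pytest.fixture
def quartet() -> sc.AnnotatedTree:
    """((a,b),(c,d)) with a,b marine and c,d non-marine, unit branches."""
    return sc.annotate(
        sc.read_tree("((a:1,b:1):1,(c:1,d:1):1);"),
        {"a": "marine", "b": "marine", "c": "non_marine", "d": "non_marine"},
    )
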