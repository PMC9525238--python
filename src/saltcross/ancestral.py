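"""Ancestral habitat reconstruction.

Two complementary reconstructions under the 2-state chain:

* :func:`marginal_posteriors` — per-node posterior state probabilities by
  the standard up-down (inside-outside) algorithm; these are the pie-chart
  quantities reported at deep nodes, and can be pooled over tree sets and
  alternative rootings with :func:`root_state_summary`.
* :func:`joint_ml_states` — the single jointly most likely assignment of
  states to all internal nodes (Pupko dynamic programme), which is the
  discrete habitat history consumed by event counting.  Ties are broken
  deterministically (higher marginal posterior, then marine) and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .ctmc import (
    STATES,
    STATE_INDEX,
    RateModel,
    RegimePartition,
    RootPolicy,
    paint_regimes,
    transition_matrix,
)
from .phylo_io import AnnotatedTree, Habitat, TreeSet, reroot, annotate

__all__ = [
    "NodePosterior",
    "TraitHistory",
    "ensure_node_ids",
    "marginal_posteriors",
    "joint_ml_states",
    "root_state_summary",
]

_TIE_REL_TOL = 1e-12


def ensure_node_ids(tree: dendropy.Tree) -> None:
    """Give every unlabelled internal node a stable id (preorder n0, n1, ...)."""
    counter = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        if not nd.label:
            nd.label = f"n{counter}"
        counter += 1


def node_id(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.taxon is not None else nd.label


def _edge_matrices(
    tree: dendropy.Tree,
    model: RateModel | RegimePartition,
) -> tuple[dict[int, np.ndarray], RateModel]:
    """P(t) per branch (keyed by id of child node) and the root's model."""
    if isinstance(model, RegimePartition):
        painting = paint_regimes(tree, model.clade_defs, model.background)
        mats = {}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            m = model.models[painting[id(nd)]]
            mats[id(nd)] = transition_matrix(m, nd.edge.length or 0.0)
        return mats, model.models[model.background]
    mats = {
        id(nd): transition_matrix(model, nd.edge.length or 0.0)
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    }
    return mats, model


def _partials(
    atree: AnnotatedTree, mats: dict[int, np.ndarray]
) -> dict[int, np.ndarray]:
    """Scaled downward partial likelihoods L_v(state), keyed by node id()."""
    part: dict[int, np.ndarray] = {}
    for nd in atree.tree.postorder_node_iter():
        if nd.is_leaf():
            vec = np.zeros(2)
            vec[STATE_INDEX[atree.labels[nd.taxon.label]]] = 1.0
        else:
            vec = np.ones(2)
            for child in nd.child_nodes():
                vec = vec * (mats[id(child)] @ part[id(child)])
            tot = vec.sum()
            if not (tot > 0.0) or not np.isfinite(tot):
                raise ArithmeticError(f"non-finite partial at node {node_id(nd)}")
            vec = vec / tot  # per-node scaling; cancels in posteriors
        part[id(nd)] = vec
    return part


@dataclass
class NodePosterior:
    """Per-node marginal posterior habitat probabilities."""

    probs: dict[str, tuple[float, float]]  # node id -> (p_marine, p_nonmarine)
    root_id: str
    provenance: dict = field(default_factory=dict)

    def p_marine(self, node: str) -> float:
        return self.probs[node][0]

    @property
    def root(self) -> tuple[float, float]:
        return self.probs[self.root_id]


def marginal_posteriors(
    atree: AnnotatedTree,
    model: RateModel | RegimePartition,
    root: RootPolicy = RootPolicy.equal(),
) -> NodePosterior:
    """Marginal posterior state probabilities at every node (up-down pass)."""
    tree = atree.tree
    if len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree has no internal structure")
    ensure_node_ids(tree)
    mats, root_model = _edge_matrices(tree, model)
    part = _partials(atree, mats)
    root_w = np.array(root.probs(root_model))

    outside: dict[int, np.ndarray] = {id(tree.seed_node): root_w.copy()}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        # message from above through nd, including nd's other children
        children = nd.child_nodes()
        down = [mats[id(c)] @ part[id(c)] for c in children]
        o_nd = outside[id(nd)]
        for k, child in enumerate(children):
            sib = o_nd.copy()
            for j, d in enumerate(down):
                if j != k:
                    sib = sib * d
            o_child = mats[id(child)].T @ sib
            tot = o_child.sum()
            outside[id(child)] = o_child / tot if tot > 0 else o_child
    probs: dict[str, tuple[float, float]] = {}
    for nd in tree.preorder_node_iter():
        post = part[id(nd)] * outside[id(nd)]
        post = post / post.sum()
        probs[node_id(nd)] = (float(post[0]), float(post[1]))
    return NodePosterior(
        probs,
        root_id=node_id(tree.seed_node),
        provenance={"root_policy": root.kind},
    )


@dataclass
class TraitHistory:
    """A single state assignment to every node plus its transition edges."""

    tree: dendropy.Tree
    states: dict[str, Habitat]  # node id -> state
    transitions: list[tuple[str, Habitat, Habitat]]  # (child node id, from, to)
    tie_nodes: set[str] = field(default_factory=set)
    log_likelihood: float | None = None

    def state_of(self, nd: dendropy.Node) -> Habitat:
        return self.states[node_id(nd)]

    def to_newick(self) -> str:
        """Annotated Newick with the reconstructed state in node labels."""
        clone = self.tree.clone(depth=1)
        for nd in clone.preorder_node_iter():
            nid = node_id(nd)
            tag = self.states[nid].value
            if nd.is_leaf():
                continue
            nd.label = f"{nid}|{tag}"
        return clone.as_string(schema="newick", suppress_rooting=True).strip()


def joint_ml_states(
    atree: AnnotatedTree,
    model: RateModel | RegimePartition,
    root: RootPolicy = RootPolicy.equal(),
) -> TraitHistory:
    """Exact joint maximum-likelihood ancestral states (Pupko DP).

    Deterministic tie-breaking: prefer the state with the higher marginal
    posterior at that node, then marine; tied nodes are flagged so that
    downstream event counts can be reported as ranges.
    """
    tree = atree.tree
    ensure_node_ids(tree)
    mats, root_model = _edge_matrices(tree, model)
    marg = marginal_posteriors(atree, model, root)
    with np.errstate(divide="ignore"):
        logmats = {k: np.log(m) for k, m in mats.items()}

    # C[node][i] = max log-prob of node's subtree given parent state i
    C: dict[int, np.ndarray] = {}
    choice: dict[int, np.ndarray] = {}
    tie_flag: dict[int, bool] = {}

    def _pick(vals: np.ndarray, nid: str) -> tuple[int, bool]:
        hi = float(np.max(vals))
        cands = [
            j
            for j in range(2)
            if vals[j] >= hi - _TIE_REL_TOL * max(1.0, abs(hi))
        ]
        if len(cands) == 1:
            return cands[0], False
        pm = marg.probs[nid]
        cands.sort(key=lambda j: (-pm[j], j))  # higher marginal, then marine
        return cands[0], True

    for nd in tree.postorder_node_iter():
        if nd is tree.seed_node:
            continue
        lp = logmats[id(nd)]
        if nd.is_leaf():
            obs = STATE_INDEX[atree.labels[nd.taxon.label]]
            C[id(nd)] = lp[:, obs].copy()
            choice[id(nd)] = np.array([obs, obs])
            tie_flag[id(nd)] = False
            continue
        sub = np.zeros(2)
        for c in nd.child_nodes():
            sub = sub + C[id(c)]
        best = np.empty(2)
        ch = np.empty(2, dtype=int)
        tied = False
        nid = node_id(nd)
        for i in range(2):
            vals = lp[i, :] + sub
            j, t = _pick(vals, nid)
            best[i] = vals[j]
            ch[i] = j
            tied = tied or t
        C[id(nd)] = best
        choice[id(nd)] = ch
        tie_flag[id(nd)] = tied

    rootn = tree.seed_node
    root_w = np.array(root.probs(root_model))
    with np.errstate(divide="ignore"):
        vals = np.log(root_w)
    for c in rootn.child_nodes():
        vals = vals + C[id(c)]
    root_state, root_tie = _pick(vals, node_id(rootn))
    joint_loglik = float(np.max(vals))

    states: dict[str, Habitat] = {node_id(rootn): STATES[root_state]}
    ties: set[str] = {node_id(rootn)} if root_tie else set()
    assigned: dict[int, int] = {id(rootn): root_state}
    for nd in tree.preorder_node_iter():
        if nd is rootn:
            continue
        parent_state = assigned[id(nd.parent_node)]
        st = int(choice[id(nd)][parent_state])
        assigned[id(nd)] = st
        states[node_id(nd)] = STATES[st]
        if tie_flag[id(nd)]:
            ties.add(node_id(nd))
    transitions = [
        (node_id(nd), states[node_id(nd.parent_node)], states[node_id(nd)])
        for nd in tree.preorder_node_iter()
        if nd is not rootn and states[node_id(nd)] != states[node_id(nd.parent_node)]
    ]
    return TraitHistory(
        tree=tree,
        states=states,
        transitions=transitions,
        tie_nodes=ties,
        log_likelihood=joint_loglik,
    )


def root_state_summary(
    trees: TreeSet,
    models: RateModel | Sequence[RateModel],
    rootings: Mapping[str, Iterable[str] | None],
    root: RootPolicy = RootPolicy.equal(),
) -> dict[str, tuple[float, float]]:
    """Root posterior pooled over trees and model draws, per rooting.

    ``rootings`` maps a rooting name to an outgroup tip set (or ``None`` to
    keep the tree's existing root); each rooting is applied to every member
    of the tree set, the marginal root posterior is computed for every
    (tree, draw) pair, and the equally weighted mean is returned — the way
    deep-node habitat probabilities are pooled over posterior tree sets.
    """
    if isinstance(models, RateModel):
        models = [models]
    models = list(models)
    if not models:
        raise ValueError("no model draws supplied")
    out: dict[str, tuple[float, float]] = {}
    for name, outgroup in rootings.items():
        acc = np.zeros(2)
        count = 0
        for atree in trees:
            if outgroup is None:
                rerooted = atree
            else:
                rerooted = AnnotatedTree(
                    reroot(atree.tree, outgroup), dict(atree.labels)
                )
            for m in models:
                acc += np.array(
                    marginal_posteriors(rerooted, m, root).root
                )
                count += 1
        acc /= count
        out[name] = (float(acc[0]), float(acc[1]))
    return out
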