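"""Two-state continuous-time Markov model of habitat evolution.

The model (an Mk2 chain on {marine, non-marine}) has instantaneous rates
q_MN (marine -> non-marine) and q_NM (non-marine -> marine), both in
transitions per unit branch length (substitutions/site).  With
s = q_MN + q_NM the chain has stationary frequencies
pi = (q_NM/s, q_MN/s) and the closed-form transition probabilities

    P_ij(t) = pi_j + (delta_ij - pi_j) * exp(-s t).

The "global rate" of a clade is the scalar r = pi_M q_MN + pi_NM q_NM, the
expected number of habitat transitions per unit branch length at
stationarity; dividing Q by r gives the normalized matrix Q-hat whose
expected flux is 1, so r summarizes a clade's overall transition speed
regardless of direction.

Likelihoods are computed by Felsenstein pruning with per-node scaling
(accumulated in log space) so that trees with tens of thousands of tips
stay finite.  Branch-specific rate regimes ("painting" major clades with
their own rate matrices, stem branch included) are supported through
:class:`RegimePartition`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .phylo_io import AnnotatedTree, Habitat

__all__ = [
    "RateModel",
    "RootPolicy",
    "RegimePartition",
    "transition_matrix",
    "normalize",
    "paint_regimes",
    "clade_defs_from_labels",
    "TreeLikelihood",
    "log_likelihood",
]

STATE_INDEX = {Habitat.MARINE: 0, Habitat.NON_MARINE: 1}
STATES = (Habitat.MARINE, Habitat.NON_MARINE)


@dataclass(frozen=True)
class RateModel:
    """Asymmetric 2-state rate matrix (q_MN, q_NM) with derived quantities."""

    q_mn: float
    q_nm: float

    def __post_init__(self) -> None:
        if self.q_mn < 0 or self.q_nm < 0:
            raise ValueError("rates must be non-negative")

    @property
    def s(self) -> float:
        return self.q_mn + self.q_nm

    @property
    def pi(self) -> tuple[float, float]:
        """Stationary frequencies (pi_M, pi_NM); (0.5, 0.5) for the s=0 chain."""
        if self.s == 0.0:
            return (0.5, 0.5)
        return (self.q_nm / self.s, self.q_mn / self.s)

    @property
    def global_rate(self) -> float:
        """Expected transitions per unit branch length at stationarity."""
        pi_m, pi_nm = self.pi
        return pi_m * self.q_mn + pi_nm * self.q_nm

    def q_matrix(self) -> np.ndarray:
        return np.array(
            [[-self.q_mn, self.q_mn], [self.q_nm, -self.q_nm]], dtype=float
        )

    def to_dict(self) -> dict:
        return {"q_mn": self.q_mn, "q_nm": self.q_nm}


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """Closed-form P(t); identity for t=0 or a frozen (s=0) chain."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if model.s == 0.0:
        return np.eye(2)
    pi_m, pi_nm = model.pi
    e = math.exp(-model.s * t)
    return np.array(
        [
            [pi_m + pi_nm * e, pi_nm * (1.0 - e)],
            [pi_m * (1.0 - e), pi_nm + pi_m * e],
        ]
    )


def normalize(model: RateModel) -> tuple[RateModel, float]:
    """Rescale Q so one transition is expected per unit branch length.

    Returns (Q-hat, r) with Q = r * Q-hat; r is the clade's global rate.
    """
    if model.s == 0.0:
        raise ValueError("cannot normalize the zero rate matrix")
    r = model.global_rate
    return RateModel(model.q_mn / r, model.q_nm / r), r


@dataclass(frozen=True)
class RootPolicy:
    """Prior on the state at the root: equal, stationary, or fixed p_M."""

    kind: str = "equal"
    p_marine: float | None = None

    @classmethod
    def equal(cls) -> "RootPolicy":
        return cls("equal")

    @classmethod
    def stationary(cls) -> "RootPolicy":
        return cls("stationary")

    @classmethod
    def fixed(cls, p_marine: float) -> "RootPolicy":
        if not 0.0 <= p_marine <= 1.0:
            raise ValueError("p_marine must be in [0, 1]")
        return cls("fixed", p_marine)

    def probs(self, model: RateModel) -> tuple[float, float]:
        if self.kind == "equal":
            return (0.5, 0.5)
        if self.kind == "stationary":
            return model.pi
        if self.kind == "fixed":
            return (self.p_marine, 1.0 - self.p_marine)
        raise ValueError(f"unknown root policy {self.kind!r}")


def clade_defs_from_labels(
    tree: dendropy.Tree, names: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Clade tip sets from internal-node labels carried in the Newick."""
    defs: dict[str, set[str]] = {}
    wanted = set(names) if names is not None else None
    for nd in tree.preorder_internal_node_iter():
        if nd.label and (wanted is None or nd.label in wanted):
            defs[nd.label] = {lf.taxon.label for lf in nd.leaf_iter()}
    if wanted is not None and wanted - set(defs):
        raise ValueError(f"clade labels not found in tree: {sorted(wanted - set(defs))}")
    return defs


def paint_regimes(
    tree: dendropy.Tree,
    clade_defs: Mapping[str, Iterable[str]],
    background: str = "background",
) -> dict[int, str]:
    """Assign every branch (keyed by id() of its child node) to a regime.

    A clade's regime covers every branch inside it plus its stem branch;
    nested clades resolve to the most specific (smallest) containing clade.
    Each clade must be monophyletic in ``tree``.
    """
    painting: dict[int, str] = {
        id(nd): background for nd in tree if nd is not tree.seed_node
    }
    # paint larger clades first so nested (smaller) clades overwrite
    order = sorted(clade_defs, key=lambda n: -len(set(clade_defs[n])))
    for name in order:
        tips = set(clade_defs[name])
        mrca = tree.mrca(taxon_labels=sorted(tips))
        below = {lf.taxon.label for lf in mrca.leaf_iter()}
        if below != tips:
            raise ValueError(
                f"clade {name!r} is not monophyletic "
                f"(MRCA spans {len(below)} tips, expected {len(tips)})"
            )
        for nd in mrca.preorder_iter():
            if nd is tree.seed_node:
                continue
            painting[id(nd)] = name  # includes the stem branch (mrca itself)
    return painting


@dataclass
class RegimePartition:
    """Clade-specific rate matrices over a painted tree."""

    models: dict[str, RateModel]
    clade_defs: dict[str, set[str]]
    background: str = "background"

    def __post_init__(self) -> None:
        if self.background not in self.models:
            raise ValueError(f"no RateModel for background regime {self.background!r}")
        missing = set(self.clade_defs) - set(self.models)
        if missing:
            raise ValueError(f"no RateModel for clades: {sorted(missing)}")

    @property
    def regime_names(self) -> list[str]:
        return [self.background] + sorted(self.clade_defs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "background": self.background,
                "models": {k: m.to_dict() for k, m in self.models.items()},
                "clades": {k: sorted(v) for k, v in self.clade_defs.items()},
            },
            indent=2,
        )


class TreeLikelihood:
    """Pruning likelihood engine over a fixed tree and tip labelling.

    The topology is flattened once (postorder index arrays, per-edge regime
    ids); each call to :meth:`loglik` then costs one vectorized P(t)
    evaluation per regime plus a single postorder sweep, which makes the
    MCMC over rates cheap even on large trees.
    """

    def __init__(
        self,
        atree: AnnotatedTree,
        clade_defs: Mapping[str, Iterable[str]] | None = None,
        background: str = "background",
        root: RootPolicy = RootPolicy.equal(),
    ):
        tree = atree.tree
        self.root_policy = root
        self.background = background
        nodes = list(tree.postorder_node_iter())
        self._nodes = nodes
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.root_index = index[id(tree.seed_node)]
        self.edge_length = np.array(
            [
                (nd.edge.length or 0.0) if nd is not tree.seed_node else 0.0
                for nd in nodes
            ]
        )
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")
        # regimes
        if clade_defs:
            painting = paint_regimes(tree, clade_defs, background)
            self.regime_names = [background] + sorted(set(clade_defs))
            rix = {name: i for i, name in enumerate(self.regime_names)}
            self.edge_regime = np.array(
                [
                    rix[painting[id(nd)]] if nd is not tree.seed_node else 0
                    for nd in nodes
                ],
                dtype=int,
            )
        else:
            self.regime_names = [background]
            self.edge_regime = np.zeros(n, dtype=int)
        self._regime_edge_idx = [
            np.nonzero(self.edge_regime == r)[0]
            for r in range(len(self.regime_names))
        ]
        # traversal structure: internal nodes in postorder with child indices
        self.internal: list[tuple[int, list[int]]] = []
        self.tip_state: list[tuple[int, int]] = []
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                label = nd.taxon.label
                self.tip_state.append((i, STATE_INDEX[atree.labels[label]]))
            else:
                self.internal.append(
                    (i, [index[id(c)] for c in nd.child_nodes()])
                )
        self.n_tips = len(self.tip_state)

    def loglik(
        self, models: RateModel | Mapping[str, RateModel] | Sequence[RateModel]
    ) -> float:
        """Log-likelihood of the tip labels under per-regime rate models."""
        if isinstance(models, RateModel):
            models = [models] * len(self.regime_names)
        elif isinstance(models, Mapping):
            models = [models[name] for name in self.regime_names]
        if len(models) != len(self.regime_names):
            raise ValueError("one RateModel required per regime")
        n = self.n_nodes
        pmm = np.empty(n)
        pmn = np.empty(n)
        pnm = np.empty(n)
        pnn = np.empty(n)
        root_model = models[0]
        for r, model in enumerate(models):
            idx = self._regime_edge_idx[r]
            if idx.size == 0:
                continue
            t = self.edge_length[idx]
            pi_m, pi_nm = model.pi
            e = np.exp(-model.s * t)
            pmm[idx] = pi_m + pi_nm * e
            pmn[idx] = pi_nm * (1.0 - e)
            pnm[idx] = pi_m * (1.0 - e)
            pnn[idx] = pi_nm + pi_m * e
        # python-float sweeps: 2 states only, faster than per-node numpy
        PMM, PMN, PNM, PNN = (
            pmm.tolist(), pmn.tolist(), pnm.tolist(), pnn.tolist()
        )
        part_m = [0.0] * n
        part_n = [0.0] * n
        for i, s in self.tip_state:
            if s == 0:
                part_m[i] = 1.0
            else:
                part_n[i] = 1.0
        logscale = 0.0
        for i, children in self.internal:
            lm = 1.0
            ln = 1.0
            for c in children:
                cm = part_m[c]
                cn = part_n[c]
                lm *= PMM[c] * cm + PMN[c] * cn
                ln *= PNM[c] * cm + PNN[c] * cn
            tot = lm + ln
            if tot <= 0.0 or not math.isfinite(tot):
                raise ArithmeticError(
                    f"non-finite partial likelihood at node index {i}"
                )
            part_m[i] = lm / tot
            part_n[i] = ln / tot
            logscale += math.log(tot)
        w_m, w_n = self.root_policy.probs(root_model)
        r = self.root_index
        lik = w_m * part_m[r] + w_n * part_n[r]
        if lik <= 0.0:
            raise ArithmeticError("zero likelihood at root")
        return logscale + math.log(lik)


def log_likelihood(
    atree: AnnotatedTree,
    model: RateModel | RegimePartition,
    root: RootPolicy = RootPolicy.equal(),
) -> float:
    """Felsenstein pruning log-likelihood of an annotated tree.

    ``model`` may be a single :class:`RateModel` (homogeneous) or a
    :class:`RegimePartition` (clade-painted heterogeneous model).
    """
    if isinstance(model, RegimePartition):
        engine = TreeLikelihood(
            atree, model.clade_defs, model.background, root=root
        )
        return engine.loglik(model.models)
    engine = TreeLikelihood(atree, root=root)
    return engine.loglik(model)
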