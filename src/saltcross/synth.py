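"""Synthetic trees, habitat histories and study-style bundles.

Every inference stage of the package can be exercised against data whose
truth is recorded: birth–death trees conditioned on a tip count, habitat
labels evolved down the tree by exact Gillespie simulation of the 2-state
chain (per-branch regimes supported, every event recorded with its
position along its branch), jittered tree replicates standing in for sets
of alternative phylogenies, and multi-clade "study bundles" whose clades
carry distinguishable rate regimes (a fast, non-marine-biased fungi-like
regime vs a slow apicomplexa-like regime, by default).

All outputs are bit-reproducible given a seed.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .ancestral import ensure_node_ids, node_id
from .ctmc import RateModel, RegimePartition, paint_regimes
from .phylo_io import AnnotatedTree, Habitat, TreeSet, write_tree

__all__ = [
    "SimulationConfig",
    "TrueEvent",
    "TrueHistory",
    "simulate_tree",
    "simulate_history",
    "make_tree_set",
    "simulate_partitioned_tree",
    "study_like_bundle",
]

_RETRY_CAP = 100


@dataclass
class SimulationConfig:
    """Tree + trait simulation settings.

    birth/death rates are in events per lineage per time unit; the tree is
    conditioned on ``num_tips`` extant tips.  ``rate_scale`` multiplies all
    branch lengths after simulation (mapping time units to a
    substitutions/site regime); ``jitter_sd`` is the log-normal sd used for
    replicate tree sets.
    """

    num_tips: int = 200
    birth_rate: float = 1.0
    death_rate: float = 0.0
    rate_scale: float = 1.0
    jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_tips < 2:
            raise ValueError("num_tips must be >= 2")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def simulate_tree(cfg: SimulationConfig) -> dendropy.Tree:
    """Birth–death tree conditioned on tip count, seed-deterministic.

    Tips are renamed t1..tn in leaf order; branch lengths are multiplied
    by ``cfg.rate_scale``.  Total extinction before the target tip count
    triggers an internal resample (up to a retry cap).
    """
    rng = random.Random(cfg.seed)
    last_exc: Exception | None = None
    for _ in range(_RETRY_CAP):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=cfg.birth_rate,
                death_rate=cfg.death_rate,
                num_extant_tips=cfg.num_tips,
                rng=rng,
            )
            break
        except Exception as exc:  # total extinction; retry with same stream
            last_exc = exc
    else:
        raise RuntimeError(
            f"birth–death simulation failed {_RETRY_CAP} times"
        ) from last_exc
    tree.is_rooted = True
    tree.suppress_unifurcations()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    for nd in tree.preorder_node_iter():
        nd.label = None  # drop simulator labels; ids reassigned on demand
        if nd is not tree.seed_node and nd.edge.length is not None:
            nd.edge.length *= cfg.rate_scale
    tree.seed_node.edge.length = None
    ensure_node_ids(tree)
    return tree


@dataclass
class TrueEvent:
    """A simulated habitat switch, located on its branch."""

    edge: str  # child-node id of the branch carrying the event
    direction: str  # "M->NM" or "NM->M"
    position: float  # fraction along the branch, in [0, 1)
    persistent_tip_count: int = 0  # filled in after simulation


@dataclass
class TrueHistory:
    """Ground-truth trait history recorded during simulation."""

    root_state: Habitat
    node_states: dict[str, Habitat]
    events: list[TrueEvent] = field(default_factory=list)

    def counted_events(self, min_clade_size: int = 2) -> list[TrueEvent]:
        return [e for e in self.events if e.persistent_tip_count >= min_clade_size]

    def counts_by_direction(self, min_clade_size: int = 2) -> dict[str, int]:
        out = {"M->NM": 0, "NM->M": 0}
        for e in self.counted_events(min_clade_size):
            out[e.direction] += 1
        return out


def _regime_rates(
    model: RateModel | RegimePartition, tree: dendropy.Tree
) -> dict[int, RateModel]:
    if isinstance(model, RegimePartition):
        painting = paint_regimes(tree, model.clade_defs, model.background)
        return {
            id(nd): model.models[painting[id(nd)]]
            for nd in tree.preorder_node_iter()
            if nd is not tree.seed_node
        }
    return {
        id(nd): model
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    }


def simulate_history(
    tree: dendropy.Tree,
    model: RateModel | RegimePartition,
    root_state: Habitat | None = None,
    seed: int = 0,
) -> tuple[AnnotatedTree, TrueHistory]:
    """Evolve habitat states down the tree by Gillespie simulation.

    Waiting times between switches on a branch are exponential at the
    branch regime's current-state exit rate.  ``root_state=None`` draws the
    root from the stationary distribution of the root regime's chain.
    Every event is recorded with its branch and position; tip labels are
    the states reached at the leaves.
    """
    rng = np.random.default_rng(seed)
    ensure_node_ids(tree)
    rates = _regime_rates(model, tree)
    root_model = (
        model.models[model.background]
        if isinstance(model, RegimePartition)
        else model
    )
    if root_state is None:
        root_state = (
            Habitat.MARINE if rng.random() < root_model.pi[0] else Habitat.NON_MARINE
        )
    node_states: dict[str, Habitat] = {node_id(tree.seed_node): root_state}
    events: list[TrueEvent] = []
    events_on_edge: dict[str, int] = {}
    state_at: dict[int, Habitat] = {id(tree.seed_node): root_state}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        state = state_at[id(nd.parent_node)]
        length = nd.edge.length or 0.0
        m = rates[id(nd)]
        pos = 0.0
        nid = node_id(nd)
        while True:
            rate = m.q_mn if state is Habitat.MARINE else m.q_nm
            if rate <= 0.0:
                break
            wait = rng.exponential(1.0 / rate)
            if pos + wait >= length or length == 0.0:
                break
            pos += wait
            new_state = state.other()
            events.append(
                TrueEvent(
                    edge=nid,
                    direction="M->NM" if state is Habitat.MARINE else "NM->M",
                    position=pos / length,
                )
            )
            events_on_edge[nid] = events_on_edge.get(nid, 0) + 1
            state = new_state
        state_at[id(nd)] = state
        node_states[nid] = state
    labels = {
        lf.taxon.label: state_at[id(lf)] for lf in tree.leaf_node_iter()
    }
    history = TrueHistory(root_state=root_state, node_states=node_states, events=events)
    _fill_persistence(tree, history, events_on_edge)
    return AnnotatedTree(tree, labels), history


def _fill_persistence(
    tree: dendropy.Tree, history: TrueHistory, events_on_edge: dict[str, int]
) -> None:
    """Per-event count of extant tips reachable with no further event.

    An event is only 'visible at present' through edges carrying no later
    events: tips below a subsequent switch are unreachable in the same
    state.  For the last event on a branch, reachable tips are those in
    the child's subtree connected through entirely event-free edges.
    """
    by_id = {node_id(nd): nd for nd in tree.preorder_node_iter()}
    # tips reachable downward from a node through event-free edges
    clean_tips: dict[int, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            clean_tips[id(nd)] = 1
            continue
        total = 0
        for c in nd.child_nodes():
            if events_on_edge.get(node_id(c), 0) == 0:
                total += clean_tips[id(c)]
        clean_tips[id(nd)] = total
    last_on_edge: dict[str, int] = {}
    for i, ev in enumerate(history.events):
        last_on_edge[ev.edge] = i  # preorder + in-branch order: last wins
    for i, ev in enumerate(history.events):
        if last_on_edge[ev.edge] != i:
            ev.persistent_tip_count = 0  # a later switch on the same branch
        else:
            ev.persistent_tip_count = clean_tips[id(by_id[ev.edge])]


def make_tree_set(
    atree: AnnotatedTree,
    n: int = 100,
    jitter_sd: float = 0.1,
    seed: int = 0,
    mean_corrected: bool = True,
) -> TreeSet:
    """Replicate trees with log-normally jittered branch lengths.

    Stands in for posterior sets of alternative phylogenies: topology and
    labels are shared, each branch length is multiplied by an i.i.d.
    log-normal factor.  With ``mean_corrected`` the factor has mean 1
    (mu = -sd^2/2) so expected branch lengths match the source tree.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mu = -0.5 * jitter_sd**2 if mean_corrected else 0.0
    members = []
    for _ in range(n):
        clone = atree.tree.clone(depth=1)
        for nd in clone.preorder_node_iter():
            if nd is clone.seed_node or nd.edge.length is None:
                continue
            nd.edge.length *= float(rng.lognormal(mu, jitter_sd)) if jitter_sd else 1.0
        members.append(AnnotatedTree(clone, dict(atree.labels)))
    return TreeSet(members)


def simulate_partitioned_tree(
    clades: Mapping[str, tuple[int, RateModel]],
    background: RateModel,
    stem_length: float = 0.5,
    root_state: Habitat | None = Habitat.MARINE,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[AnnotatedTree, TrueHistory, RegimePartition]:
    """One tree whose named subtrees evolve under clade-specific regimes.

    Each entry of ``clades`` (name -> (tip count, RateModel)) becomes a
    monophyletic subtree hanging off the root by a stem branch (painted in
    the clade's regime); habitat states then evolve over the whole painted
    tree.  Returns the annotated tree, the recorded truth, and the
    partition (with ``background`` governing the root edges).
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    tree = dendropy.Tree()
    tree.seed_node = root
    tree.is_rooted = True
    clade_defs: dict[str, set[str]] = {}
    models: dict[str, RateModel] = {"background": background}
    namespace = dendropy.TaxonNamespace()
    for name, (n_tips, model) in sorted(clades.items()):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_cfg = SimulationConfig(
            num_tips=n_tips,
            birth_rate=cfg.birth_rate,
            death_rate=cfg.death_rate,
            rate_scale=cfg.rate_scale,
            seed=sub_seed,
        )
        sub = simulate_tree(sub_cfg)
        tips = []
        for lf in sub.leaf_node_iter():
            lf.taxon = dendropy.Taxon(label=f"{name}_{lf.taxon.label}")
            namespace.add_taxon(lf.taxon)
            tips.append(lf.taxon.label)
        top = sub.seed_node
        top.edge.length = stem_length * cfg.rate_scale
        top.label = name
        root.add_child(top)
        clade_defs[name] = set(tips)
        models[name] = model
    tree.taxon_namespace = namespace
    tree.update_taxon_namespace()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.label in clade_defs:
            continue
        nd.label = None
    ensure_node_ids(tree)
    partition = RegimePartition(models=models, clade_defs=clade_defs)
    atree, history = simulate_history(
        tree, partition, root_state=root_state, seed=int(rng.integers(0, 2**31 - 1))
    )
    return atree, history, partition


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def study_like_bundle(
    clades: Mapping[str, dict],
    out_dir: str | Path,
    n_trees: int = 20,
    jitter_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Emit a directory of per-clade tree sets, habitat tables and truth.

    ``clades`` maps a clade name to a spec dict with keys ``n_tips``,
    ``model`` (RateModel), and optionally ``root_state``, ``birth_rate``,
    ``rate_scale``.  Per clade, writes ``<name>.trees.nwk`` (one Newick per
    line), ``<name>.habitats.tsv`` and ``<name>.true_events.tsv``, plus a
    ``manifest.json`` listing every file with a checksum.  Defaults emulate
    the study's shape: clade regimes range from fast, non-marine-biased
    (fungi-like) to slow and symmetric (apicomplexa-like).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "clades": {}, "files": {}}
    for name in sorted(clades):
        spec = clades[name]
        n_tips = int(spec["n_tips"])
        if n_tips < 4:
            raise ValueError(f"clade {name!r}: size must be >= 4")
        model: RateModel = spec["model"]
        cfg = SimulationConfig(
            num_tips=n_tips,
            birth_rate=float(spec.get("birth_rate", 1.0)),
            rate_scale=float(spec.get("rate_scale", 1.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        tree = simulate_tree(cfg)
        atree, truth = simulate_history(
            tree,
            model,
            root_state=spec.get("root_state"),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trees = make_tree_set(
            atree, n=n_trees, jitter_sd=jitter_sd, seed=int(rng.integers(0, 2**31 - 1))
        )
        tree_path = out / f"{name}.trees.nwk"
        tree_path.write_text("".join(write_tree(at.tree) + "\n" for at in trees))
        hab_path = out / f"{name}.habitats.tsv"
        hab_path.write_text(
            "tip_id\thabitat\n"
            + "".join(f"{t}\t{h.value}\n" for t, h in sorted(atree.labels.items()))
        )
        ev_path = out / f"{name}.true_events.tsv"
        ev_path.write_text(
            "edge\tdirection\tposition\tpersistent_tip_count\n"
            + "".join(
                f"{e.edge}\t{e.direction}\t{e.position:.6f}\t{e.persistent_tip_count}\n"
                for e in truth.events
            )
        )
        manifest["clades"][name] = {
            "n_tips": n_tips,
            "q_mn": model.q_mn,
            "q_nm": model.q_nm,
            "root_state": truth.root_state.value,
            "n_true_events": len(truth.events),
            "trees": tree_path.name,
            "habitats": hab_path.name,
            "true_events": ev_path.name,
        }
        for p in (tree_path, hab_path, ev_path):
            manifest["files"][p.name] = _sha256(p)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
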