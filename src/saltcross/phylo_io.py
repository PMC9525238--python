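"""Reading, writing and manipulating habitat-annotated phylogenies.

Trees are ``dendropy.Tree`` objects throughout the package: rooted (or
explicitly rootable), branch lengths in expected substitutions/site,
polytomies allowed, internal-node labels retained as clade tags.  Habitat
labels live beside the tree in an :class:`AnnotatedTree`, a total map from
tip name to one of two states (marine / non-marine), optionally collapsed
from the four-state vocabulary (soil, freshwater, marine euphotic, marine
aphotic) used for community-level analyses.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Habitat",
    "FOUR_STATE_COLLAPSE",
    "AnnotatedTree",
    "TreeSet",
    "read_tree",
    "read_tree_set",
    "write_tree",
    "read_habitat_table",
    "annotate",
    "reroot",
    "subsample_tips",
    "tip_labels",
    "total_branch_length",
]


class Habitat(str, Enum):
    """Binary habitat state on either side of the salt barrier."""

    MARINE = "marine"
    NON_MARINE = "non_marine"

    def other(self) -> "Habitat":
        return Habitat.NON_MARINE if self is Habitat.MARINE else Habitat.MARINE


#: Fixed, total, idempotent collapse from the 4-state vocabulary to binary.
FOUR_STATE_COLLAPSE: dict[str, Habitat] = {
    "soil": Habitat.NON_MARINE,
    "freshwater": Habitat.NON_MARINE,
    "marine_euphotic": Habitat.MARINE,
    "marine_aphotic": Habitat.MARINE,
    # binary values pass through unchanged (idempotence)
    "marine": Habitat.MARINE,
    "non_marine": Habitat.NON_MARINE,
}

FOUR_STATES = ("soil", "freshwater", "marine_euphotic", "marine_aphotic")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(
        nd.edge.length or 0.0 for nd in tree if nd is not tree.seed_node
    )


@dataclass
class AnnotatedTree:
    """A phylogeny plus a total tip -> habitat map."""

    tree: dendropy.Tree
    labels: dict[str, Habitat]

    def __post_init__(self) -> None:
        tips = set(tip_labels(self.tree))
        missing = tips - set(self.labels)
        if missing:
            raise ValueError(f"unlabelled tips: {', '.join(sorted(missing))}")
        self.labels = {t: self.labels[t] for t in sorted(tips)}

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def habitats_present(self) -> set[Habitat]:
        return set(self.labels.values())

    def clone(self) -> "AnnotatedTree":
        return AnnotatedTree(self.tree.clone(depth=1), dict(self.labels))


@dataclass
class TreeSet:
    """An ordered collection of annotated trees over one shared tip set.

    Stands in for the sets of ~100 alternative phylogenies used to carry
    phylogenetic uncertainty through the rate analyses.
    """

    members: list[AnnotatedTree] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("TreeSet must contain at least one tree")
        ref = self.members[0].labels
        for i, at in enumerate(self.members[1:], start=1):
            if at.labels != ref:
                raise ValueError(
                    f"tree {i} has a different tip set or labelling than tree 0"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> AnnotatedTree:
        return self.members[i]

    @property
    def labels(self) -> dict[str, Habitat]:
        return self.members[0].labels


def _parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error classes
        raise ValueError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    return tree


def read_tree(
    newick_text: str, default_branch_length: float | None = None
) -> dendropy.Tree:
    """Parse a single Newick statement into a rooted tree.

    Branch lengths are required on every non-root edge; a missing length is
    a parse-time error unless ``default_branch_length`` (typically 0.0) is
    given explicitly.  Negative lengths are always rejected.  Quoted labels
    and square-bracket comments are accepted (comments discarded); internal
    node labels are retained as clade tags.
    """
    if ";" not in newick_text:
        raise ValueError("Newick parse error: missing terminating ';'")
    tree = _parse_newick(newick_text)
    for nd in tree:
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None:
            if default_branch_length is None:
                name = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                raise ValueError(
                    f"missing branch length on edge above {name!r}; "
                    "pass default_branch_length=0.0 to accept"
                )
            nd.edge.length = default_branch_length
        elif nd.edge.length < 0:
            raise ValueError(f"negative branch length {nd.edge.length}")
    return tree


def read_tree_set(
    source: str | Iterable[str],
    table: Mapping[str, str] | Mapping[str, Habitat],
    mode: str = "binary",
) -> TreeSet:
    """Read one tree per line (file path or newick lines) into a TreeSet."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    else:
        lines = [ln.strip() for ln in source if ln.strip()]
    return TreeSet([annotate(read_tree(ln), table, mode=mode) for ln in lines])


def write_tree(tree: dendropy.Tree) -> str:
    """Serialize to a single-line Newick string (round-trips read_tree)."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def read_habitat_table(source: str | io.TextIOBase) -> dict[str, str]:
    """Read a ``tip_id<TAB>habitat`` TSV into a dict.

    Duplicate rows are legal only if they agree on the habitat.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if not {"tip_id", "habitat"}.issubset(df.columns):
        raise ValueError("habitat table must have columns tip_id, habitat")
    out: dict[str, str] = {}
    for tip, hab in zip(df["tip_id"], df["habitat"]):
        if tip in out and out[tip] != hab:
            raise ValueError(f"conflicting habitat labels for tip {tip!r}")
        out[tip] = hab
    return out


def annotate(
    tree: dendropy.Tree,
    table: Mapping[str, str] | Mapping[str, Habitat],
    mode: str = "binary",
) -> AnnotatedTree:
    """Attach habitat labels to every tip of ``tree``.

    In binary mode, 4-state values are collapsed via the fixed map
    (soil/freshwater -> non-marine, euphotic/aphotic -> marine).  Table
    entries for tips absent from the tree are ignored with a warning; tips
    absent from the table are an error.
    """
    if mode != "binary":
        raise NotImplementedError("only binary mode is implemented for analysis")
    tips = set(tip_labels(tree))
    extra = set(table) - tips
    if extra:
        log.warning(
            "habitat table rows for %d tips absent from tree (ignored): %s",
            len(extra),
            ", ".join(sorted(extra)[:10]),
        )
    labels: dict[str, Habitat] = {}
    for tip in tips & set(table):
        value = table[tip]
        if isinstance(value, Habitat):
            labels[tip] = value
            continue
        try:
            labels[tip] = FOUR_STATE_COLLAPSE[str(value)]
        except KeyError:
            raise ValueError(f"unknown habitat value {value!r} for tip {tip!r}")
    return AnnotatedTree(tree, labels)  # raises on unlabelled tips


def _find_outgroup_edge(tree: dendropy.Tree, outgroup: set[str]):
    """Edge whose removal splits the unrooted tree into outgroup | rest."""
    all_tips = set(tip_labels(tree))
    if not outgroup or outgroup == all_tips:
        raise ValueError("outgroup must be a proper non-empty subset of tips")
    if not outgroup.issubset(all_tips):
        raise ValueError(f"outgroup tips not in tree: {sorted(outgroup - all_tips)}")
    # A set of tips is a clade in the unrooted sense iff some edge bipartitions
    # the tips into exactly (outgroup, complement).
    for nd in tree.postorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in nd.leaf_iter()}
        if below == outgroup or below == all_tips - outgroup:
            return nd.edge
    raise ValueError("outgroup is not monophyletic in the unrooted topology")


def reroot(tree: dendropy.Tree, outgroup: str | Iterable[str]) -> dendropy.Tree:
    """Root (a clone of) the tree on the edge subtending ``outgroup``.

    The new root is placed at the midpoint of that edge, which leaves every
    tip-to-tip path length unchanged.  The outgroup may be a tip name or a
    tip set that forms a clade in the unrooted topology.
    """
    if isinstance(outgroup, str):
        outgroup = {outgroup}
    outgroup = set(outgroup)
    new = tree.clone(depth=1)
    new.is_rooted = True
    edge = _find_outgroup_edge(new, outgroup)
    length = edge.length or 0.0
    new.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
    new.suppress_unifurcations()
    return new


def subsample_tips(
    atree: AnnotatedTree,
    habitat: Habitat | str | set,
    fraction: float,
    seed: int,
) -> AnnotatedTree:
    """Remove ``round(fraction * n_target)`` random tips of a habitat class.

    Used for the sampling-effort sensitivity design (removing 5–70% of a
    habitat's tips in replicate).  Unifurcations left by pruning are
    collapsed with branch lengths summed.  Deterministic given ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if isinstance(habitat, (Habitat, str)):
        habitat = {habitat}
    targets_wanted = {Habitat(h) for h in habitat}
    target_tips = sorted(
        t for t, h in atree.labels.items() if h in targets_wanted
    )
    if not target_tips:
        raise ValueError(f"no tips with habitat {sorted(h.value for h in targets_wanted)}")
    k = int(round(fraction * len(target_tips)))
    if atree.n_tips - k < 2:
        raise ValueError("subsampling would leave fewer than 2 tips")
    if k == 0:
        return atree.clone()
    rng = np.random.default_rng(seed)
    removed = set(rng.choice(target_tips, size=k, replace=False).tolist())
    new = atree.tree.clone(depth=1)
    new.prune_taxa_with_labels(sorted(removed))
    # collapse a root unifurcation left by pruning one side of the root
    new.suppress_unifurcations()
    labels = {t: h for t, h in atree.labels.items() if t not in removed}
    return AnnotatedTree(new, labels)
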