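"""Transition events: counting, persistence filtering and relative timing.

A reconstructed habitat history is turned into directed transition events
(one per branch whose parent and child states differ).  Following the
conservative convention that a colonization only "counts" if it
established, an event is flagged ``counted`` only when it founds a clade
with at least ``min_clade_size`` (default 2) tips still in the new habitat
— tips reachable from the transition without any further state change.

Relative timing uses mean-path-length (MPL) chronograms: each node's age
is the mean path length to its descendant tips (the calibration-free core
of Pathd8), normalized so the root has age 1 and tips age 0.  An event on
a branch is placed at the branch midpoint, and its relative time is
measured from the root (0 = root, 1 = present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .ancestral import TraitHistory, node_id
from .phylo_io import Habitat

__all__ = [
    "Chronogram",
    "TransitionEvent",
    "mpl_chronogram",
    "count_transitions",
    "event_times",
    "time_histogram",
    "tally",
]

DIRECTIONS = ("M->NM", "NM->M")


def _direction(frm: Habitat, to: Habitat) -> str:
    return "M->NM" if frm is Habitat.MARINE else "NM->M"


@dataclass
class Chronogram:
    """Tree with relative node ages: root exactly 1, tips exactly 0."""

    tree: dendropy.Tree
    ages: dict[str, float]  # node id -> age above present, in [0, 1]

    def age(self, node: str) -> float:
        return self.ages[node]


def mpl_chronogram(tree: dendropy.Tree, epsilon_factor: float = 1e-9) -> Chronogram:
    """Relative chronogram by mean path length smoothing.

    Node age = mean path length from the node to its descendant tips.
    Monotonicity (parent strictly older than child) is enforced by raising
    any offending parent to max(child ages) + eps with
    eps = ``epsilon_factor`` x root age, then ages are divided by the root
    age so the root sits at 1 and tips at 0.
    """
    from .ancestral import ensure_node_ids

    ensure_node_ids(tree)
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise ValueError("chronogram requires at least 2 tips")
    raw: dict[int, float] = {}
    ntips: dict[int, int] = {}
    pathsum: dict[int, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            raw[id(nd)] = 0.0
            ntips[id(nd)] = 1
            pathsum[id(nd)] = 0.0
        else:
            s = 0.0
            n = 0
            for c in nd.child_nodes():
                s += pathsum[id(c)] + (c.edge.length or 0.0) * ntips[id(c)]
                n += ntips[id(c)]
            pathsum[id(nd)] = s
            ntips[id(nd)] = n
            raw[id(nd)] = s / n
    root_age = raw[id(tree.seed_node)]
    if root_age <= 0.0:
        raise ValueError("tree has zero total depth; cannot build chronogram")
    eps = epsilon_factor * root_age
    # enforce strict parent > child, children already final in postorder
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        limit = max(raw[id(c)] for c in nd.child_nodes())
        if raw[id(nd)] <= limit:
            raw[id(nd)] = limit + eps
    root_age = raw[id(tree.seed_node)]
    ages = {
        node_id(nd): (0.0 if nd.is_leaf() else raw[id(nd)] / root_age)
        for nd in tree.preorder_node_iter()
    }
    ages[node_id(tree.seed_node)] = 1.0
    return Chronogram(tree, ages)


@dataclass
class TransitionEvent:
    """A directed habitat switch on one branch of a reconstructed history."""

    edge: str  # id of the child node of the branch
    parent: str
    direction: str  # "M->NM" or "NM->M"
    persistent_tip_count: int
    counted: bool
    relative_time: float | None = None  # 0 = root, 1 = present
    tie_flagged: bool = False


def _persistent_tips(child: dendropy.Node, history: TraitHistory) -> int:
    """Tips reachable from ``child`` with no further state change."""
    target = history.state_of(child)
    count = 0
    stack = [child]
    while stack:
        nd = stack.pop()
        if history.state_of(nd) is not target:
            continue
        if nd.is_leaf():
            count += 1
        else:
            stack.extend(nd.child_nodes())
    return count


def count_transitions(
    history: TraitHistory, min_clade_size: int = 2
) -> list[TransitionEvent]:
    """All state-change events of a history, with the persistence filter.

    Every branch whose parent and child states differ yields an event; the
    event is ``counted`` iff at least ``min_clade_size`` descendant tips
    are reachable from the transition without a further state change
    (excluding non-establishing colonists).  ``min_clade_size=1`` recovers
    the unfiltered total.
    """
    by_id = {node_id(nd): nd for nd in history.tree.preorder_node_iter()}
    events = []
    for child_id, frm, to in history.transitions:
        child = by_id[child_id]
        persistent = _persistent_tips(child, history)
        events.append(
            TransitionEvent(
                edge=child_id,
                parent=node_id(child.parent_node),
                direction=_direction(frm, to),
                persistent_tip_count=persistent,
                counted=persistent >= min_clade_size,
                tie_flagged=(
                    child_id in history.tie_nodes
                    or node_id(child.parent_node) in history.tie_nodes
                ),
            )
        )
    return events


def event_times(
    events: Sequence[TransitionEvent],
    chrono: Chronogram,
    placement: str = "midpoint",
) -> list[TransitionEvent]:
    """Attach a relative time (from the root, in [0, 1]) to each event.

    The event is placed on its branch at the midpoint by default
    (``placement`` may also be ``"parent"`` or ``"child"``); with node ages
    measured above the present, relative time = 1 - placement age.
    """
    for ev in events:
        if ev.edge not in chrono.ages or ev.parent not in chrono.ages:
            raise KeyError(f"edge {ev.parent}->{ev.edge} absent from chronogram")
        a_p = chrono.ages[ev.parent]
        a_c = chrono.ages[ev.edge]
        if placement == "midpoint":
            age = 0.5 * (a_p + a_c)
        elif placement == "parent":
            age = a_p
        elif placement == "child":
            age = a_c
        else:
            raise ValueError(f"unknown placement {placement!r}")
        ev.relative_time = 1.0 - age
    return list(events)


def time_histogram(
    events: Sequence[TransitionEvent],
    bins: int = 20,
    counted_only: bool = True,
) -> pd.DataFrame:
    """Binned event counts on relative time [0, 1], per direction."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []
    for direction in DIRECTIONS:
        times = [
            ev.relative_time
            for ev in events
            if ev.direction == direction
            and ev.relative_time is not None
            and (ev.counted or not counted_only)
        ]
        counts, _ = np.histogram(times, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"direction": direction, "bin_lo": lo, "bin_hi": hi, "count": int(c)}
            )
    return pd.DataFrame(rows)


def tally(
    event_sets: Iterable[Sequence[TransitionEvent]],
) -> pd.DataFrame:
    """Per-direction counted-event distributions across a tree set.

    One inner sequence per tree/history.  Returns boxplot-style summaries
    (median, quartiles, 1.5 x IQR whiskers) of counted events per tree for
    each direction, plus the same for all detected (unfiltered) events.
    """
    per_tree: dict[tuple[str, str], list[int]] = {}
    n_trees = 0
    event_sets = list(event_sets)
    if not event_sets:
        raise ValueError("tally requires at least one history")
    for events in event_sets:
        n_trees += 1
        for population in ("counted", "all"):
            for direction in DIRECTIONS:
                key = (population, direction)
                n = sum(
                    1
                    for ev in events
                    if ev.direction == direction
                    and (ev.counted or population == "all")
                )
                per_tree.setdefault(key, []).append(n)
    rows = []
    for (population, direction), counts in per_tree.items():
        arr = np.asarray(counts, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_w = arr[arr >= q1 - 1.5 * iqr].min()
        hi_w = arr[arr <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "population": population,
                "direction": direction,
                "n_trees": n_trees,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": lo_w,
                "whisker_hi": hi_w,
                "total": int(arr.sum()),
            }
        )
    return pd.DataFrame(rows)


def events_table(events: Sequence[TransitionEvent]) -> pd.DataFrame:
    """Events as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "edge": ev.edge,
                "parent": ev.parent,
                "direction": ev.direction,
                "counted": ev.counted,
                "persistent_tip_count": ev.persistent_tip_count,
                "relative_time": ev.relative_time,
                "tie_flagged": ev.tie_flagged,
            }
            for ev in events
        ]
    )
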