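"""Community distinctness: unweighted UniFrac and similarity networks.

Unweighted UniFrac between two tip sets is the fraction of branch length
unique to one community among the branch length leading to either; 0 means
identical communities, 1 phylogenetically disjoint ones.  Significance is
assessed by a Monte-Carlo permutation test that shuffles tip-to-community
assignments across the union of the two communities (the scheme used by
mothur's unweighted test), with Bonferroni adjustment across pairs.

Sequence-similarity networks are built from all-against-all BLAST-style
hit tables at given identity/coverage thresholds, and habitat assortativity
(Newman's categorical coefficient) measures whether edges preferentially
connect same-habitat sequences — high assortativity means marine and
non-marine sequences form distinct clusters.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "unifrac_unweighted",
    "unifrac_significance",
    "upgma_dendrogram",
    "BLAST_COLUMNS",
    "read_hit_table",
    "build_graph",
    "assortativity",
]


def _edge_partition(
    tree: dendropy.Tree, a: set[str], b: set[str]
) -> tuple[float, float]:
    """(unique, total) branch length over branches leading to A and/or B."""
    below: dict[int, tuple[bool, bool]] = {}
    unique = 0.0
    total = 0.0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            flags = (label in a, label in b)
        else:
            in_a = in_b = False
            for c in nd.child_nodes():
                ca, cb = below[id(c)]
                in_a = in_a or ca
                in_b = in_b or cb
            flags = (in_a, in_b)
        below[id(nd)] = flags
        if nd is tree.seed_node:
            continue
        in_a, in_b = flags
        if in_a or in_b:
            length = nd.edge.length or 0.0
            total += length
            if in_a != in_b:
                unique += length
    return unique, total


def unifrac_unweighted(tree: dendropy.Tree, a: Iterable[str], b: Iterable[str]) -> float:
    """Unweighted UniFrac distance between tip sets ``a`` and ``b``."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("communities must be non-empty")
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    stray = (a | b) - tips
    if stray:
        raise ValueError(f"community members not in tree: {sorted(stray)[:5]}")
    unique, total = _edge_partition(tree, a, b)
    if total == 0.0:
        raise ValueError("no branch length leads to either community")
    return unique / total


def unifrac_significance(
    tree: dendropy.Tree,
    communities: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise UniFrac distances with Monte-Carlo p-values.

    The null distribution for each pair shuffles tip membership across the
    union of the two communities, preserving community sizes.  p-values are
    p = (1 + #{null >= observed}) / (1 + n_perm), Bonferroni-adjusted
    across all pairs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = sorted(communities)
    if len(names) < 2:
        raise ValueError("need at least 2 communities")
    sets = {k: set(communities[k]) for k in names}
    rng = np.random.default_rng(seed)
    pairs = [(x, y) for i, x in enumerate(names) for y in names[i + 1 :]]
    rows = []
    for x, y in pairs:
        obs = unifrac_unweighted(tree, sets[x], sets[y])
        # tips present in both communities stay in both under the shuffle;
        # exclusive memberships are reassigned at random, sizes preserved
        both = sets[x] & sets[y]
        pool = sorted((sets[x] | sets[y]) - both)
        n_x = len(sets[x] - both)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            pa, pb = set(perm[:n_x]), set(perm[n_x:])
            if unifrac_unweighted(tree, pa | both, pb | both) >= obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        rows.append({"a": x, "b": y, "distance": obs, "p": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def upgma_dendrogram(distances: pd.DataFrame | np.ndarray, names: Sequence[str] | None = None) -> str:
    """UPGMA clustering of a distance matrix, returned as Newick."""
    if isinstance(distances, pd.DataFrame):
        names = list(distances.index)
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        if names is None:
            names = [f"s{i}" for i in range(mat.shape[0])]
    from scipy.spatial.distance import squareform

    linkage = hierarchy.linkage(squareform(mat, checks=False), method="average")
    root, _ = hierarchy.to_tree(linkage, rd=True)

    def _newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = _newick(node.get_left(), node.dist)
        right = _newick(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({_newick(root.get_left(), root.dist)},{_newick(root.get_right(), root.dist)});"


BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(source: str | io.TextIOBase) -> pd.DataFrame:
    """Read a 12-column tabular (BLAST outfmt 6) hit table."""
    try:
        df = pd.read_csv(
            source, sep="\t", header=None, names=BLAST_COLUMNS, comment="#"
        )
    except Exception as exc:
        raise ValueError(f"malformed hit table: {exc}") from exc
    if df.shape[1] != 12:
        raise ValueError("hit table must have 12 tab-separated columns")
    for col in ("pident", "length", "qstart", "qend"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(
                f"malformed hit table row at line {int(bad.idxmax()) + 1}: "
                f"non-numeric {col}"
            )
        df[col] = pd.to_numeric(df[col])
    return df


def build_graph(
    hits: pd.DataFrame | str,
    habitats: Mapping[str, str],
    identity_threshold: float,
    coverage_threshold: float = 75.0,
    seq_lengths: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Build a habitat-labelled similarity graph from a pairwise hit table.

    An undirected edge joins two sequences when a hit between them passes
    the identity and query-coverage thresholds; self-hits are dropped and
    duplicate pairs are collapsed to the maximum-identity hit.  Query
    coverage is alignment length / query sequence length x 100 (requires
    ``seq_lengths``; when omitted, the alignment span relative to the
    largest observed query coordinate is used as a proxy).
    """
    if isinstance(hits, str) or isinstance(hits, io.TextIOBase):
        hits = read_hit_table(hits)
    g = nx.Graph()
    if seq_lengths is None:
        seq_lengths = hits.groupby("qseqid")["qend"].max().to_dict()
    for row in hits.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q == s:
            continue
        qlen = seq_lengths.get(q)
        if not qlen:
            raise ValueError(f"no sequence length for query {q!r}")
        coverage = 100.0 * row.length / qlen
        if row.pident < identity_threshold or coverage < coverage_threshold:
            continue
        if g.has_edge(q, s) and g[q][s]["identity"] >= row.pident:
            continue
        g.add_edge(q, s, identity=float(row.pident), coverage=float(coverage))
    for node in g.nodes:
        if node not in habitats:
            raise ValueError(f"no habitat label for sequence {node!r}")
        g.nodes[node]["habitat"] = str(habitats[node])
    return g


def assortativity(graph: nx.Graph) -> float:
    """Newman categorical assortativity of habitat labels over edges.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i); 1 when edges
    connect only same-habitat sequences, negative for disassortative
    mixing.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("assortativity undefined on an edgeless graph")
    labels = {d.get("habitat") for _, d in graph.nodes(data=True)}
    if len(labels) < 2:
        return 1.0  # single category: all mixing is within-habitat
    return float(nx.attribute_assortativity_coefficient(graph, "habitat"))
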