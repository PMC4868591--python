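"""Shared test utilities: random tree strings, brute-force rooting
oracles, and worked-example tree builders.

Everything here is deliberately independent of the package's own
bipartition sweep: rootings are produced by dendropy's reroot machinery
and clades are collected by plain recursion over node children.
"""

from __future__ import annotations

import random

from cladesort import parse_tree
from cladesort.tree_io import PhyloTree, format_number


# ---------------------------------------------------------------------------
# random tree strings

def random_newick(
    rng: random.Random,
    labels: list[str],
    with_supports: bool = True,
    support_range: tuple[int, int] = (0, 100),
) -> str:
    """Random rooted binary tree string over ``labels``."""

    def build(ls: list[str]) -> str:
        if len(ls) == 1:
            return f"{ls[0]}:{rng.randint(1, 9)}"
        k = rng.randint(1, len(ls) - 1)
        left, right = build(ls[:k]), build(ls[k:])
        sup = (
            format_number(rng.randint(*support_range)) if with_supports else ""
        )
        return f"({left},{right}){sup}:{rng.randint(1, 9)}"

    ls = list(labels)
    rng.shuffle(ls)
    k = rng.randint(1, len(ls) - 1)
    return f"({build(ls[:k])},{build(ls[k:])});"


# ---------------------------------------------------------------------------
# brute-force oracles over all rootings

def _labels_below(nd) -> frozenset:
    if nd.is_leaf():
        return frozenset([nd.label])
    out = frozenset()
    for child in nd.child_nodes():
        out |= _labels_below(child)
    return out


def _edge_support_map(tree: PhyloTree) -> dict:
    """Canonical split key -> support, from the rooted file form.

    A bifurcated root means two nodes may annotate the same unrooted
    edge; the larger value wins (absent counts lowest), matching how
    the file's annotation is interpreted.
    """
    all_tips = frozenset(tree.tip_labels)
    out: dict = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = _labels_below(nd)
        key = frozenset((below, all_tips - below))
        prev = out.get(key)
        if prev is None or (nd.support is not None and nd.support > prev):
            out[key] = nd.support
    return out


def all_rootings(newick: str) -> list[PhyloTree]:
    """Every rooting of the tree (one per edge), with support values
    re-attached to the correct edges after rerooting.

    Assumes unique tip labels.
    """
    base = parse_tree(newick)
    support_map = _edge_support_map(base)
    all_tips = frozenset(base.tip_labels)
    n_edges = sum(
        1 for nd in base.tree.preorder_node_iter() if nd.parent_node is not None
    )
    rootings = []
    for i in range(n_edges):
        pt = parse_tree(newick)
        edges = [
            nd.edge
            for nd in pt.tree.preorder_node_iter()
            if nd.parent_node is not None
        ]
        edge = edges[i]
        if edge.length is None:
            edge.length = 1.0
        pt.tree.reroot_at_edge(edge, update_bipartitions=False)
        pt.tree.suppress_unifurcations()
        for nd in pt.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if nd.parent_node is None:
                nd.support = None
                nd.label = None
                continue
            below = _labels_below(nd)
            sup = support_map.get(frozenset((below, all_tips - below)))
            nd.support = sup
            nd.label = None if sup is None else format_number(sup)
        rootings.append(pt)
    return rootings


def bruteforce_bipartition_sides(newick: str) -> set:
    """Union, over all rootings, of rooted clades whose own side and
    complement both hold >= 2 leaves.  Assumes unique tip labels."""
    base = parse_tree(newick)
    n = base.n_tips
    sides = set()
    for pt in all_rootings(newick):
        for nd in pt.tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            below = _labels_below(nd)
            if 2 <= len(below) <= n - 2:
                sides.add(below)
    return sides


# ---------------------------------------------------------------------------
# worked-example trees

def caterpillar(labels: list[str], length: int = 1) -> str:
    """Unsupported ladder subtree string over ``labels`` (no trailing length)."""
    out = f"{labels[0]}:{length}"
    for label in labels[1:]:
        out = f"({out},{label}:{length}):{length}"
    return out


def interrupted_clade_tree(
    n_rhodophyta: int = 10,
    n_viridiplantae: int = 7,
    n_stramenopiles: int = 6,
    n_interrupting: int = 1,
    support: int = 99,
) -> str:
    """Tree holding a supported clade of target leaves (three algal
    groups) interrupted by Haptophyceae tips, plus three target and
    three bacterial tips outside the clade."""
    targets = (
        [f"Rhodophyta_sp{i}" for i in range(1, n_rhodophyta + 1)]
        + [f"Viridiplantae_sp{i}" for i in range(1, n_viridiplantae + 1)]
        + [f"Stramenopiles_sp{i}" for i in range(1, n_stramenopiles + 1)]
    )
    interrupting = [f"Haptophyceae_sp{i}" for i in range(1, n_interrupting + 1)]
    clade = caterpillar(targets + interrupting)
    clade = clade.rsplit(":", 1)[0] + f"{support}:1"  # support on the full clade
    outside = caterpillar(
        [
            "Rhodophyta_out1",
            "Viridiplantae_out1",
            "Stramenopiles_out1",
            "Cyanobacteria_sp1",
            "Proteobacteria_sp1",
            "Firmicutes_sp1",
        ]
    )
    return f"({clade},{outside});"


def exclusive_clade_tree(n_in_clade: int = 24, n_targets_outside: int = 5) -> str:
    """Tree with a support-99 all-target clade plus stray targets and
    bacteria outside it."""
    inside = [f"Rhodophyta_sp{i}" for i in range(1, n_in_clade + 1)]
    clade = caterpillar(inside)
    clade = clade.rsplit(":", 1)[0] + "99:1"
    outside = caterpillar(
        [f"Viridiplantae_out{i}" for i in range(1, n_targets_outside + 1)]
        + ["Cyanobacteria_sp1", "Proteobacteria_sp1", "Firmicutes_sp1"]
    )
    return f"({clade},{outside});"
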