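"""Benchmark tree generator.

For a requested final size of X tips, a random bifurcating base
topology with round(1.05*X) tips is built by random sequential
attachment.  One internal clade of round(0.2*X) tips carries the target
term in its labels; the remaining labels are drawn from a fixed
non-target vocabulary and shuffled.  round(0.05*X) non-target tips are
then pruned (suppressing the resulting degree-2 nodes), leaving exactly
X tips and — unless building a negative control — exactly one maximal
all-target clade.  Every internal node receives a single fill support
value and every edge a uniform (0, 1] branch length.  Files are written
with eNewick support placement.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy

from .tree_io import ENEWICK, PhyloTree, format_number, to_enewick

__all__ = [
    "SimulationSpec",
    "SimulationError",
    "simulate_tree",
    "simulate_set",
    "DEFAULT_TARGET_TERM",
    "NONTARGET_VOCABULARY",
]

DEFAULT_TARGET_TERM = "Targetgroup"

#: lineage-like prefixes for non-target tips; none may contain the
#: target term as a substring (checked at simulation time)
NONTARGET_VOCABULARY = (
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Cyanobacteria",
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
    "Haptophyceae",
    "Cryptophyta",
    "Euglenozoa",
    "Amoebozoa",
    "Opisthokonta",
)


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one benchmark set.

    ``target_fraction`` (0.2) and ``surplus_fraction`` (0.05) define the
    embedded-clade size and the number of tips pruned from the oversize
    base tree; X values that keep both integral (multiples of 20) are
    recommended.
    """

    x: int
    n: int = 1
    seed: int = 0
    negative_control: bool = False
    target_term: str = DEFAULT_TARGET_TERM
    support_fill: float = 100.0
    target_fraction: float = 0.2
    surplus_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.x < 20:
            raise SimulationError("x must be >= 20 (target clade would be too small)")
        if self.n < 1:
            raise SimulationError("n must be >= 1")
        if not self.target_term:
            raise SimulationError("target_term must be non-empty")
        if self.support_fill < 0:
            raise SimulationError("support_fill must be >= 0")
        if self.n_removed < 0:
            raise SimulationError("negative number of tips to remove")

    @property
    def n_base_tips(self) -> int:
        return round((1.0 + self.surplus_fraction) * self.x)

    @property
    def n_removed(self) -> int:
        return round(self.surplus_fraction * self.x)

    @property
    def n_target_clade(self) -> int:
        return round(self.target_fraction * self.x)


def _random_topology(labels: list[str], rng: random.Random) -> dendropy.Node:
    """Rooted bifurcating topology over ``labels`` by random sequential
    attachment; returns the subtree root node."""
    if len(labels) == 1:
        leaf = dendropy.Node()
        leaf.label = labels[0]
        return leaf
    root = dendropy.Node()
    attachable: list[dendropy.Node] = []
    for label in labels[:2]:
        leaf = dendropy.Node()
        leaf.label = label
        root.add_child(leaf)
        attachable.append(leaf)
    for label in labels[2:]:
        host = attachable[rng.randrange(len(attachable))]
        parent = host.parent_node
        joint = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(joint)
        joint.add_child(host)
        leaf = dendropy.Node()
        leaf.label = label
        joint.add_child(leaf)
        attachable.append(joint)
        attachable.append(leaf)
    return root


def _prune_leaf(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    # suppress the degree-2 node this leaves behind
    if parent.num_child_nodes() == 1 and parent.parent_node is not None:
        grand = parent.parent_node
        child = parent.child_nodes()[0]
        grand.remove_child(parent)
        grand.add_child(child)
    while tree.seed_node.num_child_nodes() == 1:
        new_root = tree.seed_node.child_nodes()[0]
        tree.seed_node.remove_child(new_root)
        tree.seed_node = new_root


def simulate_tree(
    spec: SimulationSpec, rng: Optional[random.Random] = None
) -> PhyloTree:
    """Generate one benchmark tree with exactly ``spec.x`` tips."""
    if rng is None:
        rng = random.Random(spec.seed)

    n_nontarget = spec.n_base_tips - (
        0 if spec.negative_control else spec.n_target_clade
    )
    nontarget_labels = []
    for i in range(n_nontarget):
        label = f"{NONTARGET_VOCABULARY[i % len(NONTARGET_VOCABULARY)]}_sp{i + 1:03d}"
        if spec.target_term in label:
            raise SimulationError(
                f"target term {spec.target_term!r} collides with the "
                "non-target label vocabulary"
            )
        nontarget_labels.append(label)
    rng.shuffle(nontarget_labels)  # random label swap among non-targets

    backbone = _random_topology(nontarget_labels, rng)
    tree = dendropy.Tree()
    tree.seed_node = backbone

    if not spec.negative_control:
        target_labels = [
            f"{spec.target_term}_tax{i + 1:03d}" for i in range(spec.n_target_clade)
        ]
        subtree = _random_topology(target_labels, rng)
        hosts = [
            nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
        ]
        host = hosts[rng.randrange(len(hosts))]
        parent = host.parent_node
        joint = dendropy.Node()
        parent.remove_child(host)
        parent.add_child(joint)
        joint.add_child(host)
        joint.add_child(subtree)

    removable = [
        nd
        for nd in tree.leaf_node_iter()
        if spec.target_term not in nd.label
    ]
    for leaf in rng.sample(removable, spec.n_removed):
        _prune_leaf(tree, leaf)

    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = round(1.0 - rng.random(), 6)
        if nd.is_leaf():
            nd.support = None
        elif nd.parent_node is not None:
            nd.support = float(spec.support_fill)
            nd.label = format_number(nd.support)
        else:
            nd.support = None
            nd.label = None

    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips != spec.x:
        raise SimulationError(
            f"internal error: simulated tree has {n_tips} tips, expected {spec.x}"
        )
    return PhyloTree(tree, source_dialect=ENEWICK)


def simulate_set(
    spec: SimulationSpec,
    out_dir: Path,
    replicate_topology: bool = True,
) -> list[Path]:
    """Write ``spec.n`` eNewick files plus a ``manifest.tsv`` ground-truth map.

    With ``replicate_topology`` (the benchmark design) all files hold
    the same tree — one technical replicate; otherwise each file is an
    independent draw from the same seeded stream.  Identical specs and
    seeds produce byte-identical file sets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(spec.n)))
    names = [f"tree_{i + 1:0{width}d}.tre" for i in range(spec.n)]
    for name in names:
        if (out_dir / name).exists():
            raise SimulationError(f"refusing to overwrite existing file: {out_dir / name}")

    rng = random.Random(spec.seed)
    truth = "negative" if spec.negative_control else "exclusive"
    paths: list[Path] = []
    if replicate_topology:
        text = to_enewick(simulate_tree(spec, rng)) + "\n"
        texts = [text] * spec.n
    else:
        texts = [to_enewick(simulate_tree(spec, rng)) + "\n" for _ in range(spec.n)]
    for name, text in zip(names, texts):
        path = out_dir / name
        path.write_text(text)
        paths.append(path)

    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("filename\tground_truth\n")
        for name in names:
            fh.write(f"{name}\t{truth}\n")
    return paths
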