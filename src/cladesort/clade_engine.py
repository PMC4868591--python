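"""Clade identification and classification on unrooted trees.

Tip labels are matched against user-supplied target terms by exact,
case-sensitive substring search.  Every internal edge of the unrooted
topology defines a bipartition of the tips; *both* leaf-set sides are
candidate clades and share the support value annotated on that edge.
Candidates are then classified as Exclusive (targets only) or
Non-Exclusive (a small, bounded fraction of interrupting non-target
leaves), subject to support and whole-tree target-proportion thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy

from .tree_io import PhyloTree

__all__ = [
    "ALL_EXCLUSIVE",
    "EXCLUSIVE",
    "NON_EXCLUSIVE",
    "TargetSpecError",
    "CriteriaError",
    "TargetSpec",
    "SortCriteria",
    "CandidateClade",
    "TreeClassification",
    "match_targets",
    "enumerate_bipartitions",
    "classify_clade",
    "classify_tree",
]

ALL_EXCLUSIVE = "ALL_EXCLUSIVE"
EXCLUSIVE = "EXCLUSIVE"
NON_EXCLUSIVE = "NON_EXCLUSIVE"

#: clade-family request codes
FAMILY_EXCLUSIVE = "E"
FAMILY_NON_EXCLUSIVE = "NE"
_VALID_FAMILIES = frozenset({FAMILY_EXCLUSIVE, FAMILY_NON_EXCLUSIVE})


class TargetSpecError(ValueError):
    """Invalid target-term configuration."""


class CriteriaError(ValueError):
    """Invalid sorting-threshold configuration."""


@dataclass(frozen=True)
class TargetSpec:
    """Ordered, case-sensitive substring terms identifying target tips."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise TargetSpecError("at least one target term is required")
        for term in self.terms:
            if not term:
                raise TargetSpecError("target terms must be non-empty")
        for i, a in enumerate(self.terms):
            for j, b in enumerate(self.terms):
                if i != j and a in b:
                    raise TargetSpecError(
                        f"target terms must be unique: {a!r} is a "
                        f"substring of {b!r}"
                    )

    @classmethod
    def from_string(cls, text: str) -> "TargetSpec":
        """Build from a comma-separated term list, e.g. ``"Rhodophyta,Viridiplantae"``."""
        return cls(tuple(t.strip() for t in text.split(",") if t.strip()))

    def matches(self, label: str) -> bool:
        return any(term in label for term in self.terms)


@dataclass(frozen=True)
class SortCriteria:
    """Threshold bundle controlling which clades qualify.

    ``min_support`` is compared on the file's native support scale.
    ``min_prop_target`` is the minimum fraction of *all* target leaves
    in the tree that a clade must contain.  ``clade_exclusivity`` is the
    minimum within-clade target fraction for a Non-Exclusive clade
    (1.0 is disallowed: a fully-target clade is Exclusive instead).
    """

    min_support: float = 0.0
    min_prop_target: float = 0.7
    clade_exclusivity: float = 0.9
    clades_sorted: frozenset = field(
        default=frozenset({FAMILY_EXCLUSIVE, FAMILY_NON_EXCLUSIVE})
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "clades_sorted", frozenset(self.clades_sorted))
        if not self.clades_sorted or not self.clades_sorted <= _VALID_FAMILIES:
            raise CriteriaError(
                "clades_sorted must be a non-empty subset of {'E', 'NE'}"
            )
        if self.min_support < 0:
            raise CriteriaError("min_support must be >= 0")
        if not 0.0 <= self.min_prop_target <= 1.0:
            raise CriteriaError("min_prop_target must be within [0.0, 1.0]")
        if self.clade_exclusivity >= 1.0:
            raise CriteriaError(
                "clade_exclusivity must be < 1.0 (specification of 1.0 is "
                "not allowed: a fully-target clade is Exclusive)"
            )
        if self.clade_exclusivity < 0.0:
            raise CriteriaError("clade_exclusivity must be >= 0.0")


@dataclass(frozen=True)
class CandidateClade:
    """One side of an internal-edge bipartition, with target tallies."""

    leaf_labels: tuple[str, ...]
    support: float
    n_target: int
    n_nontarget: int
    prop_of_tree_targets: float

    @property
    def size(self) -> int:
        return self.n_target + self.n_nontarget

    @property
    def prop_within(self) -> float:
        return self.n_target / self.size if self.size else 0.0


@dataclass(frozen=True)
class TreeClassification:
    """Per-tree outcome: labels plus every qualifying clade with its tag."""

    source_file: Optional[Path]
    labels: frozenset
    qualifying_clades: tuple  # of (CandidateClade, tag) pairs

    @property
    def is_hit(self) -> bool:
        return bool(self.labels)


def match_targets(
    tree: PhyloTree, targets: TargetSpec
) -> tuple[list[str], list[str]]:
    """Partition tip labels (per leaf, duplicates counted) into
    target and non-target lists."""
    hits: list[str] = []
    misses: list[str] = []
    for label in tree.tip_labels:
        (hits if targets.matches(label) else misses).append(label)
    return hits, misses


def _leafsets_below(tree: dendropy.Tree) -> dict:
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([id(nd)])
        else:
            acc = frozenset()
            for child in nd.child_nodes():
                acc |= below[child]
            below[nd] = acc
    return below


def enumerate_bipartitions(
    tree: PhyloTree, targets: Optional[TargetSpec] = None
) -> list[CandidateClade]:
    """Emit both sides of every internal edge of the unrooted topology.

    Each non-trivial bipartition (both sides holding >= 2 leaves)
    contributes exactly two candidates that partition the tip set and
    share the edge's support.  A bifurcated root in the file collapses
    onto a single unrooted edge; when its two children disagree on the
    annotated support, the larger value is used.  Absent support counts
    as 0.
    """
    leaves = tree.leaf_nodes()
    labels = {id(nd): nd.label for nd in leaves}
    is_target = {
        id(nd): bool(targets and targets.matches(nd.label)) for nd in leaves
    }
    total_targets = sum(is_target.values())
    all_ids = frozenset(labels)
    n = len(leaves)
    if n < 4:
        return []

    below = _leafsets_below(tree.tree)
    splits: dict = {}  # normalized split -> [side_ids, support]
    order: list = []
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = below[nd]
        if len(side) < 2 or n - len(side) < 2:
            continue
        comp = all_ids - side
        key = frozenset((side, comp))
        support = nd.support if nd.support is not None else 0.0
        if key in splits:
            splits[key][1] = max(splits[key][1], support)
        else:
            splits[key] = [side, support]
            order.append(key)

    def _make(side_ids: frozenset, support: float) -> CandidateClade:
        names = tuple(sorted(labels[i] for i in side_ids))
        nt = sum(1 for i in side_ids if is_target[i])
        return CandidateClade(
            leaf_labels=names,
            support=support,
            n_target=nt,
            n_nontarget=len(side_ids) - nt,
            prop_of_tree_targets=(nt / total_targets) if total_targets else 0.0,
        )

    candidates: list[CandidateClade] = []
    for key in order:
        side, support = splits[key]
        candidates.append(_make(side, support))
        candidates.append(_make(all_ids - side, support))
    return candidates


def classify_clade(
    clade: CandidateClade, criteria: SortCriteria
) -> Optional[str]:
    """Tag a candidate as EXCLUSIVE, NON_EXCLUSIVE or None.

    Threshold comparisons are inclusive (>=) and exact — proportions are
    small rationals, so no epsilon is applied.
    """
    if clade.support < criteria.min_support:
        return None
    if clade.prop_of_tree_targets < criteria.min_prop_target:
        return None
    if clade.n_nontarget == 0:
        return EXCLUSIVE if clade.n_target >= 2 else None
    if criteria.clade_exclusivity <= clade.prop_within < 1.0:
        return NON_EXCLUSIVE
    return None


def classify_tree(
    tree: PhyloTree,
    targets: TargetSpec,
    criteria: Optional[SortCriteria] = None,
    source_file: Optional[Path] = None,
) -> TreeClassification:
    """Classify one tree: unrooted bipartition sweep plus the
    all-target check.

    Labels are restricted to the requested clade families; an all-target
    tree gets ALL_EXCLUSIVE (and EXCLUSIVE) on leaf composition alone,
    with no support or proportion requirement.  The result is invariant
    to how the input file happens to be rooted.
    """
    if criteria is None:
        criteria = SortCriteria()
    want_e = FAMILY_EXCLUSIVE in criteria.clades_sorted
    want_ne = FAMILY_NON_EXCLUSIVE in criteria.clades_sorted

    target_labels, nontarget_labels = match_targets(tree, targets)
    labels: set = set()
    qualifying: list = []

    for clade in enumerate_bipartitions(tree, targets):
        tag = classify_clade(clade, criteria)
        if tag == EXCLUSIVE and want_e:
            labels.add(EXCLUSIVE)
            qualifying.append((clade, tag))
        elif tag == NON_EXCLUSIVE and want_ne:
            labels.add(NON_EXCLUSIVE)
            qualifying.append((clade, tag))

    if want_e and target_labels and not nontarget_labels:
        labels.add(ALL_EXCLUSIVE)
        labels.add(EXCLUSIVE)

    qualifying.sort(key=lambda pair: (-pair[0].size, pair[0].leaf_labels))
    return TreeClassification(
        source_file=source_file,
        labels=frozenset(labels),
        qualifying_clades=tuple(qualifying),
    )
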