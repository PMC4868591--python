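"""Reading, writing and dialect conversion for phylogenetic trees.

Two plain-text dialects are handled:

* standard Newick, where an internal node's support value is written as
  a node label before the colon — ``(A:1,B:1)99:0.5``;
* the extended-Newick ("eNewick") support placement, where the value
  follows the branch length in square brackets — ``(A:1,B:1):0.5[99]``.

Only the support-placement flavour of eNewick is accepted; hybrid-node
network syntax (``#H`` tags) is rejected.  Support values are kept on
whatever scale the file uses (0–1 or 0–100); no rescaling happens here.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterator, Optional

import dendropy

__all__ = [
    "NEWICK",
    "ENEWICK",
    "PhyloTree",
    "NewickParseError",
    "EnewickConversionError",
    "StandardNewickWarning",
    "parse_tree",
    "convert_enewick",
    "write_tree",
    "to_enewick",
]

NEWICK = "newick"
ENEWICK = "enewick"


class NewickParseError(ValueError):
    """Raised when a tree string cannot be parsed."""


class EnewickConversionError(ValueError):
    """Raised when a bracketed support value cannot be rewritten."""


class StandardNewickWarning(UserWarning):
    """Emitted when eNewick conversion receives standard Newick input."""


_NUM = r"[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"
# `):L[S]` — bracketed support following an internal node's branch length
_SUPPORT_BRACKET = re.compile(rf"\)\s*:\s*({_NUM})\s*\[\s*({_NUM})\s*\]")
# any bracketed number immediately after a branch length (dialect hint)
_DIALECT_HINT = re.compile(rf":\s*{_NUM}\s*\[")
# inverse rewrite: `)S:L` -> `):L[S]`
_LABEL_THEN_LENGTH = re.compile(rf"\)({_NUM}):({_NUM})")

_QUOTE_TRIGGERS = set(" ()[]{}:;,'\"")


def convert_enewick(text: str) -> str:
    """Rewrite eNewick support brackets into standard Newick node labels.

    Every ``):L[S]`` token becomes ``)S:L``.  Standard Newick input is
    returned unchanged with a :class:`StandardNewickWarning`.  A bracket
    that is not attached to an internal node's branch length (e.g. on a
    tip, or with no preceding length) raises
    :class:`EnewickConversionError`, as does hybrid-node syntax.
    """
    if "#" in text:
        raise EnewickConversionError(
            "hybrid-node eNewick syntax ('#' tags) is not supported"
        )
    out, n_rewritten = _SUPPORT_BRACKET.subn(r")\2:\1", text)
    bad = out.find("[")
    if bad != -1:
        raise EnewickConversionError(
            "bracketed support value not attached to an internal node's "
            f"branch length (character {bad} after rewriting)"
        )
    if n_rewritten == 0:
        warnings.warn(
            "input contains no support brackets; already standard Newick",
            StandardNewickWarning,
            stacklevel=2,
        )
    return out


def _validate_syntax(text: str) -> None:
    if not text or not text.strip():
        raise NewickParseError("empty input")
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at character {i}")
    if depth > 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at end of input (character {len(text)})"
        )
    if ";" not in text:
        raise NewickParseError(
            f"missing ';' terminator at character {len(text)}"
        )


def _support_from_label(label: Optional[str]) -> Optional[float]:
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError:
        return None  # non-numeric labels carry no support
    if value != value or value in (float("inf"), float("-inf")):
        return None
    if value < 0:
        raise NewickParseError(f"negative support value {label!r}")
    return value


class PhyloTree:
    """An unrooted phylogenetic tree with labeled tips and node support.

    Thin wrapper over a rooted :class:`dendropy.Tree` representation.
    Tip names live on ``node.label`` (duplicates permitted); each
    internal node carries ``node.support`` (float, or None when absent)
    alongside its raw label.
    """

    __slots__ = ("tree", "source_dialect")

    def __init__(self, tree: dendropy.Tree, source_dialect: str = NEWICK):
        self.tree = tree
        self.source_dialect = source_dialect

    @property
    def tip_labels(self) -> list[str]:
        return [nd.label for nd in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def leaf_nodes(self) -> list[dendropy.Node]:
        return list(self.tree.leaf_node_iter())

    def internal_nodes(self, exclude_root: bool = False) -> Iterator[dendropy.Node]:
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            if exclude_root and nd.parent_node is None:
                continue
            yield nd

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {self.n_tips} tips, dialect={self.source_dialect}>"


def parse_tree(text: str) -> PhyloTree:
    """Parse a standard-Newick or eNewick tree string.

    Dialect is auto-detected: a bracketed value immediately following a
    branch length marks the input as eNewick, which is rewritten via
    :func:`convert_enewick` before parsing.  Supports are captured on
    the file's native scale; nodes without a numeric label have absent
    (``None``) support.
    """
    _validate_syntax(text)
    if "#" in text:
        raise NewickParseError(
            "hybrid-node eNewick networks ('#' tags) are not supported"
        )
    dialect = NEWICK
    if _DIALECT_HINT.search(text):
        dialect = ENEWICK
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", StandardNewickWarning)
                text = convert_enewick(text)
        except EnewickConversionError as exc:
            raise NewickParseError(str(exc)) from exc
    elif "[" in text:
        raise NewickParseError(
            "bracketed value without a preceding branch length at "
            f"character {text.find('[')}"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises reader-specific subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            if not nd.label:
                raise NewickParseError("tree contains an unlabeled tip")
            nd.support = None
        else:
            nd.support = _support_from_label(nd.label)
        if nd.edge.length is not None and nd.edge.length < 0:
            raise NewickParseError(
                f"negative branch length {nd.edge.length}"
            )
    return PhyloTree(tree, source_dialect=dialect)


def format_number(value: float) -> str:
    """Minimal decimal form: integers lose the trailing ``.0``."""
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(value)


def _quoted(label: str) -> str:
    if any(ch in _QUOTE_TRIGGERS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_text(nd: dendropy.Node) -> str:
    if nd.is_leaf():
        out = _quoted(nd.label)
    else:
        out = "(" + ",".join(_node_text(c) for c in nd.child_nodes()) + ")"
        label = nd.label
        if label is None and getattr(nd, "support", None) is not None:
            label = format_number(nd.support)
        if label is not None:
            out += _quoted(label)
    if nd.parent_node is not None and nd.edge.length is not None:
        out += ":" + format_number(nd.edge.length)
    return out


def write_tree(tree: PhyloTree) -> str:
    """Serialize to standard Newick, support as internal node label."""
    return _node_text(tree.tree.seed_node) + ";"


def to_enewick(tree: PhyloTree) -> str:
    """Serialize with eNewick support placement (``):L[S]``).

    Requires every supported internal node to also carry a branch
    length, since the dialect attaches the bracket to the length.
    """
    for nd in tree.internal_nodes(exclude_root=True):
        if getattr(nd, "support", None) is not None and nd.edge.length is None:
            raise EnewickConversionError(
                "cannot place support in brackets: node has no branch length"
            )
    return _LABEL_THEN_LENGTH.sub(r"):\2[\1]", write_tree(tree))
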