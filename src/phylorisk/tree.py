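"""Rooted phylogenetic trees with branch lengths, plus Newick and metadata I/O.

The tree model is deliberately small: a :class:`PhyloTree` is a rooted tree of
:class:`Node` objects, each carrying the length of the branch *above* it.  A
branch is therefore identified by its child node, and the "descendants of a
branch" are the tips below that node — the convention every downstream index
(PD, branch-loss probability, EDGE credits, range unions) relies on.  A stem
branch above the root is permitted and is stored as the root node's length.

Newick parsing is delegated to :mod:`dendropy`; this module only normalises
the result into the lightweight structure used by the rest of the package.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "IUCN_CATEGORIES",
    "Node",
    "PhyloTree",
    "TipMetadata",
    "NewickParseError",
    "TreeValidationError",
    "MetadataError",
    "read_newick",
    "write_newick",
    "read_metadata",
]

#: Closed vocabulary of IUCN Red List categories used throughout.
IUCN_CATEGORIES = ("CE", "E", "V", "NT", "LC", "DD", "NE")


class NewickParseError(ValueError):
    """Malformed Newick input; message includes the source position."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate tips, negative lengths, ...)."""


class MetadataError(ValueError):
    """Invalid tip-metadata table."""


class Node:
    """A tree node; ``length`` is the branch above this node (>= 0)."""

    __slots__ = ("label", "length", "parent", "children", "_tipset")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self._tipset: frozenset[str] | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def tipset(self) -> frozenset[str]:
        """Labels of all tips descended from (or equal to) this node."""
        if self._tipset is None:
            if self.is_tip:
                self._tipset = frozenset((self.label,))
            else:
                s: set[str] = set()
                for c in self.children:
                    s.update(c.tipset)
                self._tipset = frozenset(s)
        return self._tipset

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label or ''} {kind} L={self.length}>"


class PhyloTree:
    """Rooted tree with non-negative branch lengths and unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        labels = [t.label for t in self.tips()]
        if any(not lab for lab in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self.preorder():
            if node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} at {node.label or 'internal node'}"
                )

    # -- traversal ---------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def branches(self) -> list[Node]:
        """All branches, each identified by its child node.

        Every non-root node is a branch; the root is included only when it
        carries a stem (positive length above the root).
        """
        out = []
        for node in self.preorder():
            if node.parent is not None or node.length > 0:
                out.append(node)
        return out

    def total_length(self) -> float:
        return sum(b.length for b in self.branches())

    # -- lookup ------------------------------------------------------------

    def tip(self, label: str) -> Node:
        for t in self.tips():
            if t.label == label:
                return t
        raise KeyError(f"unknown tip label: {label!r}")

    def find_clade(self, label: str) -> Node:
        """Node whose (internal or tip) label matches, searched preorder."""
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def clade_branches(self, node: Node) -> list[Node]:
        """The branch above ``node`` plus every branch inside its clade."""
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return out


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | os.PathLike | io.TextIOBase, default_length: float | None = None) -> PhyloTree:
    """Parse a Newick string, path or handle into a :class:`PhyloTree`.

    Internal-node labels (commonly bootstrap supports) are stored but unused.
    Branch lengths are mandatory unless ``default_length`` is given.  A length
    on the outermost group becomes a stem above the root.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        path = os.fspath(source)
        if not os.path.exists(path):
            raise FileNotFoundError(f"tree file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(str(exc)) from exc

    def convert(dnode) -> Node:
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is None:
                length = 0.0  # stemless root
            elif default_length is not None:
                length = default_length
            else:
                raise TreeValidationError(
                    "branch length missing (pass default_length to fill gaps)"
                )
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def _fmt_length(x: float) -> str:
    # shortest round-tripping representation; integers without the trailing .0
    return str(int(x)) if x == int(x) else repr(x)


def _newick_node(node: Node) -> str:
    label = node.label or ""
    length = f":{_fmt_length(node.length)}"
    if node.is_tip:
        return f"{label}{length}"
    inner = ",".join(_newick_node(c) for c in node.children)
    return f"({inner}){label}{length}"


def write_newick(tree: PhyloTree) -> str:
    """Serialise to Newick; a positive root length is written as a stem."""
    root = tree.root
    inner = ",".join(_newick_node(c) for c in root.children)
    label = root.label or ""
    stem = f":{_fmt_length(root.length)}" if root.length > 0 else ""
    return f"({inner}){label}{stem};"


# ---------------------------------------------------------------------------
# Tip metadata


@dataclass(frozen=True)
class TipMetadata:
    """IUCN category, optional explicit extinction probability, localities.

    An explicit probability, when present, overrides whatever the category
    would convert to.
    """

    label: str
    category: str = "NE"
    probability: float | None = None
    localities: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.category not in IUCN_CATEGORIES:
            raise MetadataError(
                f"unknown IUCN category {self.category!r} for tip {self.label!r}; "
                f"expected one of {IUCN_CATEGORIES}"
            )
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise MetadataError(
                f"extinction probability {self.probability} for {self.label!r} not in [0, 1]"
            )


def read_metadata(
    source: str | os.PathLike | io.TextIOBase,
    tree: PhyloTree | None = None,
    strict: bool = False,
) -> dict[str, TipMetadata]:
    """Read a tab-separated tip-metadata table.

    Columns: ``tip``, ``iucn_category``, optional ``probability``, optional
    ``localities`` (semicolon-separated).  When a tree is supplied, table rows
    naming unknown tips warn (or raise when ``strict``), and tree tips missing
    from the table are recorded as not evaluated (NE).
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if "tip" not in df.columns or "iucn_category" not in df.columns:
        raise MetadataError("metadata table needs 'tip' and 'iucn_category' columns")

    out: dict[str, TipMetadata] = {}
    tree_tips = set(tree.tip_labels) if tree is not None else None
    for _, row in df.iterrows():
        tip = row["tip"].strip()
        if tree_tips is not None and tip not in tree_tips:
            msg = f"metadata row for {tip!r} does not match any tree tip"
            if strict:
                raise MetadataError(msg)
            import warnings

            warnings.warn(msg, stacklevel=2)
        prob_raw = row.get("probability", "").strip() if "probability" in df.columns else ""
        prob = float(prob_raw) if prob_raw else None
        loc_raw = row.get("localities", "").strip() if "localities" in df.columns else ""
        locs = frozenset(p.strip() for p in loc_raw.split(";") if p.strip())
        out[tip] = TipMetadata(
            label=tip,
            category=row["iucn_category"].strip(),
            probability=prob,
            localities=locs,
        )
    if tree_tips is not None:
        for tip in sorted(tree_tips - set(out)):
            out[tip] = TipMetadata(label=tip, category="NE")
    return out


def write_metadata(metadata: dict[str, TipMetadata], path: str | os.PathLike) -> None:
    rows = []
    for tip in sorted(metadata):
        m = metadata[tip]
        rows.append(
            {
                "tip": m.label,
                "iucn_category": m.category,
                "probability": "" if m.probability is None else repr(m.probability),
                "localities": ";".join(sorted(m.localities)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
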