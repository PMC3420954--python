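"""Time-calibrated trees (chronograms): reading, validation, and queries.

A :class:`Chronogram` is a rooted tree whose branch lengths are in units of
absolute time (millions of years, MY).  Downstream likelihood code addresses
nodes by integer id; user-facing interfaces address internal nodes by the
unordered pair of tip labels whose most recent common ancestor they are
(e.g. ``"A|B"``), which is stable under ladderization and label reordering.

Newick parsing and writing are delegated to :mod:`dendropy`; the in-memory
representation here is a flat arrays-of-parents structure convenient for the
pruning algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "mrca",
    "node_age",
    "reroot_at_node",
]

#: Relative tolerance for the ultrametricity check. Published chronograms
#: carry rounding error, so exact path-length equality is not required.
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed into a chronogram."""


@dataclass
class Chronogram:
    """Rooted tree with branch lengths in MY.

    Node ids are integers ``0 .. n_nodes-1`` in postorder (tips and internal
    nodes interleaved; the root is always the last id).  ``parent[root]`` is
    ``-1`` and ``branch_length[root]`` is ``nan``.
    """

    parent: np.ndarray
    branch_length: np.ndarray
    children: list[list[int]]
    labels: list[str | None]
    _tip_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._tip_index:
            self._tip_index = {
                self.labels[i]: i for i in self.tip_ids if self.labels[i] is not None
            }

    # -- structure -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def postorder(self) -> range:
        """Node ids in postorder (children always precede parents)."""
        return range(self.n_nodes)

    # -- metric queries ------------------------------------------------
    def depths(self) -> np.ndarray:
        """Distance from the root to every node, in MY."""
        d = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):  # preorder, skipping root
            d[v] = d[self.parent[v]] + self.branch_length[v]
        return d

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        tip_depths = self.depths()[self.tip_ids]
        h = tip_depths.max()
        if h == 0:
            return True
        return bool(np.all(np.abs(tip_depths - h) <= rtol * h))

    def validate(self, require_ultrametric: bool = False) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        labels = [l for l in (self.labels[i] for i in self.tip_ids)]
        if any(l is None for l in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        bl = self.branch_length[: self.n_nodes - 1]
        if np.any(~np.isfinite(bl)) or np.any(bl < 0):
            raise ValueError("all non-root branch lengths must be finite and >= 0")
        if require_ultrametric and not self.is_ultrametric():
            raise ValueError("tree is not ultrametric within tolerance")


def _from_dendropy(dtree: dendropy.Tree) -> Chronogram:
    dnodes = [nd for nd in dtree.postorder_node_iter()]
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.full(n, np.nan)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: list[str | None] = [None] * n
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else "an internal node"
                raise NewickParseError(f"missing branch length on the edge above {who}")
            blen[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label is not None:
            labels[i] = nd.label
    return Chronogram(parent=parent, branch_length=blen, children=children, labels=labels)


def read_newick(text: str) -> Chronogram:
    """Parse a newick string into a :class:`Chronogram`.

    Branch lengths must be present on every non-root edge.  Unbalanced
    parentheses are reported with the character offset of the imbalance.
    """
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' by character offset {len(text)}"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    tree.validate()
    return tree


def write_newick(tree: Chronogram) -> str:
    """Serialize with full float precision (round-trips to 1e-9 or better)."""

    def render(v: int) -> str:
        if tree.is_tip(v):
            body = tree.labels[v]
        else:
            inner = ",".join(render(c) for c in tree.children[v])
            body = f"({inner})" + (tree.labels[v] or "")
        if tree.parent[v] < 0:
            return body
        return f"{body}:{tree.branch_length[v]:.17g}"

    return render(tree.root) + ";"


def mrca(tree: Chronogram, taxa: set[str] | list[str] | tuple[str, ...]) -> int:
    """Most recent common ancestor of a set of tip labels.

    The mrca of a single tip is that tip itself.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    ids = [tree.tip_id(t) for t in taxa]
    # Postorder ids satisfy child < parent, so repeatedly lifting the
    # smallest id converges on the common ancestor.
    current = set(ids)
    while len(current) > 1:
        v = min(current)
        current.remove(v)
        current.add(int(tree.parent[v]))
    return current.pop()


def parse_node_spec(tree: Chronogram, spec: str) -> int:
    """Resolve a node address of the form ``"A|B"`` (two-tip mrca) or ``"A"``."""
    parts = [p.strip() for p in spec.split("|") if p.strip()]
    if not parts:
        raise ValueError(f"empty node specification: {spec!r}")
    return mrca(tree, parts)


def node_age(tree: Chronogram, node: int) -> float:
    """Age of a node in MY before present (tips are age 0).

    Requires an ultrametric tree; the age is the tree height minus the
    root-to-node distance.
    """
    if not tree.is_ultrametric():
        raise ValueError("node ages are only defined on ultrametric trees")
    d = tree.depths()
    h = d[tree.tip_ids].max()
    return float(max(h - d[node], 0.0))


def reroot_at_node(tree: Chronogram, new_root: int) -> Chronogram:
    """Return a copy of the tree rerooted at an internal node.

    The unrooted topology and all path lengths between tips are preserved;
    the old root, if left with a single child, is suppressed and its two
    incident branch lengths merged.  Used to check likelihood invariance of
    time-reversible models under root placement.
    """
    if tree.is_tip(new_root):
        raise ValueError("cannot reroot at a tip")
    if new_root == tree.root:
        return tree
    # Undirected adjacency with edge lengths.
    adj: dict[int, list[tuple[int, float]]] = {v: [] for v in range(tree.n_nodes)}
    for v in range(tree.n_nodes - 1):
        p = int(tree.parent[v])
        w = float(tree.branch_length[v])
        adj[v].append((p, w))
        adj[p].append((v, w))
    # Orient away from the new root.
    parent_of: dict[int, tuple[int, float]] = {}
    order = [new_root]
    seen = {new_root}
    stack = [new_root]
    while stack:
        v = stack.pop()
        for u, w in adj[v]:
            if u not in seen:
                seen.add(u)
                parent_of[u] = (v, w)
                order.append(u)
                stack.append(u)
    kids: dict[int, list[int]] = {v: [] for v in order}
    for u, (v, _) in parent_of.items():
        kids[v].append(u)
    # Suppress unifurcations (the old root typically becomes one).
    def resolve(v: int) -> tuple[int, float]:
        extra = 0.0
        while v in kids and len(kids[v]) == 1 and tree.labels[v] is None:
            child = kids[v][0]
            extra += parent_of[child][1]
            v = child
        return v, extra

    # Build the new chronogram in postorder.
    new_children_struct: list[list[int]] = []
    new_blen: list[float] = []
    new_labels: list[str | None] = []

    def build(v: int, pending: float) -> int:
        v, extra = resolve(v)
        child_ids = []
        for c in kids.get(v, []):
            child_ids.append(build(c, parent_of[c][1]))
        new_children_struct.append(child_ids)
        new_blen.append(pending + extra)
        new_labels.append(tree.labels[v])
        return len(new_children_struct) - 1

    root_id = build(new_root, float("nan"))
    n = len(new_children_struct)
    parent = np.full(n, -1, dtype=np.int64)
    for v, cs in enumerate(new_children_struct):
        for c in cs:
            parent[c] = v
    assert root_id == n - 1
    blen = np.array(new_blen)
    blen[root_id] = np.nan
    return Chronogram(
        parent=parent, branch_length=blen,
        children=new_children_struct, labels=new_labels,
    )


def ascii_sketch(tree: Chronogram) -> str:
    """Minimal indented text rendering, for CLI inspection only."""
    lines: list[str] = []

    def walk(v: int, indent: int) -> None:
        tag = tree.labels[v] or f"<{v}>"
        bl = tree.branch_length[v]
        suffix = "" if math.isnan(bl) else f" :{bl:g}"
        lines.append("  " * indent + tag + suffix)
        for c in tree.children[v]:
            walk(c, indent + 1)

    walk(tree.root, 0)
    return "\n".join(lines)
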