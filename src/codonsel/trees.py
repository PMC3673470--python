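"""Phylogeny handling: Newick I/O and foreground-branch tagging.

Trees are consumed, never inferred.  Input Newick may carry PAML-style
``#1`` branch tags marking foreground lineages for branch-site and
two-ratio tests; alternatively a plain-text clade file can name leaf sets
whose stem branches are tagged after parsing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "read_clade_file",
    "TreeParseError",
]

_TAG_RE = re.compile(r"\s*#\s*(\d+)\s*$")

#: Branch length substituted (with a warning) when the Newick omits one.
DEFAULT_BRANCH_LENGTH = 0.1


class TreeParseError(ValueError):
    """Malformed Newick input."""


@dataclass
class PhyloTree:
    """Rooted (or arbitrarily rooted) tree in parent-array form.

    Node ids are 0..n_nodes-1 with the root last in ``postorder``.  Leaves
    carry labels; every non-root node has a branch (length + foreground
    flag) to its parent.
    """

    parent: np.ndarray               # parent id per node, -1 at root
    children: list[list[int]]
    lengths: np.ndarray              # branch length above each node (0 at root)
    foreground: np.ndarray           # bool per node: branch above is foreground
    labels: list[str | None]         # leaf label or None for internal nodes
    root: int
    postorder: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if np.any(self.lengths < 0):
            raise TreeParseError("negative branch length")
        labs = [l for l in self.labels if l is not None]
        if len(set(labs)) != len(labs):
            raise TreeParseError("duplicate leaf labels")
        if not self.postorder:
            self.postorder = self._compute_postorder()

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def has_foreground(self) -> bool:
        return bool(self.foreground.any())

    def leaf_set(self, node: int) -> frozenset[str]:
        """Labels of all leaves below (and including) ``node``."""
        out: set[str] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.add(self.labels[v])
        return frozenset(out)

    def mrca(self, labels: set[str]) -> int:
        """Most recent common ancestor of the given leaf labels."""
        want = frozenset(labels)
        missing = want - set(self.leaf_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        best = self.root
        for node in self.postorder:
            if want <= self.leaf_set(node):
                best = node
                break
        return best

    def tag_clades(self, clades: list[set[str]]) -> "PhyloTree":
        """Mark the stem branch above each clade's MRCA as foreground."""
        fg = self.foreground.copy()
        for clade in clades:
            node = self.mrca(set(clade))
            if node == self.root:
                warnings.warn("clade spans the whole tree; root has no stem branch")
                continue
            fg[node] = True
        return PhyloTree(
            self.parent.copy(), [list(c) for c in self.children],
            self.lengths.copy(), fg, list(self.labels), self.root,
        )

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(), [list(c) for c in self.children],
            np.asarray(lengths, float), self.foreground.copy(),
            list(self.labels), self.root,
        )

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


def _strip_tag(label: str | None) -> tuple[str | None, bool]:
    if label is None:
        return None, False
    m = _TAG_RE.search(label)
    if m:
        stripped = label[: m.start()] or None
        return stripped, True
    return label, False


def read_newick(text: str, tag_dialect: str = "paml") -> PhyloTree:
    """Parse a Newick string, recovering ``#1``-style foreground tags.

    ``tag_dialect="paml"`` interprets a trailing ``#<digit>`` on a leaf or
    internal-node label as marking the branch above that node foreground;
    ``"none"`` leaves labels untouched.  Branch lengths absent from the
    input default to 0.1 with a warning.
    """
    if tag_dialect not in ("paml", "none"):
        raise ValueError(f"unknown tag dialect {tag_dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"could not parse Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    lengths = np.zeros(n)
    foreground = np.zeros(n, dtype=bool)
    labels: list[str | None] = [None] * n
    missing_length = False

    for nd in dnodes:
        i = ids[id(nd)]
        if nd.parent_node is not None:
            p = ids[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                missing_length = True
                lengths[i] = DEFAULT_BRANCH_LENGTH
            else:
                lengths[i] = float(nd.edge.length)
        raw = nd.taxon.label if nd.taxon is not None else nd.label
        if tag_dialect == "paml":
            raw, tagged = _strip_tag(raw)
            foreground[i] = tagged and nd.parent_node is not None
        if nd.is_leaf():
            if raw is None:
                raise TreeParseError("leaf without a label")
            labels[i] = raw
    if missing_length:
        warnings.warn(
            f"branch length(s) missing from Newick; defaulted to {DEFAULT_BRANCH_LENGTH}"
        )
    root = ids[id(dtree.seed_node)]
    return PhyloTree(parent, children, lengths, foreground, labels, root)


def read_clade_file(text: str) -> list[set[str]]:
    """Parse a plain-text foreground spec: one whitespace-separated leaf
    set per line (blank lines and ``#`` comments ignored).  Each set's
    stem branch is tagged via :meth:`PhyloTree.tag_clades`."""
    clades = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            clades.append(set(line.split()))
    return clades


def write_newick(tree: PhyloTree, tags: bool = True) -> str:
    """Serialize to Newick, emitting ``#1`` tags for foreground branches."""

    def render(node: int) -> str:
        tag = "#1" if (tags and tree.foreground[node]) else ""
        if not tree.children[node]:
            core = tree.labels[node] + tag
        else:
            inner = ",".join(render(c) for c in tree.children[node])
            core = f"({inner}){tag}"
        if node == tree.root:
            return core
        return f"{core}:{tree.lengths[node]:.10g}"

    return render(tree.root) + ";"
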