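"""Rooted phylogenies with a single taggable foreground branch.

Newick I/O follows the convention of codon-model software: the foreground
branch is marked by the token ``#1`` after the label of the node *below*
that branch (its child node).  Parsing is delegated to dendropy after the
nonstandard tag has been folded into node labels.

Internally a tree is stored as flat arrays (parent pointers, branch
lengths, a postorder) so that pruning-algorithm likelihoods stay cheap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

from psgscan.errors import InvalidArgumentError, InvalidTreeError, UnknownBranchError

_FG_SENTINEL = "__FGTAG__"
_FG_RE = re.compile(r"\s*#\s*1")


@dataclass
class Phylogeny:
    """Rooted binary tree with branch lengths in expected substitutions per codon.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root);
    ``lengths[i]`` is the length of the branch above node ``i`` (0 at the
    root); ``labels[i]`` is the leaf name for leaves and '' for internal
    nodes.  ``postorder`` visits children before parents, root last.
    ``foreground`` is the index of the child node of the foreground branch,
    or None.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list[str]
    postorder: np.ndarray
    foreground: int | None = None
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.parent)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    self.children[p].append(i)
        if np.any(self.lengths < 0):
            raise InvalidTreeError("negative branch length")

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def clade_leaves(self, node: int) -> list[str]:
        """Sorted leaf names below ``node`` (inclusive)."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(self.labels[v])
        return sorted(out)

    def branch_id(self, node: int) -> str:
        """Stable identifier of the branch above ``node``: its clade's leaf names."""
        return "+".join(self.clade_leaves(node))

    def find_branch(self, branch: int | str) -> int:
        """Resolve a branch given as node index, leaf name, or clade id 'A+B'."""
        if isinstance(branch, (int, np.integer)):
            if not 0 <= branch < self.n_nodes or branch == self.root:
                raise UnknownBranchError(f"no branch above node {branch}")
            return int(branch)
        for i in range(self.n_nodes):
            if i != self.root and self.branch_id(i) == branch:
                return i
        raise UnknownBranchError(branch)

    def with_foreground(self, branch: int | str) -> "Phylogeny":
        return Phylogeny(
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            labels=list(self.labels),
            postorder=self.postorder.copy(),
            foreground=self.find_branch(branch),
        )

    def scaled(self, factor: float) -> "Phylogeny":
        if factor <= 0:
            raise InvalidArgumentError("scale factor must be positive")
        return Phylogeny(
            parent=self.parent.copy(),
            lengths=self.lengths * factor,
            labels=list(self.labels),
            postorder=self.postorder.copy(),
            foreground=self.foreground,
        )

    # -- newick I/O ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, require_lengths: bool = True) -> "Phylogeny":
        """Parse newick; a single '#1' token marks the foreground branch."""
        tagged = _FG_RE.sub(_FG_SENTINEL, newick)
        # the tag may follow the branch length ("A:0.1 #1"); move it back
        # onto the node label so it survives newick parsing
        tagged = re.sub(
            r":\s*([0-9.eE+\-]+)" + _FG_SENTINEL, _FG_SENTINEL + r":\1", tagged
        )
        n_tags = tagged.count(_FG_SENTINEL)
        if n_tags > 1:
            raise InvalidTreeError("more than one '#1' foreground tag")
        try:
            dt = dendropy.Tree.get(
                data=tagged, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise InvalidTreeError(f"newick parse failure: {exc}") from exc

        nodes = list(dt.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        labels = [""] * n
        fg = None
        for nd in nodes:
            i = index[id(nd)]
            label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            if label.endswith(_FG_SENTINEL):
                label = label[: -len(_FG_SENTINEL)]
                fg = i
            labels[i] = label
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    if require_lengths:
                        raise InvalidTreeError("branch without a length")
                else:
                    lengths[i] = float(nd.edge.length)
        tree = cls(
            parent=parent, lengths=lengths, labels=labels,
            postorder=np.arange(n), foreground=fg,
        )
        leaf_names = tree.leaf_names
        if len(set(leaf_names)) != len(leaf_names):
            raise InvalidTreeError("duplicate leaf names")
        for i in range(n):
            if tree.children[i] and len(tree.children[i]) != 2:
                raise InvalidTreeError("tree is not binary")
        if fg is not None and fg == tree.root:
            raise InvalidTreeError("root has no branch; cannot be foreground")
        return tree

    def to_newick(self) -> str:
        """Deterministic newick with branch lengths and the '#1' foreground tag."""

        def fmt(i: int) -> str:
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                body = f"({inner})"
            else:
                body = self.labels[i]
            if i == self.foreground:
                body += " #1"
            if self.parent[i] >= 0:
                body += f":{self.lengths[i]:.6g}"
            return body

        return fmt(self.root) + ";"
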