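"""Rooted ultrametric species timetrees and their unrooted counterparts.

The central object is :class:`SpeciesTimeTree`, a rooted binary tree whose
internal nodes carry ages in units of 100 Myr and whose tips sit at age 0.
It is the ground truth for rate simulation and the fixed topology for all
downstream dating.  A small index-based representation is used internally
(parent arrays, branch tables) because both the simulator and the MCMC
need fast traversal; Newick I/O goes through DendroPy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np

__all__ = [
    "SpeciesTimeTree",
    "build_reference_timetree",
    "REFERENCE_NEWICK",
    "REFERENCE_AGES",
]

# Fixed 9-taxon study tree: a 7-taxon caterpillar (nodes 2..7) plus a
# 2-taxon clade (node 8) hanging directly off the root (node 1).
REFERENCE_NEWICK = "(((((((sp1,sp2)7,sp3)6,sp4)5,sp5)4,sp6)3,sp7)2,(sp8,sp9)8)1;"

# Node ages, 100-Myr units (node label -> age).
REFERENCE_AGES = {
    1: 1.0,
    2: 0.95,
    3: 0.55,
    4: 0.40,
    5: 0.25,
    6: 0.15,
    7: 0.10,
    8: 0.50,
}


@dataclass
class SpeciesTimeTree:
    """Rooted binary ultrametric tree with node ages.

    Nodes are indexed 0..2s-2: tips first (0..s-1, in the order of
    ``tip_names``), then internal nodes in the order of ``internal_labels``
    (the root is always the first internal node).  Every non-root node has a
    parent branch; branches are numbered 0..2s-3 in the fixed order of
    ``branch_child`` (preorder over non-root nodes), so a rooted s-tip tree
    has 2s-2 branches.
    """

    tip_names: list[str]
    internal_labels: list[int]
    parent: np.ndarray          # (n_nodes,), -1 for the root
    children: list[list[int]]   # (n_nodes,), empty for tips
    ages: np.ndarray            # (n_nodes,), tips at 0.0
    branch_child: np.ndarray = field(init=False)  # branch b -> child node

    def __post_init__(self) -> None:
        self._validate()
        root = self.root_index
        order: list[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            if v != root:
                order.append(v)
            stack.extend(reversed(self.children[v]))
        self.branch_child = np.asarray(order, dtype=np.intp)

    # -- basic structure -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.ages)

    @property
    def n_branches(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def root_index(self) -> int:
        return self.n_tips  # first internal node

    def node_index(self, label: int) -> int:
        """Index of the internal node with the given label."""
        return self.n_tips + self.internal_labels.index(label)

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root_index])

    def branch_durations(self) -> np.ndarray:
        """Time spanned by each branch (parent age - child age)."""
        child = self.branch_child
        return self.ages[self.parent[child]] - self.ages[child]

    def _validate(self) -> None:
        s = self.n_tips
        if s < 2:
            raise ValueError("need at least two tips")
        if np.any(self.ages[:s] != 0.0):
            raise ValueError("tips must sit at age 0")
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not self.ages[p] > self.ages[v]:
                raise ValueError(
                    f"parent age must exceed child age (node {v}: "
                    f"{self.ages[p]} <= {self.ages[v]})"
                )

    # -- conversions -----------------------------------------------------

    def with_ages(self, ages_by_label: dict[int, float]) -> "SpeciesTimeTree":
        """Copy of the tree with internal node ages replaced."""
        ages = self.ages.copy()
        for lab, a in ages_by_label.items():
            ages[self.node_index(lab)] = a
        return SpeciesTimeTree(
            tip_names=list(self.tip_names),
            internal_labels=list(self.internal_labels),
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            ages=ages,
        )

    def to_newick(self, branch_lengths: np.ndarray | None = None) -> str:
        """Newick string; with branch lengths if given (one per branch),
        otherwise with time durations as branch lengths.  Internal node
        labels are retained and node ages are written as ``[&age=...]``
        comments."""
        if branch_lengths is None:
            blen = self.branch_durations()
        else:
            blen = np.asarray(branch_lengths, dtype=float)
            if blen.shape != (self.n_branches,):
                raise ValueError("one branch length per branch required")
        len_of = {int(c): float(l) for c, l in zip(self.branch_child, blen)}

        def fmt(v: int) -> str:
            if not self.children[v]:
                name = self.tip_names[v]
            else:
                inner = ",".join(fmt(c) for c in self.children[v])
                lab = self.internal_labels[v - self.n_tips]
                name = f"({inner}){lab}"
                name += f"[&age={self.ages[v]:.6g}]"
            if v in len_of:
                name += f":{len_of[v]:.10g}"
            return name

        return fmt(self.root_index) + ";"

    @classmethod
    def from_newick(
        cls, newick: str, ages_by_label: dict[int, float] | None = None
    ) -> "SpeciesTimeTree":
        """Build from a Newick string with labelled internal nodes.

        Ages are taken from ``[&age=...]`` node comments if present,
        otherwise from ``ages_by_label`` keyed by internal node label.
        """
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
        tips = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
        tip_idx = {name: i for i, name in enumerate(tips)}
        s = len(tips)

        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        labels: list[int] = []
        for nd in internals:
            if nd.label is None:
                raise ValueError("internal nodes must carry integer labels")
            labels.append(int(nd.label))
        int_idx = {id(nd): s + k for k, nd in enumerate(internals)}

        n = s + len(internals)
        parent = np.full(n, -1, dtype=np.intp)
        children: list[list[int]] = [[] for _ in range(n)]
        ages = np.zeros(n)

        def idx(nd: dendropy.Node) -> int:
            if nd.is_leaf():
                return tip_idx[nd.taxon.label.replace(" ", "_")]
            return int_idx[id(nd)]

        for nd in internals:
            i = idx(nd)
            age = None
            for comment in nd.comments:
                if comment.startswith("&age="):
                    age = float(comment[5:])
            if age is None and ages_by_label is not None:
                age = ages_by_label.get(int(nd.label))
            if age is None:
                raise ValueError(f"no age for internal node {nd.label}")
            ages[i] = age
            for ch in nd.child_nodes():
                j = idx(ch)
                parent[j] = i
                children[i].append(j)

        return cls(
            tip_names=tips,
            internal_labels=labels,
            parent=parent,
            children=children,
            ages=ages,
        )


def build_reference_timetree() -> SpeciesTimeTree:
    """The fixed 9-taxon study timetree.

    Root (node 1) at age 1.0 (= 100 Myr); nodes 2..7 form a nested
    caterpillar at ages 0.95, 0.55, 0.40, 0.25, 0.15, 0.10 and node 8
    subtends a two-taxon clade at age 0.50 on the other side of the root.
    """
    return SpeciesTimeTree.from_newick(REFERENCE_NEWICK, REFERENCE_AGES)


def write_gene_trees_newick(path, trees_newick: list[str]) -> None:
    """Write one Newick gene tree per line."""
    with open(path, "w") as fh:
        for nwk in trees_newick:
            fh.write(nwk + "\n")


def _unrooted_branch_map(tree: SpeciesTimeTree) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Map rooted branches to unrooted branches.

    Unrooting a rooted binary tree merges the two root-adjacent branches
    into a single branch; all other branches map one-to-one.  Returns
    ``(rooted_to_unrooted, unrooted_edges)`` where ``rooted_to_unrooted[b]``
    is the unrooted branch index of rooted branch ``b`` and
    ``unrooted_edges`` lists (node_u, node_v) pairs for the 2s-3 unrooted
    branches (the merged branch connects the two root children).
    """
    root = tree.root_index
    child = tree.branch_child
    root_kids = tree.children[root]
    if len(root_kids) != 2:
        raise ValueError("root must be binary")
    mapping = np.empty(tree.n_branches, dtype=np.intp)
    edges: list[tuple[int, int]] = [(root_kids[0], root_kids[1])]
    for b, c in enumerate(child):
        if c in root_kids:
            mapping[b] = 0
        else:
            mapping[b] = len(edges)
            edges.append((int(tree.parent[c]), int(c)))
    return mapping, edges


def rooted_to_unrooted_lengths(tree: SpeciesTimeTree, rooted_lengths: np.ndarray) -> np.ndarray:
    """Collapse the 2s-2 rooted branch lengths to 2s-3 unrooted lengths.

    The two branches incident to the root are summed into one; this is the
    mapping under which the unrooted likelihood of a reversible model is
    invariant to root placement.
    """
    rooted_lengths = np.asarray(rooted_lengths, dtype=float)
    mapping, edges = _unrooted_branch_map(tree)
    out = np.zeros(len(edges))
    np.add.at(out, mapping, rooted_lengths)
    return out
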