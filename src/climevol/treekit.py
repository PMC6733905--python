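"""Rooted phylogenetic trees: Newick I/O, path metrics, bipartitions, locus jackknife.

The container is deliberately small: nodes carry a parent link, an ordered
list of children, a non-negative branch length and an optional label.  Branch
lengths are in Ma for dated (ultrametric) trees and in expected
substitutions/site for gene trees.  Newick parsing is delegated to dendropy;
everything downstream operates on this container.

Root-to-tip path sums on substitution-scaled gene trees are the package's
proxy for lineage-specific molecular substitution rate, and bipartition
recovery across locus-jackknife replicates (the GJP statistic) is the support
measure used for phylogenomic topologies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Tree",
    "TreeNode",
    "LocusSet",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "root_to_tip_paths",
    "reroot_on_outgroup",
    "drop_tip",
    "bipartitions",
    "patristic_distances",
    "resample_loci",
    "gjp_support",
    "GJP_CONFIDENCE",
]

#: GJP percentage above which a bipartition is called confidently supported.
GJP_CONFIDENCE = 75.0


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class TreeNode:
    __slots__ = ("parent", "children", "length", "label")

    def __init__(self, label=None, length=0.0, parent=None):
        self.parent = parent
        self.children: list[TreeNode] = []
        self.length = float(length)
        self.label = label

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} len={self.length:g}>"


class Tree:
    """A rooted tree with unique, non-empty tip labels and branch lengths >= 0."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversals (iterative: must survive 1000-deep chains) --------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def find_tip(self, label: str) -> TreeNode:
        for t in self.tips():
            if t.label == label:
                return t
        raise KeyError(
            f"tip {label!r} not in tree; available tips: {sorted(self.tip_labels)}"
        )

    # -- metrics -------------------------------------------------------------

    def depths(self) -> dict[TreeNode, float]:
        """Distance from the root to every node (root branch length excluded)."""
        d = {self.root: 0.0}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                d[c] = d[node] + c.length
                stack.append(c)
        return d

    @property
    def depth(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tips())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depths()
        paths = [d[t] for t in self.tips()]
        lo, hi = min(paths), max(paths)
        return hi == 0.0 or (hi - lo) <= rtol * hi

    def validate(self) -> None:
        labels = self.tip_labels
        if any(lab in (None, "") for lab in labels):
            raise ValueError("tip labels must be non-empty")
        dup = {lab for lab in labels if labels.count(lab) > 1}
        if dup:
            raise ValueError(f"duplicate tip labels: {sorted(dup)}")
        for n in self.preorder():
            if n.length < 0:
                raise ValueError(f"negative branch length at {n.label!r}")

    def copy(self) -> "Tree":
        mapping = {self.root: TreeNode(self.root.label, self.root.length)}
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                mapping[c] = mapping[node].add_child(TreeNode(c.label, c.length))
                stack.append(c)
        return Tree(mapping[self.root])

    def __repr__(self):  # pragma: no cover
        return f"<Tree {len(self.tip_labels)} tips>"


# -- Newick I/O --------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Missing branch lengths become 0 with a logged warning.  Malformed input,
    duplicate or empty tip labels raise :class:`NewickParseError`.
    """
    import dendropy

    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    # dendropy's reader recurses once per nesting level; deep chains (pectinate
    # or ladder trees) need a higher recursion ceiling than Python's default
    import sys

    old_limit = sys.getrecursionlimit()
    needed = 10 * text.count("(") + 1000
    if needed > old_limit:
        sys.setrecursionlimit(needed)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    finally:
        sys.setrecursionlimit(old_limit)

    missing = 0

    def _convert(dnode):
        nonlocal missing
        if dnode.edge.length is None:
            missing += 1
            length = 0.0
        else:
            length = dnode.edge.length
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return TreeNode(label=label, length=length)

    root = _convert(dtree.seed_node)
    stack = [(dtree.seed_node, root)]
    while stack:
        dnode, node = stack.pop()
        for dchild in dnode.child_nodes():
            child = node.add_child(_convert(dchild))
            stack.append((dchild, child))
    if missing:
        logger.warning("%d branch lengths missing in Newick input; set to 0", missing)
    tree = Tree(root)
    try:
        tree.validate()
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc
    return tree


_NEEDS_QUOTES = re.compile(r"[\s()\[\]{}:;,'\"]")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTES.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialise a tree to Newick; re-parsing yields an isomorphic tree with
    identical branch lengths (floats are written with full round-trip precision)."""
    parts: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _format_label(node.label if node.label is not None else "")
        else:
            inner = ",".join(parts.pop(id(c)) for c in node.children)
            s = f"({inner})"
            if node.label:
                s += _format_label(node.label)
        s += f":{node.length!r}"
        parts[id(node)] = s
    return parts[id(tree.root)] + ";"


# -- path metrics ------------------------------------------------------------

def root_to_tip_paths(tree: Tree) -> dict[str, float]:
    """Sum of branch lengths from the root to each tip.

    On substitution-scaled gene trees these sums estimate lineage-specific
    molecular substitution rates (all tips share the same elapsed time).
    """
    d = tree.depths()
    return {t.label: d[t] for t in tree.tips()}


def patristic_distances(tree: Tree) -> pd.DataFrame:
    """All pairwise tip-to-tip path lengths, as a symmetric DataFrame."""
    tips = tree.tips()
    # ancestor -> cumulative distance, per tip
    anc: dict[str, dict[int, float]] = {}
    for t in tips:
        # distance from the tip up to each of its ancestors
        node, dist = t, 0.0
        path = {}
        while node is not None:
            path[id(node)] = dist
            if node.parent is not None:
                dist += node.length
            node = node.parent
        anc[t.label] = path
    labels = [t.label for t in tips]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    order = {id(n): i for i, n in enumerate(tree.preorder())}
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            # deepest common ancestor = shared key with maximal preorder index
            shared = anc[a.label].keys() & anc[b.label].keys()
            mrca = max(shared, key=lambda k: order[k])
            dist = anc[a.label][mrca] + anc[b.label][mrca]
            mat.loc[a.label, b.label] = mat.loc[b.label, a.label] = dist
    return mat


# -- rerooting ---------------------------------------------------------------

def reroot_on_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Reroot so the outgroup tip is one child of the root and the ingroup the other.

    The outgroup's terminal branch is split evenly on either side of the new
    root; all ingroup pairwise path lengths are preserved.
    """
    tree = tree.copy()
    try:
        og = tree.find_tip(outgroup)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    if og.parent is tree.root and len(tree.root.children) == 2:
        return tree

    # Walk from the outgroup's parent to the old root, reversing parent links.
    half = og.length / 2.0
    new_root = TreeNode()
    old_parent = og.parent
    old_parent.children.remove(og)
    og.length = half
    new_root.add_child(og)

    # Reverse the chain: former parent chain becomes a descent on the ingroup side.
    carry = half
    chain = []
    node = old_parent
    while node is not None:
        chain.append(node)
        node = node.parent
    attach = new_root
    for i, node in enumerate(chain):
        upper = chain[i + 1] if i + 1 < len(chain) else None
        if upper is not None:
            upper.children.remove(node)
        saved_length = node.length
        node.parent = attach
        node.length = carry
        attach.children.append(node)
        attach = node
        carry = saved_length
    out = Tree(new_root)
    _suppress_unifurcations(out)
    return out


def _suppress_unifurcations(tree: Tree) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if not node.is_leaf and len(node.children) == 1:
                child = node.children[0]
                if node is tree.root:
                    child.length += 0.0  # root edge length is not meaningful
                    child.parent = None
                    tree.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.length += node.length
                    child.parent = parent
                    parent.children[idx] = child
                changed = True
                break


def drop_tip(tree: Tree, label: str) -> Tree:
    """Return a copy with one tip removed and any resulting unifurcation collapsed."""
    tree = tree.copy()
    tip = tree.find_tip(label)
    parent = tip.parent
    if parent is None:
        raise ValueError("cannot drop the only node of a tree")
    parent.children.remove(tip)
    _suppress_unifurcations(tree)
    return tree


# -- bipartitions and jackknife support --------------------------------------

def bipartitions(tree: Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions induced by internal edges (rooting-invariant).

    Each bipartition is the unordered pair of complementary tip-label sets;
    trees with fewer than 4 tips yield the empty set.
    """
    all_tips = frozenset(tree.tip_labels)
    if len(all_tips) < 4:
        return set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    out = set()
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = below[id(node)]
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset([side, other]))
    return out


def bipartition_label(bip: frozenset[frozenset[str]]) -> str:
    sides = sorted((sorted(s) for s in bip), key=lambda s: (len(s), s))
    return ",".join(sides[0]) + " | " + ",".join(sides[1])


def gjp_support(
    reference: Tree,
    replicates: list[tuple[Tree, int]],
    confidence: float = GJP_CONFIDENCE,
) -> pd.DataFrame:
    """Gene-jackknife proportions: for each non-trivial reference bipartition and
    each replicate length bin, the percentage of replicates recovering it.

    Bins are keyed by the nominal resampling target length.  A boolean
    ``supported`` column flags proportions strictly above ``confidence``
    (default 75, the conventional confidence rule for this statistic).
    """
    ref_tips = set(reference.tip_labels)
    for rep, _ in replicates:
        rep_tips = set(rep.tip_labels)
        if rep_tips != ref_tips:
            diff = sorted(rep_tips.symmetric_difference(ref_tips))
            raise ValueError(f"replicate tip set differs from reference: {diff}")
    ref_bips = bipartitions(reference)
    by_length: dict[int, list[set]] = {}
    for rep, length in replicates:
        by_length.setdefault(length, []).append(bipartitions(rep))
    rows = []
    for bip in sorted(ref_bips, key=bipartition_label):
        for length in sorted(by_length):
            reps = by_length[length]
            pct = 100.0 * sum(bip in r for r in reps) / len(reps)
            rows.append(
                {
                    "bipartition": bipartition_label(bip),
                    "replicate_length": length,
                    "n_replicates": len(reps),
                    "gjp": pct,
                    "supported": pct > confidence,
                }
            )
    return pd.DataFrame(rows, columns=["bipartition", "replicate_length", "n_replicates", "gjp", "supported"])


# -- locus resampling ---------------------------------------------------------

@dataclass
class LocusSet:
    """Loci with aligned lengths in nucleotide positions."""

    ids: list[str]
    lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("locus identifiers must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("locus lengths must be positive")
        if len(self.ids) != len(self.lengths):
            raise ValueError("ids and lengths differ in length")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @classmethod
    def from_tsv(cls, path) -> "LocusSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(ids=df["locus_id"].astype(str).tolist(), lengths=df["length_nt"].astype(int).tolist())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"locus_id": self.ids, "length_nt": self.lengths}).to_csv(path, sep="\t", index=False)


def resample_loci(loci: LocusSet, target_length: int, seed: int) -> list[str]:
    """Sample loci uniformly without replacement until the cumulative aligned
    length first reaches or exceeds ``target_length`` ("to ca. N positions").

    Deterministic for a fixed seed.  Raises if the target exceeds the total
    available length.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    if target_length > loci.total_length:
        raise ValueError(
            f"target length {target_length} exceeds total available {loci.total_length}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(loci.ids))
    chosen, cum = [], 0
    for idx in order:
        chosen.append(loci.ids[idx])
        cum += loci.lengths[idx]
        if cum >= target_length:
            break
    return chosen
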