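"""Rooted phylogenies, unit partitions and background/foreground branch labeling.

A *unit partition* assigns every tip to a higher taxon (e.g., an insect
order).  Branch-site models need every branch of the rooted tree flagged as
*background* (within a unit) or *foreground* (among units); the flag is a pure
function of the tree and the partition.  The module also enumerates the
alternative taxon structures obtained by lumping the most derived units
together or splitting units at their basal node, which lets model selection
ask whether the chosen taxonomic level is the best one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

BACKGROUND = "background"
FOREGROUND = "foreground"


class PhyloTree:
    """A rooted (binary, after deterministic resolution) tree over named tips.

    Nodes are stored in postorder; the root is the last node.  Every non-root
    node owns the branch above it, so a binary rooted tree with n tips has
    2n - 2 branches.  Polytomies read from Newick are resolved with
    zero-length branches using a sorted child order, so parsing is
    deterministic.
    """

    def __init__(self, parent: list[int], children: list[list[int]],
                 lengths: list[float], tip_names_by_node: dict[int, str]):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_name = dict(tip_names_by_node)
        self.n_nodes = len(parent)
        self.root = self.n_nodes - 1
        self._tipsets: list[frozenset[str]] | None = None
        if np.any(self.lengths[:-1] < 0):
            bad = int(np.where(self.lengths[:-1] < 0)[0][0])
            raise ValueError(f"negative branch length on branch above node {bad}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return parse_newick(fh.read())

    # -- basic structure ---------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return sorted(self.tip_name.values())

    @property
    def n_tips(self) -> int:
        return len(self.tip_name)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def branches(self) -> list[int]:
        """Branch owners: every node except the root, in postorder."""
        return [v for v in range(self.n_nodes) if v != self.root]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def tipsets(self) -> list[frozenset[str]]:
        """Tip-label set of the subtree below each node."""
        if self._tipsets is None:
            out: list[frozenset[str]] = [frozenset()] * self.n_nodes
            for v in range(self.n_nodes):  # postorder: children precede parents
                if self.is_tip(v):
                    out[v] = frozenset([self.tip_name[v]])
                else:
                    s: frozenset[str] = frozenset()
                    for c in self.children[v]:
                        s |= out[c]
                    out[v] = s
            self._tipsets = out
        return self._tipsets

    def mrca(self, tips: set[str]) -> int:
        ts = self.tipsets()
        best = self.root
        for v in range(self.n_nodes):
            if tips <= ts[v] and len(ts[v]) < len(ts[best]):
                best = v
        return best

    def node_depths(self) -> np.ndarray:
        """Path length (sum of branch lengths) from the root to each node."""
        self._require_lengths()
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):  # reverse postorder, skip root
            depth[v] = depth[self.parent[v]] + self.lengths[v]
        return depth

    def _require_lengths(self):
        lens = self.lengths[:-1]
        if np.any(np.isnan(lens)):
            raise ValueError("tree has missing branch lengths")

    # -- rescaling / copies ------------------------------------------------

    def with_lengths(self, lengths) -> "PhyloTree":
        t = PhyloTree(self.parent.tolist(), self.children,
                      list(lengths), self.tip_name)
        return t

    def scaled(self, factor: float) -> "PhyloTree":
        return self.with_lengths(self.lengths * factor)

    # -- output ------------------------------------------------------------

    def to_newick(self, labeling: "BranchLabeling | None" = None,
                  length_format: str = "%.10g") -> str:
        """Newick string; with a labeling, foreground branches get a ``#1`` tag
        (the convention used by codon-model software for branch labels)."""

        def render(v: int) -> str:
            if self.is_tip(v):
                s = self.tip_name[v]
            else:
                s = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            if labeling is not None and v != self.root and labeling.is_foreground(v):
                s += " #1"
            if v != self.root and not np.isnan(self.lengths[v]):
                s += ":" + (length_format % self.lengths[v])
            return s

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_tips} tips, {self.n_branches} branches>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a rooted binary :class:`PhyloTree`.

    Polytomies (including unrooted trifurcating roots) are resolved into
    zero-length binary branches with children sorted by their smallest tip
    label, so the result is deterministic.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon" in str(exc):
            raise ValueError(f"duplicate tip labels: {exc}") from exc
        raise ValueError(f"malformed Newick string: {exc}") from exc
    labels = [lf.taxon.label if lf.taxon else None for lf in dtree.leaf_node_iter()]
    if any(lb is None for lb in labels):
        raise ValueError("malformed Newick string: unnamed tip")
    dup = sorted({lb for lb in labels if labels.count(lb) > 1})
    if dup:
        raise ValueError(f"duplicate tip labels: {dup}")

    parent: list[int] = []
    children: list[list[int]] = []
    lengths: list[float] = []
    tip_names: dict[int, str] = {}

    def min_tip(dnode) -> str:
        return min(lf.taxon.label for lf in dnode.leaf_iter())

    def build(dnode) -> int:
        kids = sorted(dnode.child_nodes(), key=min_tip)
        if not kids:
            idx = _new_node(parent, children, lengths)
            tip_names[idx] = dnode.taxon.label
            lengths[idx] = _edge_len(dnode)
            return idx
        if len(kids) == 1:  # knuckle: collapse, summing lengths
            idx = build(kids[0])
            el = _edge_len(dnode)
            if not np.isnan(lengths[idx]) or not np.isnan(el):
                lengths[idx] = np.nansum([lengths[idx], el])
            return idx
        sub = [build(k) for k in kids]
        # fold polytomies left-to-right into zero-length binary nodes
        while len(sub) > 2:
            a = sub.pop(0)
            b = sub.pop(0)
            m = _new_node(parent, children, lengths)
            children[m] = [a, b]
            parent[a] = parent[b] = m
            lengths[m] = 0.0
            sub.insert(0, m)
        idx = _new_node(parent, children, lengths)
        children[idx] = sub
        for s in sub:
            parent[s] = idx
        lengths[idx] = _edge_len(dnode)
        return idx

    root = build(dtree.seed_node)
    # renumber into postorder with root last
    order: list[int] = []

    def post(v: int):
        for c in children[v]:
            post(c)
        order.append(v)

    post(root)
    remap = {old: new for new, old in enumerate(order)}
    n = len(order)
    p2 = [-1] * n
    c2: list[list[int]] = [[] for _ in range(n)]
    l2 = [np.nan] * n
    t2: dict[int, str] = {}
    for old, new in remap.items():
        p2[new] = remap[parent[old]] if parent[old] != -1 else -1
        c2[new] = [remap[c] for c in children[old]]
        l2[new] = lengths[old]
        if old in tip_names:
            t2[new] = tip_names[old]
    l2[remap[root]] = np.nan  # the root owns no branch
    return PhyloTree(p2, c2, l2, t2)


def _new_node(parent, children, lengths) -> int:
    parent.append(-1)
    children.append([])
    lengths.append(np.nan)
    return len(parent) - 1


def _edge_len(dnode) -> float:
    return float(dnode.edge.length) if dnode.edge.length is not None else np.nan


def write_newick(tree: PhyloTree, labeling: "BranchLabeling | None" = None) -> str:
    return tree.to_newick(labeling=labeling)


# ---------------------------------------------------------------------------
# Unit partitions and branch labeling
# ---------------------------------------------------------------------------

@dataclass
class UnitPartition:
    """Assignment of every tip label to a named unit (higher taxon)."""

    assignment: dict[str, str]
    units: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen: list[str] = []
        for u in self.assignment.values():
            if u not in seen:
                seen.append(u)
        if not self.units:
            self.units = seen
        else:
            missing = [u for u in seen if u not in self.units]
            if missing:
                raise ValueError(f"units used but not listed: {missing}")

    def unit_of(self, tip: str) -> str:
        return self.assignment[tip]

    def tips_of(self, unit: str) -> frozenset[str]:
        return frozenset(t for t, u in self.assignment.items() if u == unit)

    @classmethod
    def from_tsv(cls, path) -> "UnitPartition":
        df = pd.read_csv(path, sep="\t", header=None, names=["tip", "unit"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["tip"], df["unit"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.assignment.items()),
                     columns=["tip", "unit"]).to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class BranchLabeling:
    """Per-branch background/foreground flags for a specific tree."""

    tree: PhyloTree
    foreground: np.ndarray  # bool per node; entry for the root unused

    def is_foreground(self, node: int) -> bool:
        return bool(self.foreground[node])

    def flag(self, node: int) -> str:
        return FOREGROUND if self.foreground[node] else BACKGROUND

    @property
    def n_foreground(self) -> int:
        return int(self.foreground[self.tree.branches()].sum())

    @property
    def n_background(self) -> int:
        return self.tree.n_branches - self.n_foreground

    @classmethod
    def all_background(cls, tree: PhyloTree) -> "BranchLabeling":
        return cls(tree, np.zeros(tree.n_nodes, dtype=bool))


def label_branches(tree: PhyloTree, partition: UnitPartition) -> BranchLabeling:
    """Flag every branch as within-unit (background) or among-unit (foreground).

    A branch is background iff the tips below it all belong to one unit and
    form a *proper* subset of that unit's tips present in the tree; the unit's
    stem branch (whole unit below it) and all deeper branches are foreground.
    The "present in the tree" qualification is the gene-tree relaxation: in a
    gene tree with paralogs or missing taxa a unit need not be monophyletic,
    and labeling then uses maximal same-unit subtrees.
    """
    missing = sorted(set(tree.tip_name.values()) - set(partition.assignment))
    if missing:
        raise ValueError(f"tips missing from unit partition: {missing}")
    tipsets = tree.tipsets()
    present: dict[str, frozenset[str]] = {
        u: partition.tips_of(u) & tipsets[tree.root] for u in partition.units
    }
    fg = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.branches():
        units_below = {partition.unit_of(t) for t in tipsets[v]}
        if len(units_below) == 1:
            (u,) = units_below
            fg[v] = tipsets[v] == present[u]  # stem of the whole unit
        else:
            fg[v] = True
    return BranchLabeling(tree, fg)


# ---------------------------------------------------------------------------
# Structure hypotheses (lump / split enumeration)
# ---------------------------------------------------------------------------

@dataclass
class StructureHypothesis:
    """A named alternative unit partition with its induced branch labeling."""

    name: str
    kind: str  # "base" | "lump" | "split"
    partition: UnitPartition
    labeling: BranchLabeling
    detail: tuple[str, ...] = ()  # units lumped or split


def _unit_crown(tree: PhyloTree, partition: UnitPartition, unit: str) -> int:
    tips = set(partition.tips_of(unit))
    node = tree.mrca(tips)
    extra = sorted(tree.tipsets()[node] - tips)
    if extra:
        raise ValueError(
            f"unit {unit!r} is not monophyletic; intruding tips: {extra}")
    return node


def enumerate_structure_hypotheses(
        tree: PhyloTree, base: UnitPartition,
        base_name: str = "orders") -> list[StructureHypothesis]:
    """All lump/split variants of a base partition, plus the base itself.

    For ``k`` base units the alternatives are: two lumpings (merge the two
    most derived units; merge the ``k-1`` most derived units), read from the
    nesting of the unit crowns in the tree, and every way of splitting a
    subset of units at their basal node (``2^k - 1`` subsets).  With four
    units this yields 2 + 4 + 6 + 4 + 1 = 17 alternatives.
    """
    units = list(base.units)
    crowns = {u: _unit_crown(tree, base, u) for u in units}
    tipsets = tree.tipsets()
    out = [StructureHypothesis(base_name, "base", base, label_branches(tree, base))]

    # lumpings: find the unique clade made of exactly 2 complete units, and of
    # exactly len(units)-1 complete units (requires a ladder-like unit tree)
    unit_tipsets = {u: tipsets[crowns[u]] for u in units}
    for size, tag in ((2, "lump2"), (len(units) - 1, "lump3")):
        if size < 2 or size >= len(units) + 1:
            continue
        found = []
        for combo in itertools.combinations(units, size):
            target = frozenset().union(*(unit_tipsets[u] for u in combo))
            if any(tipsets[v] == target for v in range(tree.n_nodes)):
                found.append(combo)
        if len(found) != 1:
            raise ValueError(
                f"cannot identify a unique {size}-unit derived clade to lump "
                f"(found {len(found)}); lumping requires a ladder unit topology")
        combo = found[0]
        merged = "+".join(combo)
        assign = {t: (merged if base.unit_of(t) in combo else base.unit_of(t))
                  for t in base.assignment}
        part = UnitPartition(assign)
        out.append(StructureHypothesis(
            f"lump-{merged}", "lump", part, label_branches(tree, part),
            detail=combo))

    # splits: replace each chosen unit by its two basal daughter clades
    daughters: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for u in units:
        kids = tree.children[crowns[u]]
        if len(kids) != 2:
            raise ValueError(f"unit {u!r} crown is not bifurcating; cannot split")
        a, b = (tipsets[k] for k in kids)
        if min(a) > min(b):
            a, b = b, a
        daughters[u] = (a, b)
    for r in range(1, len(units) + 1):
        for combo in itertools.combinations(units, r):
            assign = {}
            for t in base.assignment:
                u = base.unit_of(t)
                if u in combo:
                    assign[t] = f"{u}1" if t in daughters[u][0] else f"{u}2"
                else:
                    assign[t] = u
            part = UnitPartition(assign)
            out.append(StructureHypothesis(
                "split-" + "+".join(combo), "split", part,
                label_branches(tree, part), detail=combo))
    return out


# ---------------------------------------------------------------------------
# Subtree extraction and pruning
# ---------------------------------------------------------------------------

def extract_subtree(tree: PhyloTree, node: int) -> PhyloTree:
    """The clade below ``node`` as a standalone rooted tree."""

    def render(v: int) -> str:
        if tree.is_tip(v):
            s = tree.tip_name[v]
        else:
            s = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if v != node and not np.isnan(tree.lengths[v]):
            s += ":%.12g" % tree.lengths[v]
        return s

    if tree.is_tip(node):
        raise ValueError("cannot extract a single tip as a tree")
    return parse_newick(render(node) + ";")


def prune_tree(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Restrict the tree to ``keep`` tips, suppressing degree-2 nodes by
    summing branch lengths."""
    missing = sorted(keep - set(tree.tip_name.values()))
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("pruning must retain at least 2 tips")

    def render(v: int) -> str | None:
        if tree.is_tip(v):
            if tree.tip_name[v] not in keep:
                return None
            base = tree.tip_name[v]
        else:
            parts = [render(c) for c in tree.children[v]]
            parts = [p for p in parts if p is not None]
            if not parts:
                return None
            if len(parts) == 1:
                # knuckle: the Newick reparse collapses it, summing lengths
                base = parts[0]
                if v != tree.root and not np.isnan(tree.lengths[v]):
                    return f"({base}):%.12g" % tree.lengths[v]
                return f"({base})"
            base = "(" + ",".join(parts) + ")"
        if v != tree.root and not np.isnan(tree.lengths[v]):
            base += ":%.12g" % tree.lengths[v]
        return base

    out = render(tree.root)
    assert out is not None
    return parse_newick(out + ";")


# ---------------------------------------------------------------------------
# Branch-length summaries
# ---------------------------------------------------------------------------

def max_branch_length(tree: PhyloTree) -> float:
    tree._require_lengths()
    return float(np.max(tree.lengths[tree.branches()]))


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    """Tip-by-tip path-length distances (symmetric, zero diagonal)."""
    depth = tree.node_depths()
    tips = [v for v in range(tree.n_nodes) if tree.is_tip(v)]
    names = [tree.tip_name[v] for v in tips]
    # ancestor sets for MRCA lookup on small trees
    anc: dict[int, list[int]] = {}
    for v in tips:
        chain = []
        u = v
        while u != -1:
            chain.append(u)
            u = tree.parent[u]
        anc[v] = chain
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        seen = {u: depth[u] for u in anc[tips[i]]}
        for j in range(i + 1, n):
            for u in anc[tips[j]]:
                if u in seen:
                    D[i, j] = D[j, i] = depth[tips[i]] + depth[tips[j]] - 2 * depth[u]
                    break
    return pd.DataFrame(D, index=names, columns=names)
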