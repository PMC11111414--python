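"""Phylogenetic tree container, newick I/O, bipartition algebra and per-tree metrics.

The :class:`PhyloTree` here is deliberately small: a rooted node structure
(an "unrooted" tree is represented with a basal multifurcation) carrying
branch lengths with a unit tag, optional internal-edge support values, and
the bipartition algebra needed by the quartet and concordance machinery.
Newick parsing is delegated to dendropy; writing is done directly so that
the 10-significant-digit branch-length convention is under our control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "TreeMetrics",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "rf_distance",
    "differing_branches",
    "collapse_low_support",
    "tree_metrics",
]


class PhyloNode:
    """One vertex of a tree; leaves carry a taxon ``label``."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[PhyloNode] = []
        self.parent: PhyloNode | None = None

    def add_child(self, node: "PhyloNode") -> "PhyloNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<PhyloNode {self.label or '*'}>"


class PhyloTree:
    """Rooted or unrooted phylogeny with branch lengths and optional supports.

    Parameters
    ----------
    root:
        Root node. A tree whose root has exactly two children is treated as
        rooted; a basal multifurcation is the unrooted representation.
    unit:
        Unit tag for the branch lengths: ``"subs/site"``, ``"coalescent"``,
        ``"Ma"`` or ``None`` when unknown.
    """

    def __init__(self, root: PhyloNode, unit: str | None = None):
        self.root = root
        self.unit = unit
        self._validate()

    # -- construction / validation ------------------------------------
    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        seen = set()
        for lab in labels:
            if lab is None or lab == "":
                raise ValueError("leaf without a taxon label")
            if lab in seen:
                raise ValueError(f"duplicate taxon label: {lab!r}")
            seen.add(lab)
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on edge above {node.label or 'internal node'}")

    # -- traversal ----------------------------------------------------
    def preorder(self) -> Iterator[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[PhyloNode]:
        out: list[PhyloNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    @property
    def n_taxa(self) -> int:
        return len(self.leaves())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def copy(self) -> "PhyloTree":
        def rec(node: PhyloNode) -> PhyloNode:
            new = PhyloNode(node.label, node.length, node.support)
            for child in node.children:
                new.add_child(rec(child))
            return new

        return PhyloTree(rec(self.root), unit=self.unit)

    # -- bipartitions -------------------------------------------------
    def clades(self) -> dict[PhyloNode, frozenset[str]]:
        """Taxon set below every node."""
        out: dict[PhyloNode, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset((node.label,))
            else:
                acc: set[str] = set()
                for child in node.children:
                    acc |= out[child]
                out[node] = frozenset(acc)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions in canonical form.

        Canonical form is the side *not* containing the reference taxon
        (lexicographically smallest label), so the representation is
        independent of rooting and child order.
        """
        taxa = self.taxa
        ref = min(taxa)
        clades = self.clades()
        out: set[frozenset[str]] = set()
        for node, clade in clades.items():
            if node is self.root or node.is_leaf:
                continue
            side = taxa - clade if ref in clade else clade
            if 2 <= len(side) <= len(taxa) - 2:
                out.add(side)
        return out

    def internal_edges(self) -> list[PhyloNode]:
        """Child nodes of edges internal in the unrooted sense (one per
        bipartition: with a degree-2 root the two root edges are the same
        unrooted edge and only the first is reported)."""
        taxa = self.taxa
        ref = min(taxa)
        clades = self.clades()
        out = []
        seen: set[frozenset] = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            clade = clades[node]
            if not (2 <= len(clade) <= len(taxa) - 2):
                continue
            bip = taxa - clade if ref in clade else clade
            if bip in seen:
                continue
            seen.add(bip)
            out.append(node)
        return out

    # -- structural edits ---------------------------------------------
    def restrict(self, taxa: Iterable[str]) -> "PhyloTree":
        """Prune to the given taxa, suppressing unifurcations (lengths summed)."""
        keep = set(taxa)
        missing = keep - self.taxa
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")

        def rec(node: PhyloNode) -> PhyloNode | None:
            if node.is_leaf:
                if node.label in keep:
                    return PhyloNode(node.label, node.length, node.support)
                return None
            kids = [rec(c) for c in node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            new = PhyloNode(node.label, node.length, node.support)
            for k in kids:
                new.add_child(k)
            return new

        new_root = rec(self.root)
        if new_root is None or new_root.is_leaf:
            raise ValueError("restriction leaves fewer than 2 taxa")
        new_root.length = None
        return PhyloTree(new_root, unit=self.unit)

    def suppress_unifurcations(self) -> None:
        for node in list(self.preorder()):
            while len(node.children) == 1 and node is not self.root:
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
                node = child
        while len(self.root.children) == 1 and not self.root.children[0].is_leaf:
            self.root = self.root.children[0]
            self.root.parent = None
            self.root.length = None

    # -- distances ----------------------------------------------------
    def depths(self) -> dict[PhyloNode, float]:
        """Root-to-node path lengths (missing lengths treated as 0)."""
        out: dict[PhyloNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def diameter(self) -> float:
        """Maximum pairwise tip-to-tip path length."""
        best = 0.0
        down: dict[PhyloNode, float] = {}
        for node in self.postorder():
            if node.is_leaf:
                down[node] = 0.0
            else:
                kid_depths = sorted(
                    (down[c] + (c.length or 0.0) for c in node.children), reverse=True
                )
                down[node] = kid_depths[0]
                if len(kid_depths) >= 2:
                    best = max(best, kid_depths[0] + kid_depths[1])
        return best

    def midpoint_rooted(self) -> "PhyloTree":
        """Copy of the tree rooted at the midpoint of the longest tip path."""
        t = self.copy()
        # locate the diameter path endpoints by brute force on tips
        leaves = t.leaves()
        depths = t.depths()
        # path length between two leaves via their LCA
        anc: dict[PhyloNode, list[PhyloNode]] = {}
        for leaf in leaves:
            chain = []
            n = leaf
            while n is not None:
                chain.append(n)
                n = n.parent
            anc[leaf] = chain
        best = (-1.0, None, None)
        for i, a in enumerate(leaves):
            seta = set(map(id, anc[a]))
            for b in leaves[i + 1 :]:
                lca = next(n for n in anc[b] if id(n) in seta)
                d = depths[a] + depths[b] - 2 * depths[lca]
                if d > best[0]:
                    best = (d, a, b)
        dia, a, b = best
        if dia <= 0:
            return t
        # walk from the deeper endpoint toward the other until half the diameter
        seta = set(map(id, anc[a]))
        lca = next(n for n in anc[b] if id(n) in seta)
        path = anc[a][: anc[a].index(lca)] + list(reversed(anc[b][: anc[b].index(lca)]))
        # path: nodes whose parent edge lies on the a..b path, ordered from a
        half = dia / 2.0
        acc = 0.0
        for node in path:
            elen = node.length or 0.0
            if acc + elen >= half or node is path[-1]:
                t._reroot_on_edge(node, half - acc)
                return t
            acc += elen
        return t

    def _reroot_on_edge(self, node: PhyloNode, dist_below: float) -> None:
        """Reroot on the edge above ``node``, ``dist_below`` from ``node``'s child end."""
        elen = node.length or 0.0
        dist_below = min(max(dist_below, 0.0), elen)
        old_parent = node.parent
        new_root = PhyloNode()
        # detach
        old_parent.children.remove(node)
        node.parent = None
        node.length = dist_below
        new_root.add_child(node)
        # reverse the path from old_parent to the old root
        prev = new_root
        prev_len = elen - dist_below
        cur = old_parent
        while cur is not None:
            nxt = cur.parent
            nxt_len = cur.length
            if nxt is not None:
                nxt.children.remove(cur)
            cur.parent = None
            cur.length = prev_len
            prev.add_child(cur)
            prev, prev_len, cur = cur, nxt_len, nxt
        self.root = new_root
        self.suppress_unifurcations()

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree {self.n_taxa} taxa, unit={self.unit}>"


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dnode, support_as_label: bool) -> PhyloNode:
    label = None
    support = None
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    else:
        raw = dnode.label
        if raw not in (None, "") and support_as_label:
            try:
                support = float(raw)
            except ValueError:
                label = raw
        elif raw not in (None, ""):
            label = raw
    node = PhyloNode(label=label, length=dnode.edge.length, support=support)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child, support_as_label))
    return node


def read_newick(text: str, unit: str | None = None, support_as_label: bool = True) -> PhyloTree:
    """Parse one newick string into a :class:`PhyloTree`.

    Numeric internal-node labels are interpreted as branch supports (the
    convention used for aLRT / bootstrap annotations) unless
    ``support_as_label`` is False.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed newick: {exc}") from None
    root = _from_dendropy(dtree.seed_node, support_as_label)
    root.length = root.length  # root edge length kept if present
    return PhyloTree(root, unit=unit)


def read_newick_list(text: str, unit: str | None = None) -> list[PhyloTree]:
    """Parse a newick file body with one tree per line (blank lines skipped)."""
    trees = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(read_newick(line, unit=unit))
        except ValueError as exc:
            raise ValueError(f"line {i}: {exc}") from None
    return trees


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def _node_newick(node: PhyloNode) -> str:
    if node.is_leaf:
        s = node.label
    else:
        inner = ",".join(_node_newick(c) for c in node.children)
        tag = ""
        if node.support is not None:
            tag = _fmt_len(node.support)
        elif node.label:
            tag = node.label
        s = f"({inner}){tag}"
    if node.length is not None:
        s += f":{_fmt_len(node.length)}"
    return s


def write_newick(tree: PhyloTree) -> str:
    """Serialize to newick; branch lengths at 10 significant digits."""
    return _node_newick(tree.root) + ";"


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def _check_same_taxa(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.taxa != t2.taxa:
        only1 = sorted(t1.taxa - t2.taxa)
        only2 = sorted(t2.taxa - t1.taxa)
        raise ValueError(
            "taxon sets differ: "
            f"only in first: {only1}; only in second: {only2} "
            "(use PhyloTree.restrict to compare on shared taxa)"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree, normalized: bool = False) -> float:
    """Robinson–Foulds distance: symmetric difference of nontrivial bipartitions.

    With ``normalized=True`` the count is divided by the maximum possible for
    the pair (the sum of the two trees' nontrivial internal-edge counts),
    which for two binary trees equals ``2(n - 3)``.
    """
    _check_same_taxa(t1, t2)
    b1 = t1.bipartitions()
    b2 = t2.bipartitions()
    rf = len(b1 ^ b2)
    if not normalized:
        return float(rf)
    denom = len(b1) + len(b2)
    return rf / denom if denom else 0.0


def differing_branches(t1: PhyloTree, t2: PhyloTree) -> float:
    """RF/2 — the "number of differing branches" convention for binary pairs."""
    return rf_distance(t1, t2) / 2.0


def _support_scale(tree: PhyloTree) -> float:
    vals = [n.support for n in tree.preorder() if n.support is not None]
    if not vals:
        return 1.0
    if max(vals) > 1.0:
        if any(0.0 < v < 1.0 for v in vals):
            raise ValueError("mixed support scales: values both above 1 and in (0, 1)")
        return 100.0
    return 1.0


def contract_edge(tree: PhyloTree, node: PhyloNode) -> None:
    """Contract the unrooted edge above ``node`` (an internal non-root node).

    With a degree-2 root the two root edges are the same unrooted edge, so
    contracting a root child merges the contents of *both* root children
    into the root (leaf children stay put).
    """
    parent = node.parent
    if parent is tree.root and len(tree.root.children) == 2:
        for child in list(tree.root.children):
            if not child.is_leaf:
                idx = tree.root.children.index(child)
                tree.root.children[idx : idx + 1] = child.children
                for kid in child.children:
                    kid.parent = tree.root
        return
    idx = parent.children.index(node)
    parent.children[idx : idx + 1] = node.children
    for child in node.children:
        child.parent = parent


def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract internal edges whose support is strictly below ``threshold``.

    Edges without a support annotation are never collapsed (absent values are
    "not tested", not "poorly supported"). The shared unrooted edge at a
    degree-2 root is evaluated once: it is contracted when any support
    annotated on either root child falls below the threshold. Lengths of
    contracted edges are discarded.
    """
    scale = _support_scale(tree)
    if not (0.0 <= threshold <= scale):
        raise ValueError(
            f"threshold {threshold} outside the support scale [0, {scale:g}]"
        )
    out = tree.copy()
    for node in list(out.preorder()):
        if node.is_leaf or node is out.root or node.parent is None:
            continue
        if node.parent is out.root and len(out.root.children) == 2:
            continue  # root edge handled once below
        if node.support is not None and node.support < threshold:
            contract_edge(out, node)
    if len(out.root.children) == 2:
        supports = [c.support for c in out.root.children if c.support is not None]
        candidates = [c for c in out.root.children if not c.is_leaf]
        if supports and candidates and min(supports) < threshold:
            contract_edge(out, candidates[0])
    return out


# ---------------------------------------------------------------------------
# per-tree metrics
# ---------------------------------------------------------------------------

@dataclass
class TreeMetrics:
    """Per-gene-tree covariates used in the genomic-characteristics screens."""

    n_taxa: int
    tree_length: float
    diameter: float
    stemminess: float
    clocklikeness: float | None
    clock_root: str  # "given" | "midpoint"
    mean_support: float | None
    prop_support_above: dict[float, float] = field(default_factory=dict)


def tree_metrics(
    tree: PhyloTree,
    support_thresholds: tuple[float, ...] = (0.95, 0.99),
    rooted_for_clock: bool | None = None,
) -> TreeMetrics:
    """Compute size, length, diameter, stemminess, clocklikeness and support summaries.

    Clocklikeness is the coefficient of variation (population standard
    deviation over mean) of root-to-tip path lengths. An unrooted input is
    midpoint-rooted for this purpose and the fallback is flagged.
    """
    lengths = [n.length or 0.0 for n in tree.preorder() if n is not tree.root]
    total = sum(lengths)
    internal = sum(
        (n.length or 0.0)
        for n in tree.preorder()
        if n is not tree.root and not n.is_leaf
    )
    stemminess = internal / total if total > 0 else 0.0

    use_given = tree.is_rooted if rooted_for_clock is None else rooted_for_clock
    if use_given:
        rooted, clock_root = tree, "given"
    else:
        rooted, clock_root = tree.midpoint_rooted(), "midpoint"
    depths = rooted.depths()
    tip_depths = [depths[n] for n in rooted.leaves()]
    mean_d = sum(tip_depths) / len(tip_depths)
    if mean_d <= 0:
        clocklikeness = None
    else:
        var = sum((d - mean_d) ** 2 for d in tip_depths) / len(tip_depths)
        clocklikeness = math.sqrt(var) / mean_d

    supports = [n.support for n in tree.preorder() if n.support is not None]
    scale = _support_scale(tree)
    supports01 = [s / scale for s in supports]
    mean_support = sum(supports01) / len(supports01) if supports01 else None
    prop_above = {
        thr: (sum(1 for s in supports01 if s >= thr) / len(supports01))
        for thr in support_thresholds
    } if supports01 else {thr: float("nan") for thr in support_thresholds}

    return TreeMetrics(
        n_taxa=tree.n_taxa,
        tree_length=total,
        diameter=tree.diameter(),
        stemminess=stemminess,
        clocklikeness=clocklikeness,
        clock_root=clock_root,
        mean_support=mean_support,
        prop_support_above=prop_above,
    )
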