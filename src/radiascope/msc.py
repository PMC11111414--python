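"""Synthetic species trees and multispecies-coalescent (MSC) gene trees.

The generator produces every input the rest of the pipeline consumes, with
known ground truth: an ultrametric species tree in Ma carrying per-branch
effective population sizes (Ne, diploid) and generation times (g, years);
gene trees drawn lineage-by-lineage under the MSC, optionally rerouted
through a hybridization edge (locus-level tree mixture) or degraded with
NNI/collapse estimation error.

The coalescent length of a species-tree branch of duration T (Ma) is

    d = T * 1e6 / (2 * Ne * g)   [coalescent units]

so with the default Ne = 5e5 and g = 1 yr, one Ma equals one coalescent
unit. Under the MSC the probability that a quartet around an internal
branch of length d matches the species tree is 1 - (2/3) e^(-d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tree import PhyloNode, PhyloTree, contract_edge

__all__ = [
    "SpeciesTreeModel",
    "simulate_species_tree",
    "time_to_coalescent_units",
    "simulate_gene_trees",
    "simulate_hybrid_gene_trees",
    "apply_gene_tree_error",
    "apply_branch_length_noise",
    "random_topology",
]

DEFAULT_NE = 5.0e5
DEFAULT_GEN_TIME = 1.0
DEFAULT_RATE = 1.0e-3  # subs/site/Ma


@dataclass
class SpeciesTreeModel:
    """Ultrametric species tree (Ma) with per-branch Ne, g and substitution rate.

    Per-branch quantities are keyed by the clade (frozenset of taxon labels)
    below the branch; the key covering all taxa describes the stem above the
    root, where any remaining lineages must coalesce.
    """

    tree: PhyloTree
    ne: dict[frozenset, float] = field(default_factory=dict)
    gen_time: dict[frozenset, float] = field(default_factory=dict)
    rate: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self):
        for key, d in (("ne", self.ne), ("gen_time", self.gen_time)):
            for clade, v in d.items():
                if v <= 0:
                    raise ValueError(f"{key} must be positive on branch {sorted(clade)}")

    # -- bookkeeping ---------------------------------------------------
    def clade_keys(self) -> list[frozenset]:
        return [clade for clade in self.tree.clades().values()]

    def fill_defaults(
        self,
        ne: float = DEFAULT_NE,
        gen_time: float = DEFAULT_GEN_TIME,
        rate: float = DEFAULT_RATE,
    ) -> "SpeciesTreeModel":
        for clade in set(self.clade_keys()):
            self.ne.setdefault(clade, ne)
            self.gen_time.setdefault(clade, gen_time)
            self.rate.setdefault(clade, rate)
        return self

    def node_ages(self) -> dict[PhyloNode, float]:
        """Ages (Ma before present) assuming the tree is ultrametric."""
        depths = self.tree.depths()
        tips = self.tree.leaves()
        max_d = max(depths[t] for t in tips)
        ages = {n: max_d - d for n, d in depths.items()}
        for t in tips:
            if abs(ages[t]) > 1e-6 * max(max_d, 1.0):
                raise ValueError("species tree is not ultrametric")
            ages[t] = 0.0
        return ages

    def coalescent_rate_per_ma(self, clade: frozenset) -> float:
        """Pairwise coalescence rate per Ma on the branch above ``clade``."""
        try:
            ne = self.ne[clade]
            g = self.gen_time[clade]
        except KeyError:
            raise ValueError(f"Ne/generation time missing on branch {sorted(clade)}") from None
        return 1.0e6 / (2.0 * ne * g)

    def branch_table(self) -> list[tuple[frozenset, float, float, float]]:
        """(clade, duration T in Ma, coalescent length d, Ne) per non-root branch."""
        ages = self.node_ages()
        clades = self.tree.clades()
        out = []
        for node, clade in clades.items():
            if node is self.tree.root:
                continue
            T = ages[node.parent] - ages[node]
            d = T * self.coalescent_rate_per_ma(clade)
            out.append((clade, T, d, self.ne[clade]))
        return out


def random_topology(taxa: list[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform-random sequential-join binary topology (no meaningful lengths)."""
    nodes = [PhyloNode(label=t, length=1.0) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = PhyloNode(length=1.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i] = parent
        del nodes[j]
    nodes[0].length = None
    return PhyloTree(nodes[0])


def simulate_species_tree(
    n_taxa: int,
    birth_rate: float = 0.1,
    seed: int | np.random.SeedSequence | None = None,
    ne: float = DEFAULT_NE,
    gen_time: float = DEFAULT_GEN_TIME,
    rate: float = DEFAULT_RATE,
) -> SpeciesTreeModel:
    """Yule (pure-birth) ultrametric species tree in Ma with default Ne/g/rate.

    Backward construction: with k extant lineages the next (older) join is
    an Exp(k * birth_rate) waiting time, giving expected root age
    sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4 (quartet machinery undefined below 4)")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    lineages: list[tuple[PhyloNode, float]] = [
        (PhyloNode(label=f"t{i + 1:0{width}d}"), 0.0) for i in range(n_taxa)
    ]
    age = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        age += rng.exponential(1.0 / (k * birth_rate))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, age_a), (b, age_b) = lineages[i], lineages[j]
        parent = PhyloNode()
        a.length = age - age_a
        b.length = age - age_b
        parent.add_child(a)
        parent.add_child(b)
        lineages[i] = (parent, age)
        del lineages[j]
    root = lineages[0][0]
    model = SpeciesTreeModel(PhyloTree(root, unit="Ma"))
    model.fill_defaults(ne=ne, gen_time=gen_time, rate=rate)
    return model


def time_to_coalescent_units(model: SpeciesTreeModel) -> PhyloTree:
    """Species tree with branch lengths converted to coalescent units."""
    ages = model.node_ages()
    clades = model.tree.clades()
    out = model.tree.copy()
    out_clades = out.clades()
    # map by clade identity (copy preserves topology)
    dur = {
        clades[n]: ages[n.parent] - ages[n]
        for n in clades
        if n is not model.tree.root
    }
    for node in out.preorder():
        if node is out.root:
            continue
        clade = out_clades[node]
        node.length = dur[clade] * model.coalescent_rate_per_ma(clade)
    out.unit = "coalescent"
    return out


def coalescent_to_time(tree_cu: PhyloTree, model: SpeciesTreeModel) -> PhyloTree:
    """Inverse of :func:`time_to_coalescent_units` given the same Ne/g."""
    out = tree_cu.copy()
    clades = out.clades()
    for node in out.preorder():
        if node is out.root:
            continue
        node.length = node.length / model.coalescent_rate_per_ma(clades[node])
    out.unit = "Ma"
    return out


# ---------------------------------------------------------------------------
# MSC gene-tree simulation
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node", "ma", "cu", "subs")

    def __init__(self, node: PhyloNode):
        self.node = node
        self.ma = 0.0
        self.cu = 0.0
        self.subs = 0.0

    def advance(self, dt_ma: float, c_per_ma: float, rate: float) -> None:
        self.ma += dt_ma
        self.cu += dt_ma * c_per_ma
        self.subs += dt_ma * rate


def _close_edge(lin: _Lineage, unit: str) -> float:
    return {"Ma": lin.ma, "coalescent": lin.cu, "subs/site": lin.subs}[unit]


def _simulate_one_gene_tree(
    model: SpeciesTreeModel, rng: np.random.Generator, unit: str
) -> PhyloTree:
    ages = model.node_ages()
    clades = model.tree.clades()
    # species nodes processed in order of increasing age (children before parents)
    order = sorted(clades, key=lambda n: (ages[n], 0 if n.is_leaf else 1))
    pending: dict[int, list[_Lineage]] = {}

    def run_branch(lineages: list[_Lineage], span: float, c: float, r: float) -> None:
        cur = 0.0
        while len(lineages) >= 2:
            k = len(lineages)
            pair_rate = 0.5 * k * (k - 1) * c
            w = rng.exponential(1.0 / pair_rate) if pair_rate > 0 else math.inf
            if cur + w > span:
                break
            for lin in lineages:
                lin.advance(w, c, r)
            cur += w
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = lineages[i], lineages[j]
            parent = PhyloNode()
            a.node.length = _close_edge(a, unit)
            b.node.length = _close_edge(b, unit)
            parent.add_child(a.node)
            parent.add_child(b.node)
            lineages[i] = _Lineage(parent)
            del lineages[j]
        if math.isfinite(span):
            rem = span - cur
            for lin in lineages:
                lin.advance(rem, c, r)

    for snode in order:
        clade = clades[snode]
        if snode.is_leaf:
            lineages = [_Lineage(PhyloNode(label=snode.label))]
        else:
            lineages = []
            for child in snode.children:
                lineages.extend(pending.pop(id(child)))
        c = model.coalescent_rate_per_ma(clade)
        r = model.rate.get(clade, 0.0)
        if snode is model.tree.root:
            run_branch(lineages, math.inf, c, r)
        else:
            span = ages[snode.parent] - ages[snode]
            run_branch(lineages, span, c, r)
        pending[id(snode)] = lineages

    (last,) = pending[id(model.tree.root)]
    last.node.length = None
    return PhyloTree(last.node, unit=unit)


def _locus_seeds(seed, n_loci: int, extra: int = 0) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n_loci + extra)


def simulate_gene_trees(
    model: SpeciesTreeModel,
    n_loci: int,
    seed: int | np.random.SeedSequence | None = None,
    unit: str = "coalescent",
) -> list[PhyloTree]:
    """Draw ``n_loci`` gene trees under the MSC, one sampled lineage per species.

    ``unit`` selects the output branch lengths: ``"coalescent"`` (local
    units, summed across the species branches a lineage traverses),
    ``"Ma"``, or ``"subs/site"`` using the model's per-branch rates.
    """
    if unit not in ("coalescent", "Ma", "subs/site"):
        raise ValueError(f"unknown unit {unit!r}")
    seeds = _locus_seeds(seed, n_loci)
    return [
        _simulate_one_gene_tree(model, np.random.default_rng(s), unit)
        for s in seeds[:n_loci]
    ]


# ---------------------------------------------------------------------------
# hybridization as a locus-level tree mixture
# ---------------------------------------------------------------------------

def reroute_clade(
    model: SpeciesTreeModel, donor: frozenset, recipient: frozenset
) -> SpeciesTreeModel:
    """Alternative species tree with the ``recipient`` clade attached to the
    ``donor`` branch (pulse-introgression topology), at the midpoint of the
    time interval where both branches exist."""
    donor = frozenset(donor)
    recipient = frozenset(recipient)
    tree = model.tree.copy()
    clades = tree.clades()
    by_clade = {c: n for n, c in clades.items()}
    if donor not in by_clade or recipient not in by_clade:
        raise ValueError("donor or recipient clade not present in the species tree")
    if donor & recipient:
        raise ValueError("donor and recipient clades overlap")
    ages = SpeciesTreeModel(tree).node_ages()
    d_node = by_clade[donor]
    r_node = by_clade[recipient]
    lo = max(ages[d_node], ages[r_node])
    hi = min(ages[d_node.parent], ages[r_node.parent])
    if hi <= lo:
        raise ValueError("donor and recipient branches do not overlap in time")
    t_attach = 0.5 * (lo + hi)

    # detach recipient
    r_parent = r_node.parent
    r_parent.children.remove(r_node)
    # insert attachment node on the donor branch
    d_parent = d_node.parent
    idx = d_parent.children.index(d_node)
    join = PhyloNode(length=ages[d_parent] - t_attach)
    d_parent.children[idx] = join
    join.parent = d_parent
    join.add_child(d_node)
    d_node.length = t_attach - ages[d_node]
    join.add_child(r_node)
    r_node.length = t_attach - ages[r_node]
    out_tree = PhyloTree(tree.root, unit="Ma")
    out_tree.suppress_unifurcations()

    out = SpeciesTreeModel(out_tree)
    # carry over Ne/g/rate by clade; new/changed branches inherit sensible donors
    for attr in ("ne", "gen_time", "rate"):
        src = getattr(model, attr)
        dst = getattr(out, attr)
        for clade in set(out.clade_keys()):
            if clade in src:
                dst[clade] = src[clade]
            elif clade == donor | recipient:
                dst[clade] = src[donor]
    all_taxa = out_tree.taxa
    default = {
        "ne": model.ne.get(frozenset(model.tree.taxa), DEFAULT_NE),
        "gen_time": model.gen_time.get(frozenset(model.tree.taxa), DEFAULT_GEN_TIME),
        "rate": model.rate.get(frozenset(model.tree.taxa), DEFAULT_RATE),
    }
    for attr in ("ne", "gen_time", "rate"):
        dst = getattr(out, attr)
        for clade in set(out.clade_keys()):
            dst.setdefault(clade, default[attr])
    return out


def simulate_hybrid_gene_trees(
    model: SpeciesTreeModel,
    donor: frozenset,
    recipient: frozenset,
    gamma: float,
    n_loci: int,
    seed: int | np.random.SeedSequence | None = None,
    unit: str = "coalescent",
) -> tuple[list[PhyloTree], np.ndarray]:
    """Mixture MSC: each locus follows the rerouted tree with probability gamma.

    Returns the gene trees and the boolean per-locus assignment vector.
    With ``gamma = 0`` the output equals :func:`simulate_gene_trees` under the
    same seed (the per-locus seed streams are shared by construction).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    alt = reroute_clade(model, donor, recipient)
    seeds = _locus_seeds(seed, n_loci, extra=1)
    assign_rng = np.random.default_rng(seeds[-1])
    rerouted = assign_rng.random(n_loci) < gamma
    gts = [
        _simulate_one_gene_tree(
            alt if rerouted[i] else model, np.random.default_rng(seeds[i]), unit
        )
        for i in range(n_loci)
    ]
    return gts, rerouted


# ---------------------------------------------------------------------------
# gene-tree estimation error
# ---------------------------------------------------------------------------

def _random_nni(tree: PhyloTree, node: PhyloNode, rng: np.random.Generator) -> None:
    """Apply one NNI across the unrooted edge above ``node`` (internal, non-root)."""
    parent = node.parent
    if parent is tree.root and len(tree.root.children) == 2:
        # the unrooted edge joins node and its (internal) sibling: swap one
        # child of each across the edge
        sib = next(c for c in tree.root.children if c is not node)
        if sib.is_leaf or not node.children:
            return
        x = node.children[int(rng.integers(len(node.children)))]
        y = sib.children[int(rng.integers(len(sib.children)))]
        ni, si = node.children.index(x), sib.children.index(y)
        node.children[ni], sib.children[si] = y, x
        x.parent, y.parent = sib, node
        return
    siblings = [c for c in parent.children if c is not node]
    if not siblings or not node.children:
        return
    s = siblings[int(rng.integers(len(siblings)))]
    x = node.children[int(rng.integers(len(node.children)))]
    pi = parent.children.index(s)
    ni = node.children.index(x)
    parent.children[pi], node.children[ni] = x, s
    x.parent, s.parent = parent, node


def apply_gene_tree_error(
    gene_trees: list[PhyloTree],
    p_nni: float = 0.0,
    collapse_fraction: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
) -> list[PhyloTree]:
    """Perturb gene trees: random NNIs then contraction of the shortest edges.

    Each internal edge is independently NNI-perturbed with probability
    ``p_nni``; then per tree the ``floor(collapse_fraction * n_internal)``
    shortest internal edges are contracted to polytomies, emulating the
    collapse of poorly supported branches in estimated gene trees.
    """
    if not 0.0 <= p_nni <= 1.0 or not 0.0 <= collapse_fraction <= 1.0:
        raise ValueError("p_nni and collapse_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for gt in gene_trees:
        t = gt.copy()
        for node in t.internal_edges():
            if rng.random() < p_nni:
                _random_nni(t, node, rng)
        internals = t.internal_edges()
        n_cut = int(math.floor(collapse_fraction * len(internals)))
        if n_cut:
            order = sorted(
                range(len(internals)), key=lambda i: (internals[i].length or 0.0, i)
            )
            for i in order[:n_cut]:
                node = internals[i]
                if node.parent is not None and node in node.parent.children:
                    contract_edge(t, node)
        out.append(t)
    return out


def apply_branch_length_noise(
    gene_trees: list[PhyloTree],
    sdlog: float,
    seed: int | np.random.SeedSequence | None = None,
) -> list[PhyloTree]:
    """Multiplicative lognormal branch-length noise with median multiplier 1."""
    rng = np.random.default_rng(seed)
    out = []
    for gt in gene_trees:
        t = gt.copy()
        for node in t.preorder():
            if node is t.root or node.length is None:
                continue
            node.length *= math.exp(rng.normal(0.0, sdlog))
        out.append(t)
    return out
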