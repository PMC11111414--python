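"""Per-branch quartet frequencies, support statistics, discordance tests and a
desk-scale coalescent species-tree estimator.

Around every internal branch of a binary species tree there are four taxon
groups (A, B | C, D) and three possible resolutions of the quartets drawn one
taxon per group: the species-tree pairing AB|CD and the two nearest-neighbour
interchange (NNI) alternatives AC|BD and AD|BC. Under the multispecies
coalescent with internal branch length d (coalescent units), the matching
resolution has probability 1 - (2/3) e^(-d) and each alternative
(1/3) e^(-d); equality of the two alternatives is the incomplete-lineage-
sorting (ILS) expectation that the asymmetry test checks, and equality of
all three is the polytomy null.

Counting one-per-group tuples is done without enumeration, by an aggregation
identity over the gene tree: a tuple resolved as AB|CD is separated by the
edges of its central path (k of them) and "witnessed" by the k + 1 vertices
on that path, so

    count(AB|CD) = sum over internal vertices of compatible component
                   patterns  -  sum over internal edges of separating
                   patterns

counts every resolved tuple exactly once. An explicit enumeration oracle is
shipped alongside (:func:`branch_quartet_frequencies_enum`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
from scipy import integrate, special, stats

from .tree import PhyloNode, PhyloTree

__all__ = [
    "QuartetSupport",
    "branch_quartet_frequencies",
    "branch_quartet_frequencies_enum",
    "total_quartet_score",
    "total_quartet_score_enum",
    "coalescent_branch_length",
    "local_posterior",
    "local_posterior_quadrature",
    "polytomy_test",
    "asymmetry_pvalue",
    "asymmetry_test",
    "multilocus_bootstrap",
    "estimate_species_tree",
    "msc_match_probability",
    "QuartetLabeler",
]


def msc_match_probability(d: float) -> float:
    """P(quartet matches the species tree) for internal branch length d (CU)."""
    return 1.0 - (2.0 / 3.0) * math.exp(-d)


# ---------------------------------------------------------------------------
# bitmask plumbing
# ---------------------------------------------------------------------------

class TaxonIndex:
    """Stable taxon -> bit assignment shared by a set of trees."""

    def __init__(self, taxa: Iterable[str]):
        self.labels = sorted(set(taxa))
        self.bit = {t: i for i, t in enumerate(self.labels)}
        self.n = len(self.labels)
        self.words = (self.n + 63) // 64

    def mask_int(self, labels: Iterable[str]) -> int:
        m = 0
        for t in labels:
            m |= 1 << self.bit[t]
        return m

    def to_words(self, mask: int) -> np.ndarray:
        out = np.zeros(self.words, dtype=np.uint64)
        for w in range(self.words):
            out[w] = (mask >> (64 * w)) & 0xFFFFFFFFFFFFFFFF
        return out


def _popcount(masks: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Popcount of ``masks & group`` summed over the word axis."""
    return np.bitwise_count(masks & group).sum(axis=-1).astype(np.int64)


def _tree_structure(tree: PhyloTree, index: TaxonIndex):
    """Leaf mask, internal-edge masks and vertex component masks of one tree."""
    clades = tree.clades()
    leafmask = index.mask_int(tree.taxa)
    n_gt = tree.n_taxa
    edges: set[int] = set()
    nodes: list[list[int]] = []
    for node, clade in clades.items():
        if node.is_leaf:
            continue
        cmask = index.mask_int(clade)
        if node is tree.root:
            if len(node.children) >= 3:
                nodes.append([index.mask_int(clades[c]) for c in node.children])
            continue
        k = len(clade)
        if 2 <= k <= n_gt - 2:
            edges.add(min(cmask, leafmask ^ cmask))
        comps = [index.mask_int(clades[c]) for c in node.children]
        comps.append(leafmask ^ cmask)
        nodes.append(comps)
    return leafmask, sorted(edges), nodes


class GeneTreeData:
    """Stacked bitmask representation of a gene-tree set for vectorized counting."""

    def __init__(self, gene_trees: Sequence[PhyloTree], index: TaxonIndex | None = None):
        if index is None:
            all_taxa: set[str] = set()
            for gt in gene_trees:
                all_taxa |= gt.taxa
            index = TaxonIndex(all_taxa)
        self.index = index
        self.n_gt = len(gene_trees)
        leafmasks = []
        edge_masks: list[np.ndarray] = []
        edge_gt: list[int] = []
        by_deg: dict[int, tuple[list, list]] = {}
        for g, gt in enumerate(gene_trees):
            leafmask, edges, nodes = _tree_structure(gt, index)
            leafmasks.append(index.to_words(leafmask))
            for e in edges:
                edge_masks.append(index.to_words(e))
                edge_gt.append(g)
            for comps in nodes:
                m = len(comps)
                masks, gts = by_deg.setdefault(m, ([], []))
                masks.append([index.to_words(c) for c in comps])
                gts.append(g)
        W = index.words
        self.leafmasks = np.array(leafmasks, dtype=np.uint64).reshape(self.n_gt, W)
        self.edge_masks = (
            np.array(edge_masks, dtype=np.uint64).reshape(len(edge_masks), W)
            if edge_masks
            else np.zeros((0, W), dtype=np.uint64)
        )
        self.edge_gt = np.array(edge_gt, dtype=np.int64)
        self.nodes_by_degree = {
            m: (np.array(masks, dtype=np.uint64).reshape(len(gts), m, W),
                np.array(gts, dtype=np.int64))
            for m, (masks, gts) in by_deg.items()
        }

    # patterns (i, j, k, l) over m components with {i,j} and {k,l} disjoint
    # and (i == j or k == l): the vertex lies on the central path of the tuple.
    _pattern_cache: dict[int, list[tuple[int, int, int, int]]] = {}

    @classmethod
    def _patterns(cls, m: int) -> list[tuple[int, int, int, int]]:
        if m not in cls._pattern_cache:
            pats = [
                (i, j, k, l)
                for i, j, k, l in itertools.product(range(m), repeat=4)
                if not ({i, j} & {k, l}) and (i == j or k == l)
            ]
            cls._pattern_cache[m] = pats
        return cls._pattern_cache[m]

    def count_tuples(
        self, groups: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    ) -> np.ndarray:
        """Per-gene-tree counts of one-per-group tuples resolved as each topology.

        Returns an (n_gt, 4) array: columns are the counts for the pairings
        (AB|CD, AC|BD, AD|BC) and the total number of available tuples
        (taxa present in all four groups), from which unresolved = total -
        resolved follows.
        """
        A, B, C, D = groups
        tot = np.stack([_popcount(self.leafmasks, g) for g in (A, B, C, D)], axis=1)
        n_tuples = tot.prod(axis=1)
        out = np.zeros((self.n_gt, 4), dtype=np.float64)
        out[:, 3] = n_tuples
        if not n_tuples.any():
            return out

        pairings = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))
        glist = (A, B, C, D)

        # edge term
        if len(self.edge_gt):
            e_in = [_popcount(self.edge_masks, g) for g in glist]
            e_out = [tot[self.edge_gt, i] - e_in[i] for i in range(4)]
            for t, (p, q, r, s) in enumerate(pairings):
                ee = (
                    e_in[p] * e_in[q] * e_out[r] * e_out[s]
                    + e_out[p] * e_out[q] * e_in[r] * e_in[s]
                )
                out[:, t] -= np.bincount(self.edge_gt, weights=ee, minlength=self.n_gt)

        # vertex term
        for m, (masks, node_gt) in self.nodes_by_degree.items():
            P = [_popcount(masks, g) for g in glist]  # each (N, m)
            for t, (p, q, r, s) in enumerate(pairings):
                acc = np.zeros(len(node_gt), dtype=np.float64)
                for i, j, k, l in self._patterns(m):
                    acc += P[p][:, i] * P[q][:, j] * P[r][:, k] * P[s][:, l]
                out[:, t] += np.bincount(node_gt, weights=acc, minlength=self.n_gt)
        return out


# ---------------------------------------------------------------------------
# species-tree branch decomposition
# ---------------------------------------------------------------------------

def _branch_decompositions(species_tree: PhyloTree):
    """Yield (bipartition, (A, B, C, D)) for internal branches with a binary
    context on both sides (the three NNI resolutions are defined only there).

    A branch adjacent to the root of a rooted representation is handled by
    decomposing the sibling subtree (the standard 3-cluster treatment of the
    unrooted tree).
    """
    taxa = species_tree.taxa
    ref = min(taxa)
    clades = species_tree.clades()
    seen: set[frozenset] = set()
    for v in species_tree.preorder():
        if v.is_leaf or v is species_tree.root:
            continue
        cv = clades[v]
        if not (2 <= len(cv) <= len(taxa) - 2):
            continue
        bip = taxa - cv if ref in cv else cv
        if bip in seen:
            continue
        if len(v.children) != 2:
            continue
        A, B = clades[v.children[0]], clades[v.children[1]]
        p = v.parent
        others = [clades[c] for c in p.children if c is not v]
        rest = taxa - clades[p]
        sides = others + ([rest] if rest else [])
        if len(sides) == 2:
            C, D = sides
        elif len(sides) == 1:
            sib = next(c for c in p.children if c is not v)
            if sib.is_leaf or len(sib.children) != 2:
                continue
            C, D = clades[sib.children[0]], clades[sib.children[1]]
        else:
            continue
        A, B = sorted((A, B), key=min)
        C, D = sorted((C, D), key=min)
        seen.add(bip)
        yield bip, (A, B, C, D)


@dataclass
class QuartetSupport:
    """Quartet counts and frequencies for the three resolutions of one branch.

    ``n1`` corresponds to the species-tree pairing AB|CD; ``n2`` to AC|BD and
    ``n3`` to AD|BC, with groups in canonical (smallest-taxon) order. With
    per-gene weighting each contributing gene tree adds its within-tree
    resolved-quartet proportions (so counts are non-integer and sum to the
    number of contributing gene trees, ``effective_n``).
    """

    branch: frozenset
    groups: tuple[frozenset, frozenset, frozenset, frozenset]
    n1: float
    n2: float
    n3: float
    raw: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_unresolved: float = 0.0

    @property
    def effective_n(self) -> float:
        return self.n1 + self.n2 + self.n3

    @property
    def frequencies(self) -> tuple[float, float, float]:
        n = self.effective_n
        if n == 0:
            return (math.nan, math.nan, math.nan)
        return (self.n1 / n, self.n2 / n, self.n3 / n)

    @property
    def q1(self) -> float:
        return self.frequencies[0]


def branch_quartet_frequencies(
    species_tree: PhyloTree,
    gene_trees: Sequence[PhyloTree] | GeneTreeData,
    weighting: str = "per-gene",
    unresolved: str = "none",
) -> list[QuartetSupport]:
    """Quartet counts of the three NNI resolutions around every internal branch.

    Gene trees may miss taxa and contain polytomies; unresolved quartets
    contribute to no topology by default (``unresolved="third"`` splits them
    1/3 each as a sensitivity mode). ``weighting="per-gene"`` normalizes each
    gene tree's contribution to 1; ``"raw"`` sums tuple counts directly.
    """
    if weighting not in ("per-gene", "raw"):
        raise ValueError("weighting must be 'per-gene' or 'raw'")
    if unresolved not in ("none", "third"):
        raise ValueError("unresolved must be 'none' or 'third'")
    if isinstance(gene_trees, GeneTreeData):
        data = gene_trees
    else:
        index = TaxonIndex(set(species_tree.taxa).union(*[gt.taxa for gt in gene_trees]))
        data = GeneTreeData(gene_trees, index)
    index = data.index

    out = []
    for bip, groups in _branch_decompositions(species_tree):
        words = tuple(index.to_words(index.mask_int(g)) for g in groups)
        counts = data.count_tuples(words)
        resolved = counts[:, :3].copy()
        if unresolved == "third":
            unres = counts[:, 3] - counts[:, :3].sum(axis=1)
            resolved += (unres / 3.0)[:, None]
        tot = resolved.sum(axis=1)
        contributing = tot > 0
        raw = tuple(float(x) for x in resolved.sum(axis=0))
        if weighting == "per-gene":
            with np.errstate(invalid="ignore", divide="ignore"):
                norm = np.where(contributing[:, None], resolved / np.where(tot, tot, 1.0)[:, None], 0.0)
            n1, n2, n3 = (float(x) for x in norm.sum(axis=0))
        else:
            n1, n2, n3 = raw
        out.append(
            QuartetSupport(
                branch=bip,
                groups=groups,
                n1=n1,
                n2=n2,
                n3=n3,
                raw=raw,
                n_unresolved=float(counts[:, 3].sum() - counts[:, :3].sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def _quartet_topology(bips: list[frozenset], quartet: tuple[str, str, str, str]) -> int | None:
    """Resolution of one quartet in a tree given its bipartitions (clade sides).

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, None if unresolved.
    """
    a, b, c, d = quartet
    for side in bips:
        ina, inb, inc, ind = a in side, b in side, c in side, d in side
        tot = ina + inb + inc + ind
        if tot != 2:
            continue
        if ina == inb:
            return 0
        if ina == inc:
            return 1
        if ina == ind:
            return 2
    return None


def _all_clades(tree: PhyloTree) -> list[frozenset]:
    clades = tree.clades()
    return [clades[n] for n in tree.preorder() if not n.is_leaf and n is not tree.root]


def branch_quartet_frequencies_enum(
    species_tree: PhyloTree,
    gene_trees: Sequence[PhyloTree],
    weighting: str = "per-gene",
) -> list[QuartetSupport]:
    """Brute-force oracle: loop over all one-per-group tuples of each gene tree."""
    gt_info = [( _all_clades(gt), gt.taxa) for gt in gene_trees]
    out = []
    for bip, groups in _branch_decompositions(species_tree):
        per_gene = np.zeros((len(gene_trees), 3))
        unres_total = 0.0
        for g, (bips, taxa) in enumerate(gt_info):
            present = [sorted(gr & taxa) for gr in groups]
            if any(not p for p in present):
                continue
            for tup in itertools.product(*present):
                topo = _quartet_topology(bips, tup)
                if topo is None:
                    unres_total += 1
                else:
                    per_gene[g, topo] += 1
        tot = per_gene.sum(axis=1)
        raw = tuple(float(x) for x in per_gene.sum(axis=0))
        if weighting == "per-gene":
            mask = tot > 0
            norm = np.zeros_like(per_gene)
            norm[mask] = per_gene[mask] / tot[mask, None]
            n1, n2, n3 = (float(x) for x in norm.sum(axis=0))
        else:
            n1, n2, n3 = raw
        out.append(QuartetSupport(bip, groups, n1, n2, n3, raw=raw, n_unresolved=unres_total))
    return out


# ---------------------------------------------------------------------------
# total quartet score and labelling cache
# ---------------------------------------------------------------------------

class QuartetLabeler:
    """Cache of per-gene-tree resolutions of all four-taxon subsets.

    Labels: 0/1/2 for the pairings ij|kl, ik|jl, il|jk of the sorted quartet
    (i < j < k < l); 3 unresolved; 4 at least one taxon missing.
    """

    def __init__(self, gene_trees: Sequence[PhyloTree], taxa: Iterable[str]):
        self.index = TaxonIndex(taxa)
        n = self.index.n
        self.quartets = np.array(
            list(itertools.combinations(range(n), 4)), dtype=np.int64
        )
        self.n_quartets = len(self.quartets)
        labels = np.empty((len(gene_trees), self.n_quartets), dtype=np.int8)
        for g, gt in enumerate(gene_trees):
            labels[g] = self.labels_for(gt)
        self.labels = labels
        # per-quartet counts of each resolution across gene trees
        self.match_counts = np.stack(
            [(labels == t).sum(axis=0) for t in range(3)], axis=1
        ).astype(np.float64)
        self.total_resolved = float(self.match_counts.sum())

    def _membership(self, tree: PhyloTree) -> tuple[np.ndarray, np.ndarray]:
        index = self.index
        clades = tree.clades()
        masks = []
        for node in tree.preorder():
            if node.is_leaf or node is tree.root:
                continue
            masks.append(index.to_words(index.mask_int(clades[node])))
        W = index.words
        arr = (
            np.array(masks, dtype=np.uint64).reshape(len(masks), W)
            if masks
            else np.zeros((0, W), dtype=np.uint64)
        )
        shifts = np.arange(64, dtype=np.uint64)
        cols = [((arr[:, w : w + 1] >> shifts) & np.uint64(1)) for w in range(W)]
        M = np.concatenate(cols, axis=1)[:, : index.n].astype(bool)
        present = np.zeros(index.n, dtype=bool)
        for t in tree.taxa:
            present[index.bit[t]] = True
        return M, present

    def labels_for(self, tree: PhyloTree) -> np.ndarray:
        """Label every quartet of the universe for one tree."""
        M, present = self._membership(tree)
        Q = self.quartets
        out = np.full(self.n_quartets, 3, dtype=np.int8)
        missing = ~present[Q].all(axis=1)
        if len(M):
            inq = M[:, Q]  # (E, Q, 4)
            s = inq.sum(axis=2)
            two = s == 2
            for t, (x, y) in enumerate(((0, 1), (0, 2), (0, 3))):
                hit = (two & (inq[:, :, x] == inq[:, :, y])).any(axis=0)
                out[hit] = t
        out[missing] = 4
        return out

    def score(self, candidate: PhyloTree) -> tuple[float, float]:
        """(weighted concordant count, fraction of resolved gene-tree quartets)."""
        lab = self.labels_for(candidate)
        resolved = lab < 3
        idx = np.nonzero(resolved)[0]
        count = float(self.match_counts[idx, lab[idx]].sum())
        frac = count / self.total_resolved if self.total_resolved else math.nan
        return count, frac


def total_quartet_score(
    candidate_tree: PhyloTree,
    gene_trees: Sequence[PhyloTree] | QuartetLabeler,
) -> tuple[float, float]:
    """Weighted count and fraction of gene-tree quartets concordant with the
    candidate topology, comparable across candidates on the same gene trees."""
    if isinstance(gene_trees, QuartetLabeler):
        labeler = gene_trees
    else:
        if not gene_trees:
            raise ValueError("empty gene-tree set")
        labeler = QuartetLabeler(gene_trees, candidate_tree.taxa)
    return labeler.score(candidate_tree)


def total_quartet_score_enum(
    candidate_tree: PhyloTree, gene_trees: Sequence[PhyloTree]
) -> tuple[float, float]:
    """Pure-Python oracle for :func:`total_quartet_score`."""
    if not gene_trees:
        raise ValueError("empty gene-tree set")
    cand_bips = _all_clades(candidate_tree)
    count = 0
    total = 0
    for gt in gene_trees:
        bips = _all_clades(gt)
        shared = sorted(gt.taxa & candidate_tree.taxa)
        for quartet in itertools.combinations(shared, 4):
            topo = _quartet_topology(bips, quartet)
            if topo is None:
                continue
            total += 1
            if _quartet_topology(cand_bips, quartet) == topo:
                count += 1
    return float(count), (count / total if total else math.nan)


# ---------------------------------------------------------------------------
# branch statistics
# ---------------------------------------------------------------------------

class CoalescentLength(NamedTuple):
    d: float
    saturated: bool


def coalescent_branch_length(q1: float, cap: float = 10.0) -> CoalescentLength:
    """Invert q1 = 1 - (2/3) e^(-d): d = -ln(1.5 (1 - q1)), capped.

    q1 <= 1/3 maps to d = 0 (at or below the polytomy expectation);
    q1 at or beyond the cap's resolution returns the cap, flagged saturated.
    """
    if not 0.0 <= q1 <= 1.0:
        raise ValueError("q1 must be in [0, 1]")
    if q1 <= 1.0 / 3.0:
        return CoalescentLength(0.0, False)
    arg = 1.5 * (1.0 - q1)
    if arg <= math.exp(-cap):
        return CoalescentLength(cap, True)
    return CoalescentLength(-math.log(arg), False)


def _log_marginal(n_i: float, n: float, prior_rate: float) -> float:
    """Log marginal likelihood that resolution i (with n_i of n quartets) is true.

    Integrates the multinomial quartet likelihood against the exponential
    (Yule) branch-length prior with rate ``prior_rate``; closed form via the
    regularized incomplete beta function.
    """
    alpha = prior_rate + n - n_i
    b = n_i + 1.0
    log_ib = math.log(special.betainc(alpha, b, 2.0 / 3.0))
    return (
        (n - n_i) * math.log(1.0 / 3.0)
        + alpha * math.log(1.5)
        + special.betaln(alpha, b)
        + log_ib
    )


def local_posterior(
    support: QuartetSupport | tuple[float, float, float], prior_rate: float = 0.5
) -> tuple[float, float, float]:
    """Local posterior probability of each resolution being the species-tree branch.

    Closed form under the quartet-frequency model with an exponential prior
    on the branch length (rate ``prior_rate``) and equal prior probability
    1/3 for each topology. Weighted (non-integer) counts are supported.
    """
    ns = (support.n1, support.n2, support.n3) if isinstance(support, QuartetSupport) else tuple(support)
    n = sum(ns)
    if n <= 0:
        return (1.0 / 3.0,) * 3
    logs = [_log_marginal(ni, n, prior_rate) for ni in ns]
    mx = max(logs)
    ws = [math.exp(v - mx) for v in logs]
    tot = sum(ws)
    return tuple(w / tot for w in ws)


def local_posterior_quadrature(
    support: QuartetSupport | tuple[float, float, float], prior_rate: float = 0.5
) -> tuple[float, float, float]:
    """Numerical-integration oracle for :func:`local_posterior`."""
    ns = (support.n1, support.n2, support.n3) if isinstance(support, QuartetSupport) else tuple(support)
    n = sum(ns)
    if n <= 0:
        return (1.0 / 3.0,) * 3

    def marginal(n_i: float) -> float:
        def dens(d: float) -> float:
            p = 1.0 - (2.0 / 3.0) * math.exp(-d)
            return (
                prior_rate
                * math.exp(-prior_rate * d)
                * p ** n_i
                * ((1.0 - p) / 2.0) ** (n - n_i)
            )

        val, _ = integrate.quad(dens, 0.0, np.inf, limit=200)
        return val

    ws = [marginal(ni) for ni in ns]
    tot = sum(ws)
    return tuple(w / tot for w in ws)


def polytomy_test(support: QuartetSupport | tuple[float, float, float]) -> float | None:
    """Chi-square test of (n1, n2, n3) against the 1/3-each polytomy null (2 df).

    Weighted counts are rounded to the nearest integer before the statistic
    is formed; returns None when the effective count is zero.
    """
    ns = (support.n1, support.n2, support.n3) if isinstance(support, QuartetSupport) else tuple(support)
    ns = [round(x) for x in ns]
    n = sum(ns)
    if n <= 0:
        return None
    e = n / 3.0
    stat = sum((o - e) ** 2 / e for o in ns)
    return float(stats.chi2.sf(stat, df=2))


def asymmetry_pvalue(a: float, b: float) -> float | None:
    """One-sided chi-square p-value for H1: a > b against the equal-split null.

    Statistic (a - b)^2 / (a + b) with 1 df; the two-sided p is halved when
    a > b, equals 0.5 when a == b, and is 1 - p/2 when a < b.
    """
    if a + b <= 0:
        return None
    if a == b:
        return 0.5
    stat = (a - b) ** 2 / (a + b)
    p2 = float(stats.chi2.sf(stat, df=1))
    return p2 / 2.0 if a > b else 1.0 - p2 / 2.0


def benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    """Monotone step-up BH adjustment (adjusted p-values, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    if not len(pvals):
        return []
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(a) for a in adj]


def asymmetry_test(
    branches: Sequence[QuartetSupport],
    comparisons: str = "both",
    direction: str = "canonical",
):
    """ILS-asymmetry screen over a family of branches with BH correction.

    Two one-sided comparisons per branch: ``main`` (species resolution vs the
    larger alternative; hybridization/paraphyly signal when the alternative
    wins) and ``alt`` (the two alternatives against each other; ILS predicts
    equality). ``direction="canonical"`` tests n2 > n3 in the canonical group
    order — the valid-size convention when no direction is pre-specified;
    ``"observed"`` tests larger > smaller (anti-conservative, for ranking
    only). BH is applied separately within each comparison family. Returns a
    pandas DataFrame.
    """
    import pandas as pd

    if direction not in ("canonical", "observed"):
        raise ValueError("direction must be 'canonical' or 'observed'")
    rows = []
    for comp in ("main", "alt"):
        if comparisons != "both" and comparisons != comp:
            continue
        recs = []
        for br in branches:
            if comp == "main":
                a, b = br.n1, max(br.n2, br.n3)
            elif direction == "canonical":
                a, b = br.n2, br.n3
            else:
                a, b = max(br.n2, br.n3), min(br.n2, br.n3)
            recs.append((br.branch, comp, a, b, asymmetry_pvalue(a, b)))
        ps = [r[4] for r in recs if r[4] is not None]
        adj_iter = iter(benjamini_hochberg(ps))
        for branch, c, a, b, p in recs:
            rows.append(
                {
                    "branch": branch,
                    "comparison": c,
                    "a": a,
                    "b": b,
                    "p_raw": p,
                    "p_bh": next(adj_iter) if p is not None else None,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species-tree estimation
# ---------------------------------------------------------------------------

def topology_key(tree: PhyloTree) -> str:
    """Canonical (child-sorted, length-free) newick used for tie-breaking."""

    def rec(node: PhyloNode) -> str:
        if node.is_leaf:
            return node.label
        return "(" + ",".join(sorted(rec(c) for c in node.children)) + ")"

    return rec(tree.root) + ";"


def _tree_from_splits(taxa: list[str], splits: list[frozenset]) -> PhyloTree:
    """Build a rooted tree from a laminar family of clusters (sides without
    the reference taxon)."""
    ref = min(taxa)
    clusters = sorted(set(splits), key=lambda s: (-len(s), sorted(s)))
    root = PhyloNode()
    nodes: list[tuple[frozenset, PhyloNode]] = [(frozenset(taxa), root)]
    for cl in clusters:
        node = PhyloNode(length=1.0)
        parent = None
        for cand, pn in nodes:
            if cl < cand and (parent is None or cand < parent[0]):
                parent = (cand, pn)
        parent[1].add_child(node)
        nodes.append((cl, node))
    for t in taxa:
        leaf = PhyloNode(label=t, length=1.0)
        best = None
        for cand, pn in nodes:
            if t in cand and (best is None or cand < best[0]):
                best = (cand, pn)
        best[1].add_child(leaf)
    return PhyloTree(root)


def _compatible(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    return not (a & b) or a <= b or b <= a or (a | b) == universe


def _resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Deterministically resolve polytomies by pairing the two children with
    the smallest descendant labels, repeatedly."""
    t = tree.copy()
    clades = t.clades()

    def smallest(node: PhyloNode) -> str:
        return min(clades[node])

    for node in list(t.preorder()):
        while len(node.children) > (3 if node is t.root else 2):
            kids = sorted(node.children, key=smallest)
            a, b = kids[0], kids[1]
            joined = PhyloNode(length=1.0)
            node.children.remove(a)
            node.children.remove(b)
            joined.add_child(a)
            joined.add_child(b)
            node.add_child(joined)
            clades[joined] = clades[a] | clades[b]
    return t


def _nni_neighbours(tree: PhyloTree):
    """All NNI rearrangements across internal edges (copies)."""
    out = []
    base = tree
    internal = base.internal_edges()
    for e_idx in range(len(internal)):
        for variant in range(2):
            t = base.copy()
            internals = t.internal_edges()
            node = internals[e_idx]
            parent = node.parent
            siblings = [c for c in parent.children if c is not node]
            if not siblings or len(node.children) < 2:
                continue
            s = siblings[0]
            x = node.children[variant % len(node.children)]
            pi = parent.children.index(s)
            ni = node.children.index(x)
            parent.children[pi], node.children[ni] = x, s
            x.parent, s.parent = parent, node
            out.append(t)
    return out


def enumerate_unrooted_topologies(taxa: Sequence[str]):
    """All distinct unrooted topologies on ``taxa`` (deterministic order)."""
    taxa = sorted(taxa)

    def rec(ts):
        if len(ts) == 3:
            root = PhyloNode()
            for t in ts:
                root.add_child(PhyloNode(label=t))
            yield PhyloTree(root)
            return
        for sub in rec(ts[:-1]):
            edges = [n for n in sub.preorder() if n is not sub.root]
            for i in range(len(edges)):
                t2 = sub.copy()
                e = [n for n in t2.preorder() if n is not t2.root][i]
                join = PhyloNode()
                parent = e.parent
                idx = parent.children.index(e)
                parent.children[idx] = join
                join.parent = parent
                join.add_child(e)
                join.add_child(PhyloNode(label=ts[-1]))
                yield t2

    seen = set()
    for t in rec(taxa):
        key = topology_key(t)
        if key not in seen:
            seen.add(key)
            yield t


def estimate_species_tree(
    gene_trees: Sequence[PhyloTree],
    labeler: QuartetLabeler | None = None,
    exact_below: int = 8,
) -> PhyloTree:
    """Maximum-quartet-score species tree, exact at desk scale.

    For fewer than ``exact_below`` taxa the score is maximized by exhaustive
    enumeration of unrooted topologies (105 for six taxa, 945 for seven),
    which is both cheaper and guaranteed optimal. Beyond that, a greedy
    consensus of gene-tree bipartitions (frequency-ordered, compatibility-
    checked) seeds best-improvement NNI hill-climbing to a local optimum.
    NNI alone can strand in local optima on weak-signal data, which is why
    the exact path takes over where enumeration is affordable. Deterministic
    throughout: ties break on the lexicographically smallest canonical
    newick.
    """
    if not gene_trees:
        raise ValueError("empty gene-tree set")
    taxa_sets = [gt.taxa for gt in gene_trees]
    universe = frozenset().union(*taxa_sets)
    if len(universe) < 4:
        raise ValueError("fewer than 4 taxa across gene trees")
    # every pair of taxa must co-occur in some gene tree
    taxa_list = sorted(universe)
    co = {t: set() for t in taxa_list}
    for ts in taxa_sets:
        for t in ts:
            co[t] |= ts
    for i, t1 in enumerate(taxa_list):
        for t2 in taxa_list[i + 1 :]:
            if t2 not in co[t1]:
                raise ValueError(f"taxa never co-occur in any gene tree: {t1!r}, {t2!r}")

    if labeler is None:
        labeler = QuartetLabeler(gene_trees, universe)

    if len(universe) < exact_below:
        best = None
        for cand in enumerate_unrooted_topologies(taxa_list):
            sc, _ = labeler.score(cand)
            key = topology_key(cand)
            if (
                best is None
                or sc > best[0] + 1e-9
                or (abs(sc - best[0]) <= 1e-9 and key < best[1])
            ):
                best = (sc, key, cand)
        return best[2]

    # greedy consensus over complete gene trees (bipartitions of partial trees
    # are not bipartitions of the full taxon set)
    ref = min(universe)
    counts: dict[frozenset, int] = {}
    for gt in gene_trees:
        if gt.taxa != universe:
            continue
        for bip in gt.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    accepted: list[frozenset] = []
    for bip in sorted(counts, key=lambda b: (-counts[b], sorted(b))):
        side = bip if ref not in bip else universe - bip
        if all(_compatible(side, other, universe) for other in accepted):
            accepted.append(side)
    start = _tree_from_splits(taxa_list, accepted)
    start = _resolve_polytomies(start)

    current = start
    current_score, _ = labeler.score(current)
    while True:
        best = None
        for nb in _nni_neighbours(current):
            sc, _ = labeler.score(nb)
            if sc > current_score + 1e-9:
                key = topology_key(nb)
                if best is None or sc > best[0] + 1e-9 or (abs(sc - best[0]) <= 1e-9 and key < best[1]):
                    best = (sc, key, nb)
        if best is None:
            return current
        current_score, _, current = best


def multilocus_bootstrap(
    gene_trees: Sequence[PhyloTree],
    n_reps: int,
    estimator: Callable[[Sequence[PhyloTree]], PhyloTree] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    reference: PhyloTree | None = None,
) -> tuple[dict[frozenset, float], int]:
    """Gene-only multilocus bootstrap: resample loci with replacement,
    re-estimate the species tree, and report per-branch support as the
    fraction of successful replicates containing each reference bipartition.

    Returns (support by bipartition, number of failed replicates).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if estimator is None:
        estimator = estimate_species_tree
    if reference is None:
        reference = estimator(gene_trees)
    rng = np.random.default_rng(seed)
    ref_bips = reference.bipartitions()
    hits = {b: 0 for b in ref_bips}
    failed = 0
    n = len(gene_trees)
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        sample = [gene_trees[i] for i in idx]
        try:
            est = estimator(sample)
        except Exception:
            failed += 1
            continue
        est_bips = est.bipartitions()
        for b in ref_bips:
            if b in est_bips:
                hits[b] += 1
    ok = n_reps - failed
    support = {b: (hits[b] / ok if ok else math.nan) for b in ref_bips}
    return support, failed
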