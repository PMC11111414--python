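"""Subsampling experiment designs: locus-quantity curves, clade-recovery
difficulty classes, per-group taxon reduction with quartet rescoring, and
between-data-type tree variability.

All designs sample without replacement within a replicate (the
with-replacement multilocus bootstrap lives in the quartet module) and are
fully reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quartets import QuartetSupport, branch_quartet_frequencies, estimate_species_tree
from .tree import PhyloTree, rf_distance

__all__ = [
    "SubsampleDesign",
    "run_locus_subsampling",
    "CladeRecovery",
    "clade_recovery",
    "taxon_subsample_rescore",
    "pairwise_tree_variability",
]


@dataclass
class SubsampleDesign:
    sizes: Sequence[int]
    n_replicates: int = 50
    seed: int | None = None
    estimator: Callable[[Sequence[PhyloTree]], PhyloTree] | None = None
    reference: PhyloTree | None = None
    support_threshold: float = 0.95

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def run_locus_subsampling(
    gene_trees: Sequence[PhyloTree], design: SubsampleDesign
) -> tuple[pd.DataFrame, dict]:
    """Estimate species trees from random locus subsets of increasing size.

    For each size and replicate: sample loci without replacement, run the
    estimator, and record the RF distance to the reference (the estimator on
    all loci unless supplied) plus the estimated tree's bipartitions. Returns
    a tidy table and a dict of (size, replicate) -> estimated tree.
    """
    n = len(gene_trees)
    for s in design.sizes:
        if s > n:
            raise ValueError(f"subset size {s} exceeds available loci ({n})")
    estimator = design.estimator or estimate_species_tree
    reference = design.reference or estimator(gene_trees)
    ss = np.random.SeedSequence(design.seed)
    rows = []
    trees: dict[tuple[int, int], PhyloTree] = {}
    streams = iter(ss.spawn(len(design.sizes) * design.n_replicates))
    for size in design.sizes:
        for rep in range(design.n_replicates):
            rng = np.random.default_rng(next(streams))
            idx = rng.choice(n, size=size, replace=False)
            sample = [gene_trees[i] for i in idx]
            est = estimator(sample)
            trees[(size, rep)] = est
            supports = branch_supports(est, sample)
            prop_high = (
                float(np.mean([pp >= design.support_threshold for pp in supports]))
                if supports
                else math.nan
            )
            rows.append(
                {
                    "size": size,
                    "replicate": rep,
                    "rf_to_reference": rf_distance(est, reference),
                    "prop_high_support": prop_high,
                }
            )
    return pd.DataFrame(rows), {"reference": reference, "trees": trees}


def branch_supports(tree: PhyloTree, gene_trees: Sequence[PhyloTree]) -> list[float]:
    """Local posterior probability of the tree's own resolution per branch."""
    from .quartets import local_posterior

    return [
        local_posterior(qs)[0]
        for qs in branch_quartet_frequencies(tree, gene_trees)
    ]


@dataclass
class CladeRecovery:
    clade: frozenset
    recovery: dict[int, float]  # size -> fraction of replicates containing it
    n_sister_groups: dict[int, int]
    difficulty: str  # "easy" | "needs_<N>" | "unresolved"


def _sister_of(tree: PhyloTree, clade: frozenset) -> frozenset | None:
    clades = tree.clades()
    for node, c in clades.items():
        if c == clade and node.parent is not None:
            sibs = clades[node.parent] - c
            return frozenset(sibs)
    return None


def clade_recovery(
    trees: Mapping[tuple[int, int], PhyloTree],
    reference_clades: Sequence[frozenset],
    consistency: float = 1.0,
) -> list[CladeRecovery]:
    """Recovery fraction, sister-group diversity and difficulty class per clade.

    ``easy``: recovered in a ``consistency`` fraction of replicates already
    at the smallest size; ``needs_N``: the smallest size from which recovery
    stays at or above ``consistency``; ``unresolved``: never reaches it at
    the largest size.
    """
    sizes = sorted({s for s, _ in trees})
    out = []
    for clade in reference_clades:
        rec: dict[int, float] = {}
        sisters: dict[int, set] = {}
        for size in sizes:
            reps = [t for (s, _), t in trees.items() if s == size]
            hit = 0
            sis = set()
            for t in reps:
                tclades = set(t.clades().values())
                if clade in tclades:
                    hit += 1
                s_grp = _sister_of(t, clade)
                if s_grp:
                    sis.add(s_grp)
            rec[size] = hit / len(reps) if reps else math.nan
            sisters[size] = sis
        consistent_from = None
        for size in sizes:
            if all(rec[s] >= consistency for s in sizes if s >= size):
                consistent_from = size
                break
        if consistent_from is None:
            difficulty = "unresolved"
        elif consistent_from == sizes[0]:
            difficulty = "easy"
        else:
            difficulty = f"needs_{consistent_from}"
        out.append(
            CladeRecovery(
                clade=clade,
                recovery=rec,
                n_sister_groups={s: len(v) for s, v in sisters.items()},
                difficulty=difficulty,
            )
        )
    return out


def taxon_subsample_rescore(
    gene_trees: Sequence[PhyloTree],
    species_tree: PhyloTree,
    groups: Mapping[str, str],
    per_group_sizes: Sequence[int],
    seed=None,
    n_replicates: int = 1,
    focal_branches: Sequence[frozenset] | None = None,
) -> pd.DataFrame:
    """Quartet frequencies on the species tree under reduced per-group sampling.

    For each requested per-group size and replicate, that many taxa are
    sampled from every group (all retained when a group is smaller), gene
    trees are restricted to the selection, and per-branch quartet
    frequencies of the (restricted) species tree are recomputed. Returns a
    tidy table of branch frequencies by size and replicate.
    """
    all_taxa = species_tree.taxa
    unmapped = all_taxa - set(groups)
    if unmapped:
        raise ValueError(f"taxa without group assignment: {sorted(unmapped)[:5]}")
    by_group: dict[str, list[str]] = {}
    for t in sorted(all_taxa):
        by_group.setdefault(groups[t], []).append(t)
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(per_group_sizes) * n_replicates))
    rows = []
    for size in per_group_sizes:
        for rep in range(n_replicates):
            rng = np.random.default_rng(next(streams))
            selected: set[str] = set()
            for g in sorted(by_group):
                members = by_group[g]
                if len(members) <= size:
                    selected.update(members)
                else:
                    pick = rng.choice(len(members), size=size, replace=False)
                    selected.update(members[i] for i in pick)
            if len(selected) < 4:
                continue
            sp_r = species_tree.restrict(selected)
            gts_r = []
            for gt in gene_trees:
                shared = gt.taxa & selected
                if len(shared) >= 4:
                    gts_r.append(gt.restrict(shared))
            if not gts_r:
                continue
            for qs in branch_quartet_frequencies(sp_r, gts_r):
                if focal_branches is not None and not any(
                    qs.branch == fb & frozenset(selected) or qs.branch == fb
                    for fb in focal_branches
                ):
                    continue
                q1, q2, q3 = qs.frequencies
                rows.append(
                    {
                        "per_group_size": size,
                        "replicate": rep,
                        "branch": qs.branch,
                        "n_taxa": len(selected),
                        "effective_n": qs.effective_n,
                        "q1": q1,
                        "q2": q2,
                        "q3": q3,
                    }
                )
    return pd.DataFrame(rows)


def pairwise_tree_variability(
    groups: Mapping[str, Sequence[PhyloTree]]
) -> pd.DataFrame:
    """Mean pairwise RF within and between groups of estimated trees.

    Off-diagonal cells average RF over all cross pairs; diagonal cells over
    all within-group pairs (missing when a group has fewer than two trees).
    """
    names = sorted(groups)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b:
                ts = groups[a]
                pairs = [
                    rf_distance(ts[x], ts[y])
                    for x in range(len(ts))
                    for y in range(x + 1, len(ts))
                ]
            else:
                pairs = [rf_distance(ta, tb) for ta in groups[a] for tb in groups[b]]
            val = float(np.mean(pairs)) if pairs else math.nan
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat
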