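"""Per-branch substitution rates from concordant gene-tree branches, effective
population size from dual (time vs coalescent) branch lengths, and 1-Ma
binning of branch quantities through time.

A species-tree branch of duration T Ma and coalescent length d has
time-to-coalescent ratio rho = T/d Ma per coalescent unit, which equals
2 * generation time * Ne (in years); given a generation time g this yields
Ne = T_years / (2 g d). Summary methods underestimate d under gene-tree
error, so like-for-like comparisons between branches are meaningful while
absolute Ne values are not claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "BranchTrajectoryPoint",
    "concordant_branch_rates",
    "ne_ratio",
    "bin_through_time",
    "branch_ages",
]


@dataclass
class BranchTrajectoryPoint:
    """One species-tree branch as a time-localized observation."""

    branch: frozenset
    start_age: float  # older end, Ma
    end_age: float  # younger end, Ma
    value: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_age + self.end_age)

    @property
    def duration(self) -> float:
        return self.start_age - self.end_age


def branch_ages(time_tree: PhyloTree, rel_tol: float = 1e-6) -> dict[frozenset, tuple[float, float]]:
    """(older age, younger age) in Ma for every non-root branch, keyed by the
    clade below it; requires an ultrametric tree."""
    depths = time_tree.depths()
    tips = time_tree.leaves()
    max_d = max(depths[t] for t in tips)
    for t in tips:
        if abs(max_d - depths[t]) > rel_tol * max(max_d, 1.0):
            raise ValueError("time tree is not ultrametric")
    clades = time_tree.clades()
    out = {}
    for node, clade in clades.items():
        if node is time_tree.root:
            continue
        out[clade] = (max_d - depths[node.parent], max_d - depths[node])
    return out


def _restricted_bipartitions(
    species_clades: Mapping[frozenset, tuple[float, float]], gt_taxa: frozenset
) -> dict[frozenset, frozenset]:
    """Map species-tree branch -> its bipartition restricted to the gene tree's
    taxa (canonical side), dropping branches whose restriction is trivial or
    ambiguous (several species branches collapsing onto one restricted split)."""
    if len(gt_taxa) < 4:
        return {}
    ref = min(gt_taxa)
    restricted: dict[frozenset, list[frozenset]] = {}
    all_taxa = frozenset().union(*species_clades) if species_clades else frozenset()
    for clade in species_clades:
        side = clade & gt_taxa
        other = gt_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = other if ref in side else side
        restricted.setdefault(key, []).append(clade)
    return {
        clades[0]: key for key, clades in restricted.items() if len(clades) == 1
    }


def concordant_branch_rates(
    gene_trees: Sequence[PhyloTree],
    time_tree: PhyloTree,
) -> pd.DataFrame:
    """Per-branch substitution-rate summaries from concordant gene-tree branches.

    A gene-tree branch is concordant with a species-tree branch when their
    bipartitions agree after restricting the species tree to the gene tree's
    taxa; each concordant branch length (subs/site) divided by the branch
    duration (Ma) contributes one per-locus rate. A species branch whose
    restriction collides with another's is skipped for that locus
    (conservative). Returns one row per species-tree branch with mean,
    median and contributing-locus count.
    """
    ages = branch_ages(time_tree)
    contributions: dict[frozenset, list[float]] = {c: [] for c in ages}
    for gt in gene_trees:
        gt_taxa = gt.taxa
        mapping = _restricted_bipartitions(ages, gt_taxa)
        if not mapping:
            continue
        # gene-tree bipartitions (canonical wrt the gene tree's taxa)
        ref = min(gt_taxa)
        clades = gt.clades()
        gt_bips: dict[frozenset, float] = {}
        for node, clade in clades.items():
            if node is gt.root or node.is_leaf:
                continue
            if not (2 <= len(clade) <= len(gt_taxa) - 2):
                continue
            key = gt_taxa - clade if ref in clade else clade
            gt_bips[key] = node.length or 0.0
        inverse = {bip: sp for sp, bip in mapping.items()}
        for bip, length in gt_bips.items():
            sp = inverse.get(bip)
            if sp is None:
                continue
            older, younger = ages[sp]
            T = older - younger
            if T > 0:
                contributions[sp].append(length / T)
    rows = []
    for clade, vals in contributions.items():
        older, younger = ages[clade]
        rows.append(
            {
                "branch": clade,
                "start_age": older,
                "end_age": younger,
                "duration": older - younger,
                "n_loci": len(vals),
                "rate_mean": float(np.mean(vals)) if vals else math.nan,
                "rate_median": float(np.median(vals)) if vals else math.nan,
            }
        )
    return pd.DataFrame(rows)


def ne_ratio(
    time_tree: PhyloTree,
    coalescent_tree: PhyloTree,
    generation_time: float | None = None,
    saturated: Mapping[frozenset, bool] | None = None,
) -> pd.DataFrame:
    """Per-branch time/coalescent ratio rho (Ma per coalescent unit) and Ne.

    ``time_tree`` (Ma, ultrametric) and ``coalescent_tree`` must share the
    topology; rho = T/d, and with a generation time g (years),
    Ne = T_years / (2 g d). Branches with d flagged saturated (at the
    inversion cap) report Ne as missing. Without g the rho column is still
    the 2*g*Ne-scaled quantity useful for branch-to-branch comparison.
    """
    ages = branch_ages(time_tree)
    ct_clades = {
        clade: (node.length or 0.0)
        for node, clade in coalescent_tree.clades().items()
        if node is not coalescent_tree.root
    }
    if set(ages) != set(ct_clades):
        diff = sorted(
            set(map(tuple, map(sorted, set(ages) ^ set(ct_clades))))
        )[0]
        raise ValueError(f"topology mismatch between trees at bipartition {diff}")
    saturated = saturated or {}
    rows = []
    for clade, (older, younger) in ages.items():
        T = older - younger
        d = ct_clades[clade]
        rho = T / d if d > 0 else math.nan
        ne = math.nan
        if generation_time is not None and d > 0 and not saturated.get(clade, False):
            ne = (T * 1.0e6) / (2.0 * generation_time * d)
        rows.append(
            {
                "branch": clade,
                "start_age": older,
                "end_age": younger,
                "duration": T,
                "d": d,
                "rho": rho,
                "ne": ne,
                "saturated": bool(saturated.get(clade, False)),
            }
        )
    return pd.DataFrame(rows)


def bin_through_time(
    points: Sequence[BranchTrajectoryPoint],
    bin_width: float = 1.0,
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Average branch values in fixed-width time bins (ages in Ma).

    ``midpoint`` assigns each branch to the single bin holding its midpoint
    age; ``overlap-weighted`` spreads each branch over every bin it spans,
    weighting by overlap duration. Empty bins are reported with a missing
    (NaN) mean, never zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mode not in ("midpoint", "overlap-weighted"):
        raise ValueError("mode must be 'midpoint' or 'overlap-weighted'")
    if not points:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean", "n_branches"])
    max_age = max(p.start_age for p in points)
    n_bins = max(1, int(math.ceil(max_age / bin_width - 1e-12)))
    sums = np.zeros(n_bins)
    weights = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for p in points:
        if mode == "midpoint":
            b = min(int(p.midpoint / bin_width), n_bins - 1)
            sums[b] += p.value
            weights[b] += 1.0
            counts[b] += 1
        else:
            for b in range(n_bins):
                lo, hi = b * bin_width, (b + 1) * bin_width
                ov = min(hi, p.start_age) - max(lo, p.end_age)
                if ov > 0:
                    sums[b] += p.value * ov
                    weights[b] += ov
                    counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(weights > 0, sums / np.where(weights, weights, 1.0), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": (np.arange(n_bins) + 1) * bin_width,
            "mean": means,
            "n_branches": counts,
        }
    )
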