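"""Per-locus alignment diagnostics: summary metrics, the ΔGC convergence
statistic, parametric-bootstrap stationarity and saturation screens, and the
metric-quantile subset analysis.

Both screens are valid tests by construction: the null distribution of the
statistic is generated by simulating alignments under the (stationary)
supplied model on the supplied tree, and p is the exceedance fraction with
the add-one correction p = (1 + #{sim >= obs}) / (n_sim + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqsim import BASES, SubstitutionModel, simulate_alignment
from .tree import PhyloTree, rf_distance

__all__ = [
    "LocusStats",
    "alignment_metrics",
    "delta_gc",
    "composition_chi2",
    "pi_site_entropy",
    "stationarity_test",
    "saturation_test",
    "simulate_null_statistics",
    "quantile_subset_analysis",
]


def _to_matrix(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    names = list(alignment)
    lengths = {len(alignment[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: unequal sequence lengths")
    mat = np.array([list(alignment[n]) for n in names])
    return names, mat


@dataclass
class LocusStats:
    length: int
    coverage: float
    n_parsimony_informative: int
    prop_parsimony_informative: float
    gc_per_taxon: dict[str, float]
    gc_mean: float
    gc_sd: float


def _state_counts(mat: np.ndarray) -> np.ndarray:
    """(n_seq-agnostic) per-column counts of A, C, G, T; gaps/ambiguities excluded."""
    return np.stack([(mat == b).sum(axis=0) for b in BASES], axis=1)


def alignment_metrics(alignment: Mapping[str, str]) -> LocusStats:
    """Length, coverage, parsimony-informative sites and GC summaries.

    A column is parsimony-informative when at least two states are each
    present in at least two sequences (A/C/G/T only). Coverage is the mean
    fraction of unambiguous bases per sequence; GC is computed per taxon
    over its unambiguous A/C/G/T characters.
    """
    names, mat = _to_matrix(alignment)
    L = mat.shape[1]
    counts = _state_counts(mat)
    pi = (counts >= 2).sum(axis=1) >= 2
    n_pi = int(pi.sum())

    gc: dict[str, float] = {}
    for i, name in enumerate(names):
        row = mat[i]
        n_gc = int(((row == "G") | (row == "C")).sum())
        n_at = int(((row == "A") | (row == "T")).sum())
        tot = n_gc + n_at
        gc[name] = n_gc / tot if tot else math.nan
    vals = np.array([v for v in gc.values() if not math.isnan(v)])
    acgt = sum((mat == b).sum() for b in BASES)
    return LocusStats(
        length=L,
        coverage=acgt / mat.size,
        n_parsimony_informative=n_pi,
        prop_parsimony_informative=n_pi / L,
        gc_per_taxon=gc,
        gc_mean=float(vals.mean()) if len(vals) else math.nan,
        gc_sd=float(vals.std()) if len(vals) else math.nan,
    )


def delta_gc(
    gc: Mapping[str, float],
    focal_a: Sequence[str],
    focal_b: Sequence[str],
    background: Sequence[str],
) -> float:
    """Signed GC-similarity contrast between a focal pair of groups and the rest.

    ΔGC = mean |GC difference| over (focal member, background member) pairs
    minus the mean over (focal_a, focal_b) cross pairs. Zero in expectation
    under stationary evolution; positive when the two focal groups resemble
    each other more than they resemble the background — the direction of
    composition-driven support for uniting them.
    """
    fa, fb, bg = list(focal_a), list(focal_b), list(background)
    if not fa or not fb or not bg:
        raise ValueError("focal and background sets must be nonempty")
    if set(fa) & set(fb):
        raise ValueError("focal sets must be disjoint")
    cross = [abs(gc[f] - gc[b]) for f in fa + fb for b in bg]
    within = [abs(gc[a] - gc[b]) for a in fa for b in fb]
    return float(np.mean(cross) - np.mean(within))


# ---------------------------------------------------------------------------
# model-adequacy screens
# ---------------------------------------------------------------------------

def composition_chi2(alignment: Mapping[str, str]) -> float:
    """Base-composition heterogeneity across taxa (Pearson chi-square on the
    taxa x bases table; gaps and ambiguities excluded)."""
    _, mat = _to_matrix(alignment)
    table = np.stack([[(row == b).sum() for b in BASES] for row in mat]).astype(float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    grand = table.sum()
    if grand == 0:
        return 0.0
    expected = rows * cols / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(contrib.sum())


def pi_site_entropy(alignment: Mapping[str, str]) -> float | None:
    """Mean column entropy (bits, gaps excluded) over parsimony-informative sites."""
    _, mat = _to_matrix(alignment)
    counts = _state_counts(mat)
    pi_cols = (counts >= 2).sum(axis=1) >= 2
    if not pi_cols.any():
        return None
    sub = counts[pi_cols].astype(float)
    tot = sub.sum(axis=1, keepdims=True)
    p = np.where(tot > 0, sub / np.where(tot, tot, 1.0), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    return float(ent.mean())


def simulate_null_statistics(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    n_sim: int,
    seed,
    statistic: Callable[[Mapping[str, str]], float | None],
) -> np.ndarray:
    """Null distribution of a statistic under the stationary model on ``tree``.

    Exposed so a common null can be reused across loci sharing the same
    model and tree (the calibration setting).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    stats = []
    for child in ss.spawn(n_sim):
        sim = simulate_alignment(tree, model, n_sites, seed=child)
        val = statistic(sim)
        stats.append(math.nan if val is None else val)
    return np.asarray(stats, dtype=float)


@dataclass
class ScreenResult:
    statistic: float | None
    p_value: float | None
    high_risk: bool
    n_sim: int


def _screen(
    alignment, tree, model, n_sim, seed, statistic, null_stats, risk_count
) -> ScreenResult:
    if null_stats is None:
        if n_sim < 19:
            raise ValueError("n_sim must be >= 19 for usable p-value resolution")
        _, mat = _to_matrix(alignment)
        null_stats = simulate_null_statistics(
            tree, model, mat.shape[1], n_sim, seed, statistic
        )
    null_stats = np.asarray(null_stats, dtype=float)
    obs = statistic(alignment)
    if obs is None:
        return ScreenResult(None, None, False, len(null_stats))
    valid = null_stats[~np.isnan(null_stats)]
    n_ge = int((valid >= obs).sum())
    p = (1 + n_ge) / (len(valid) + 1)
    return ScreenResult(obs, p, n_ge <= risk_count, len(valid))


def stationarity_test(
    alignment: Mapping[str, str],
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sim: int = 99,
    seed=None,
    null_stats: np.ndarray | None = None,
    risk_count: int = 0,
) -> ScreenResult:
    """Parametric-bootstrap screen for nonstationary base composition.

    The observed across-taxa composition chi-square is compared with its
    distribution under ``n_sim`` stationary simulations on the same tree and
    model; ``high_risk`` marks loci whose statistic exceeds all but at most
    ``risk_count`` simulated values (default: all of them).
    """
    return _screen(alignment, tree, model, n_sim, seed, composition_chi2, null_stats, risk_count)


def saturation_test(
    alignment: Mapping[str, str],
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sim: int = 99,
    seed=None,
    null_stats: np.ndarray | None = None,
    risk_count: int = 0,
) -> ScreenResult:
    """Entropy-based substitution-saturation screen on parsimony-informative sites.

    Mean PI-column entropy beyond the parametric null indicates multiple
    hits eroding signal; a locus is flagged high-risk when the observed
    value exceeds all (but ``risk_count``) simulated values.
    """
    return _screen(alignment, tree, model, n_sim, seed, pi_site_entropy, null_stats, risk_count)


# ---------------------------------------------------------------------------
# metric-quantile subset analysis
# ---------------------------------------------------------------------------

def quantile_subset_analysis(
    gene_trees: Sequence[PhyloTree],
    metric_values: Sequence[float],
    reference_tree: PhyloTree,
    estimator: Callable[[Sequence[PhyloTree]], PhyloTree],
    n_quantiles: int = 4,
) -> pd.DataFrame:
    """Split loci into rank quantiles of a metric, re-estimate per quantile,
    and report the RF distance of each quantile tree to the reference.

    Quantile boundaries are by rank with stable (input-order) tie handling;
    group sizes differ by at most one locus.
    """
    if len(gene_trees) != len(metric_values):
        raise ValueError("metric must be defined for every locus")
    if n_quantiles > len(gene_trees):
        raise ValueError("more quantiles than loci")
    order = np.argsort(np.asarray(metric_values, dtype=float), kind="stable")
    groups = np.array_split(order, n_quantiles)
    rows = []
    for qi, idx in enumerate(groups):
        subset = [gene_trees[i] for i in idx]
        est = estimator(subset)
        common = est.taxa & reference_tree.taxa
        rf = rf_distance(
            est.restrict(common) if est.taxa != common else est,
            reference_tree.restrict(common) if reference_tree.taxa != common else reference_tree,
        )
        vals = [metric_values[i] for i in idx]
        rows.append(
            {
                "quantile": qi + 1,
                "n_loci": len(idx),
                "metric_min": min(vals),
                "metric_max": max(vals),
                "rf_to_reference": rf,
            }
        )
    return pd.DataFrame(rows)
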