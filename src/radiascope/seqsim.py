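"""Sequence simulation under a general time-reversible model with gamma rate
heterogeneity and optional lineage-specific base-composition shifts.

The nonstationary mode switches the equilibrium frequencies (a GC target,
with within-class ratios preserved) on designated subtrees, which is the
composition-shift alternative the stationarity screen is calibrated
against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .tree import PhyloNode, PhyloTree

__all__ = ["SubstitutionModel", "simulate_alignment", "jc69", "write_fasta", "read_fasta"]

BASES = "ACGT"


@dataclass
class SubstitutionModel:
    """GTR exchangeabilities + base frequencies + discrete-gamma heterogeneity.

    ``exchangeabilities`` are the six upper-triangle terms in the order
    AC, AG, AT, CG, CT, GT. ``gamma_shape`` of None disables rate
    heterogeneity; otherwise ``n_categories`` equal-probability categories
    with median rates (normalized to mean 1) are used.
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if s.shape != (6,) or (s <= 0).any():
            raise ValueError("need 6 positive exchangeabilities (AC, AG, AT, CG, CT, GT)")
        if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self, base_freqs=None) -> np.ndarray:
        """Q with mean substitution rate scaled to 1."""
        pi = np.asarray(base_freqs if base_freqs is not None else self.base_freqs, float)
        s = np.zeros((4, 4))
        s[np.triu_indices(4, 1)] = self.exchangeabilities
        s += s.T
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        return Q / scale

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        k = self.n_categories
        a = self.gamma_shape
        probs = (2 * np.arange(k) + 1) / (2 * k)
        rates = gamma_dist.ppf(probs, a, scale=1.0 / a)
        return rates / rates.mean()

    def with_gc(self, gc: float) -> "SubstitutionModel":
        """Same exchangeabilities with equilibrium GC moved to ``gc``
        (within-class A:T and C:G ratios preserved)."""
        if not 0.0 < gc < 1.0:
            raise ValueError("gc target must be in (0, 1)")
        a, c, g, t = self.base_freqs
        at, cg = a + t, c + g
        new = (a / at * (1 - gc), c / cg * gc, g / cg * gc, t / at * (1 - gc))
        return replace(self, base_freqs=new)


def jc69(gamma_shape: float | None = None) -> SubstitutionModel:
    return SubstitutionModel(gamma_shape=gamma_shape)


def _edge_freqs(
    clade: frozenset, model: SubstitutionModel, gc_targets: dict[frozenset, float]
) -> SubstitutionModel:
    for target_clade, gc in gc_targets.items():
        if clade <= target_clade:
            return model.with_gc(gc)
    return model


def simulate_alignment(
    gene_tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.SeedSequence | None = None,
    gc_targets: dict[frozenset, float] | None = None,
) -> dict[str, str]:
    """Simulate one gapless alignment along ``gene_tree`` (subs/site lengths).

    ``gc_targets`` maps clades (frozensets of taxon labels) to GC targets;
    every edge whose subtree lies inside a target clade evolves under the
    shifted equilibrium (the composition-shift nonstationary model). Returns
    taxon -> sequence.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    gc_targets = {frozenset(k) if not isinstance(k, frozenset) else k: v
                  for k, v in (gc_targets or {}).items()}
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    cats = rng.integers(0, len(rates), size=n_sites)
    clades = gene_tree.clades()

    root_pi = np.asarray(model.base_freqs)
    root_states = rng.choice(4, size=n_sites, p=root_pi)

    eig_cache: dict[tuple, tuple] = {}

    def transition(edge_model: SubstitutionModel, t: float) -> np.ndarray:
        key = edge_model.base_freqs
        if key not in eig_cache:
            evals, evecs = np.linalg.eig(edge_model.rate_matrix())
            eig_cache[key] = (evals.real, evecs.real, np.linalg.inv(evecs).real)
        evals, evecs, inv = eig_cache[key]
        P = (evecs * np.exp(evals * t)) @ inv
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    states: dict[int, np.ndarray] = {id(gene_tree.root): root_states}
    out: dict[str, str] = {}
    base_arr = np.array(list(BASES))
    for node in gene_tree.preorder():
        if node is gene_tree.root:
            parent_states = root_states
        else:
            parent_states = states[id(node.parent)]
            edge_model = _edge_freqs(clades[node], model, gc_targets)
            t = node.length or 0.0
            child = np.empty(n_sites, dtype=np.int64)
            if t == 0.0:
                child[:] = parent_states
            else:
                for c, r in enumerate(rates):
                    idx = np.nonzero(cats == c)[0]
                    if not len(idx):
                        continue
                    cum = np.cumsum(transition(edge_model, t * r), axis=1)
                    u = rng.random(len(idx))
                    child[idx] = (cum[parent_states[idx]] < u[:, None]).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf:
            out[node.label] = "".join(base_arr[states[id(node)]])
    return out


def write_fasta(alignment: dict[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in alignment.items())


def read_fasta(text: str) -> dict[str, str]:
    from io import StringIO

    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(StringIO(text), "fasta")}
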