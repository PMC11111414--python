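"""Phylogenetic signal machinery: Brownian-motion trait simulation, Pagel's
lambda by maximum likelihood, PGLS residuals (relative brain size), the
taxon-misplacement and convergent-evolution perturbation experiments, and
constant-rate BM ancestral trajectories binned through time.

Pagel's lambda multiplies the off-diagonal entries of the BM covariance
V (shared root-to-MRCA path lengths): V(lambda) = lambda*V + (1-lambda)*
diag(V). lambda = 1 is pure BM; lambda = 0 removes all phylogenetic
covariance. The likelihood is profiled over the ancestral mean and sigma^2,
and the one-dimensional lambda search uses a single symmetric
eigendecomposition so that each likelihood evaluation is O(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .rates import BranchTrajectoryPoint, bin_through_time
from .tree import PhyloNode, PhyloTree

__all__ = [
    "bm_covariance",
    "simulate_bm",
    "simulate_bm_many",
    "SignalFit",
    "PagelLambdaEstimator",
    "pagel_lambda_ml",
    "PGLSResult",
    "pgls_residuals",
    "perturb_misplacement",
    "perturb_convergence",
    "ancestral_bm_states",
    "ancestral_bm_trajectory",
]


def bm_covariance(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Tip labels and the BM covariance matrix of shared path lengths."""
    tips = tree.leaves()
    labels = [t.label for t in tips]
    idx = {t.label: i for i, t in enumerate(tips)}
    n = len(tips)
    depths = tree.depths()
    clades = tree.clades()
    V = np.zeros((n, n))
    for node in tree.postorder():
        if node.is_leaf:
            V[idx[node.label], idx[node.label]] = depths[node]
            continue
        kids = node.children
        for a in range(len(kids)):
            ia = [idx[t] for t in clades[kids[a]]]
            for b in range(a + 1, len(kids)):
                ib = [idx[t] for t in clades[kids[b]]]
                V[np.ix_(ia, ib)] = depths[node]
                V[np.ix_(ib, ia)] = depths[node]
    return labels, V


def _lambda_cov(V: np.ndarray, lam: float) -> np.ndarray:
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def simulate_bm_many(
    tree: PhyloTree,
    sigma2: float,
    n_traits: int,
    lam: float = 1.0,
    seed=None,
    root_state: float = 0.0,
) -> pd.DataFrame:
    """Draw ``n_traits`` independent traits under lambda-scaled BM.

    Returns a DataFrame (taxa rows, trait columns). sigma2 = 0 degenerates
    to all tips equal to the root state.
    """
    if sigma2 < 0 or not 0.0 <= lam <= 1.0:
        raise ValueError("sigma2 must be >= 0 and lambda in [0, 1]")
    labels, V = bm_covariance(tree)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        data = np.full((len(labels), n_traits), root_state)
    else:
        C = np.linalg.cholesky(
            sigma2 * _lambda_cov(V, lam) + 1e-12 * np.eye(len(labels))
        )
        data = root_state + C @ rng.standard_normal((len(labels), n_traits))
    return pd.DataFrame(data, index=labels, columns=[f"trait_{i}" for i in range(n_traits)])


def simulate_bm(
    tree: PhyloTree, sigma2: float, lam: float = 1.0, seed=None, root_state: float = 0.0
) -> dict[str, float]:
    """One lambda-scaled BM trait: taxon -> value."""
    df = simulate_bm_many(tree, sigma2, 1, lam=lam, seed=seed, root_state=root_state)
    return dict(zip(df.index, df.iloc[:, 0]))


@dataclass
class SignalFit:
    lambda_: float | None
    sigma2: float | None
    mu: float | None
    loglik: float | None
    converged: bool
    n: int
    missing_dropped: int = 0


class PagelLambdaEstimator:
    """Reusable ML estimator of Pagel's lambda on one tree.

    The covariance family V(lambda) = D^(1/2) (I + lambda W) D^(1/2) with
    D = diag(V) and W = D^(-1/2) (V - D) D^(-1/2) is diagonalized once;
    every profile-likelihood evaluation is then O(n).
    """

    def __init__(self, tree: PhyloTree):
        self.labels, V = bm_covariance(tree)
        d = np.diag(V)
        if (d <= 0).any():
            raise ValueError("zero-depth tip: tree must have positive root-to-tip lengths")
        self.sqrt_d = np.sqrt(d)
        W = (V - np.diag(d)) / np.outer(self.sqrt_d, self.sqrt_d)
        self.evals, self.evecs = np.linalg.eigh(W)
        self.log_det_d = float(np.log(d).sum())
        self.ones_t = self.evecs.T @ (1.0 / self.sqrt_d)

    def _profile_loglik(self, z: np.ndarray, lam: float) -> tuple[float, float, float]:
        """(loglik, mu_hat, sigma2_hat) at lambda for transformed data z."""
        n = len(z)
        w = 1.0 + lam * self.evals
        o = self.ones_t
        sw = (o * o / w).sum()
        mu = (o * z / w).sum() / sw
        r = z - mu * o
        quad = (r * r / w).sum()
        sigma2 = quad / n
        logdet = self.log_det_d + float(np.log(w).sum())
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return ll, mu, sigma2

    def loglik(self, trait: Mapping[str, float] | Sequence[float], lam: float) -> float:
        z = self._transform(trait)
        return self._profile_loglik(z, lam)[0]

    def _transform(self, trait) -> np.ndarray:
        if isinstance(trait, Mapping):
            x = np.array([trait[t] for t in self.labels], dtype=float)
        else:
            x = np.asarray(trait, dtype=float)
        return self.evecs.T @ (x / self.sqrt_d)

    def fit(self, trait: Mapping[str, float] | Sequence[float], xatol: float = 1e-6) -> SignalFit:
        if isinstance(trait, Mapping):
            vals = np.array([trait[t] for t in self.labels], dtype=float)
        else:
            vals = np.asarray(trait, dtype=float)
        n = len(vals)
        if n < 4:
            raise ValueError("need at least 4 taxa with trait values")
        if np.ptp(vals) == 0:
            return SignalFit(None, None, float(vals[0]), None, False, n)
        z = self.evecs.T @ (vals / self.sqrt_d)
        res = minimize_scalar(
            lambda lam: -self._profile_loglik(z, lam)[0],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": xatol},
        )
        candidates = [0.0, 1.0, float(res.x)]
        best = max(candidates, key=lambda lam: self._profile_loglik(z, lam)[0])
        ll, mu, sigma2 = self._profile_loglik(z, best)
        return SignalFit(best, sigma2, mu, ll, bool(res.success), n)


def pagel_lambda_ml(
    tree: PhyloTree, trait: Mapping[str, float], xatol: float = 1e-6
) -> SignalFit:
    """ML estimate of Pagel's lambda on [0, 1] with profiled mean and sigma^2.

    Taxa missing from ``trait`` (or with non-finite values) are dropped and
    the count recorded; zero trait variance yields a missing (flagged) fit.
    """
    have = {t: v for t, v in trait.items() if v is not None and math.isfinite(v)}
    tree_taxa = tree.taxa
    used = set(have) & tree_taxa
    dropped = len(tree_taxa) - len(used)
    sub = tree.restrict(used) if used != tree_taxa else tree
    est = PagelLambdaEstimator(sub)
    fit = est.fit({t: have[t] for t in used}, xatol=xatol)
    fit.missing_dropped = dropped
    return fit


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSResult:
    intercept: float
    slope: float
    residuals: dict[str, float]
    lambda_: float
    sigma2: float
    loglik: float


def pgls_residuals(
    tree: PhyloTree,
    y: Mapping[str, float],
    x: Mapping[str, float],
    correlation: str = "BM",
) -> PGLSResult:
    """Phylogenetic GLS of y on x; residuals are in y units.

    ``correlation="BM"`` fixes lambda = 1; ``"lambda"`` profiles it by ML
    jointly with the regression. The residual vector is the relative-trait
    measure (e.g. relative brain size from log brain on log mass).
    """
    if correlation not in ("BM", "lambda"):
        raise ValueError("correlation must be 'BM' or 'lambda'")
    taxa = sorted(set(y) & set(x) & tree.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa with paired values")
    sub = tree.restrict(taxa) if set(taxa) != tree.taxa else tree
    labels, V = bm_covariance(sub)
    yv = np.array([y[t] for t in labels])
    xv = np.array([x[t] for t in labels])
    X = np.column_stack([np.ones(len(labels)), xv])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular design: predictor has no variation")

    def fit_at(lam: float):
        Vl = _lambda_cov(V, lam)
        L = np.linalg.cholesky(Vl + 1e-12 * np.eye(len(labels)))
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, yv)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yv - X @ beta
        rw = yw - Xw @ beta
        n = len(labels)
        sigma2 = float(rw @ rw) / n
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return ll, beta, resid, sigma2

    if correlation == "BM":
        lam = 1.0
    else:
        res = minimize_scalar(
            lambda l: -fit_at(l)[0], bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-6},
        )
        lam = max([0.0, 1.0, float(res.x)], key=lambda l: fit_at(l)[0])
    ll, beta, resid, sigma2 = fit_at(lam)
    return PGLSResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        residuals=dict(zip(labels, resid)),
        lambda_=lam,
        sigma2=sigma2,
        loglik=ll,
    )


# ---------------------------------------------------------------------------
# perturbation experiments
# ---------------------------------------------------------------------------

def perturb_misplacement(
    tree: PhyloTree, fraction: float, seed=None
) -> tuple[PhyloTree, list[str]]:
    """Randomly re-place round(fraction * n) tips, preserving ultrametricity.

    Each selected tip is pruned and re-attached at a uniformly random point
    on a uniformly random remaining branch, with its pendant length set so
    the tip stays at age 0. Returns the perturbed tree and the moved tips.
    A fraction rounding to zero tips returns the tree unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = tree.n_taxa
    n_move = int(round(fraction * n))
    if n_move == 0:
        return tree.copy(), []
    tips = sorted(tree.taxa)
    moved = [tips[i] for i in rng.choice(n, size=n_move, replace=False)]
    t = tree.copy()
    for label in moved:
        # prune
        leaf = next(nd for nd in t.leaves() if nd.label == label)
        parent = leaf.parent
        parent.children.remove(leaf)
        t.suppress_unifurcations()
        # choose a branch and a point on it
        depths = t.depths()
        height = max(depths[tip] for tip in t.leaves())
        edges = [nd for nd in t.preorder() if nd is not t.root]
        e = edges[int(rng.integers(len(edges)))]
        top = depths[e.parent]
        bottom = depths[e]
        dp = top + rng.random() * (bottom - top)
        # split the edge at depth dp and attach the tip
        join = PhyloNode(length=dp - top)
        gp = e.parent
        idx = gp.children.index(e)
        gp.children[idx] = join
        join.parent = gp
        join.add_child(e)
        e.length = bottom - dp
        new_leaf = PhyloNode(label=label, length=height - dp)
        join.add_child(new_leaf)
    return t, moved


def perturb_convergence(
    trait: Mapping[str, float],
    group_a: Sequence[str],
    group_b: Sequence[str],
    pairs_fraction: float,
    seed=None,
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """Convergent-evolution perturbation: cross-group pairs share one value.

    Pairs (one taxon from each group, sampled without replacement) covering
    ``pairs_fraction`` of all taxa are formed; both members of a pair
    receive the first (group A) member's trait value.
    """
    if not 0.0 <= pairs_fraction <= 1.0:
        raise ValueError("pairs_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(trait)
    n_pairs = int(round(pairs_fraction * n / 2.0))
    ga = sorted(set(group_a) & set(trait))
    gb = sorted(set(group_b) & set(trait))
    n_pairs = min(n_pairs, len(ga), len(gb))
    ia = rng.choice(len(ga), size=n_pairs, replace=False)
    ib = rng.choice(len(gb), size=n_pairs, replace=False)
    out = dict(trait)
    pairs = []
    for a_i, b_i in zip(ia, ib):
        a, b = ga[a_i], gb[b_i]
        out[b] = out[a]
        pairs.append((a, b))
    return out, pairs


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------

def ancestral_bm_states(tree: PhyloTree, trait: Mapping[str, float]) -> dict[frozenset, float]:
    """GLS/ML ancestral states under constant-rate BM, keyed by clade.

    The root state is the GLS mean; internal states are the BM conditional
    expectations given the tips. Taxa without values are dropped (flagged by
    the caller via comparison with the tree's taxa).
    """
    have = {t: v for t, v in trait.items() if v is not None and math.isfinite(v)}
    used = set(have) & tree.taxa
    sub = tree.restrict(used) if used != tree.taxa else tree
    labels, V = bm_covariance(sub)
    x = np.array([have[t] for t in labels])
    Vinv = np.linalg.inv(V + 1e-12 * np.eye(len(labels)))
    ones = np.ones(len(labels))
    mu = float(ones @ Vinv @ x / (ones @ Vinv @ ones))
    resid = x - mu
    depths = sub.depths()
    clades = sub.clades()
    idx = {lab: i for i, lab in enumerate(labels)}
    alpha = Vinv @ resid
    out: dict[frozenset, float] = {}
    for node in sub.preorder():
        if node.is_leaf:
            out[frozenset((node.label,))] = have[node.label]
            continue
        # shared path length between the internal node and each tip
        c = np.empty(len(labels))
        inside = clades[node]
        c[[idx[t] for t in inside]] = depths[node]
        anc = node.parent
        walker = node
        while anc is not None:
            sibs = clades[anc] - clades[walker]
            if sibs:
                c[[idx[t] for t in sibs]] = depths[anc]
            walker, anc = anc, anc.parent
        out[clades[node]] = mu + float(c @ alpha)
    return out


def ancestral_bm_trajectory(
    tree: PhyloTree, trait: Mapping[str, float], bin_width: float = 1.0,
    mode: str = "overlap-weighted",
) -> tuple[list[BranchTrajectoryPoint], pd.DataFrame]:
    """Branch values (mean of reconstructed endpoint states) binned through time."""
    from .rates import branch_ages

    states = ancestral_bm_states(tree, trait)
    have = {t for t in trait if trait[t] is not None and math.isfinite(trait[t])}
    used = have & tree.taxa
    sub = tree.restrict(used) if used != tree.taxa else tree
    ages = branch_ages(sub)
    clades = sub.clades()
    points = []
    for node in sub.preorder():
        if node is sub.root:
            continue
        clade = clades[node]
        parent_clade = clades[node.parent]
        older, younger = ages[clade]
        points.append(
            BranchTrajectoryPoint(
                branch=clade,
                start_age=older,
                end_age=younger,
                value=0.5 * (states[parent_clade] + states[clade]),
            )
        )
    return points, bin_through_time(points, bin_width=bin_width, mode=mode)
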