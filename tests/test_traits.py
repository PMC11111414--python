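import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from radiascope import msc, traits
from radiascope.traits import (
    PagelLambdaEstimator,
    ancestral_bm_states,
    ancestral_bm_trajectory,
    bm_covariance,
    pagel_lambda_ml,
    perturb_convergence,
    perturb_misplacement,
    pgls_residuals,
    simulate_bm,
    simulate_bm_many,
)
from radiascope.tree import read_newick


@pytest.fixture(scope="module")
def tree120():
    return msc.simulate_species_tree(120, birth_rate=0.25, seed=42).tree


class TestSimulateBM:
    def test_zero_variance_all_root_state(self, balanced4):
        trait = simulate_bm(balanced4, 0.0, seed=0, root_state=3.5)
        assert all(v == 3.5 for v in trait.values())

    def test_two_taxon_variance_closed_form(self):
        t = read_newick("(A:2,B:2);")
        df = simulate_bm_many(t, 1.5, 5000, seed=1)
        diffs = df.loc["A"] - df.loc["B"]
        expected = 2 * 1.5 * 2.0  # Var(xA - xB) = 2 sigma^2 t
        se = expected * math.sqrt(2 / 5000)
        assert abs(diffs.var(ddof=0) - expected) < 3 * se

    def test_lambda_zero_iid(self, balanced4):
        df = simulate_bm_many(balanced4, 1.0, 4000, lam=0.0, seed=2)
        # tips are uncorrelated: empirical correlation near zero
        corr = np.corrcoef(df.loc["A"], df.loc["B"])[0, 1]
        assert abs(corr) < 0.05

    def test_covariance_structure(self, balanced4):
        labels, V = bm_covariance(balanced4)
        i, j = labels.index("A"), labels.index("B")
        assert V[i, j] == pytest.approx(0.5)  # shared path to AB ancestor
        assert V[i, i] == pytest.approx(1.5)


class TestPagelLambda:
    def test_loglik_matches_mvn_oracle(self):
        t = read_newick("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")
        trait = {"A": 0.3, "B": -0.2, "C": 1.1, "D": 0.9}
        labels, V = bm_covariance(t)
        x = np.array([trait[l] for l in labels])
        est = PagelLambdaEstimator(t)
        for lam in (0.0, 0.5, 1.0):
            Vl = lam * V
            np.fill_diagonal(Vl, np.diag(V))
            # profile mu and sigma2 exactly as the estimator defines them
            Vinv = np.linalg.inv(Vl)
            ones = np.ones(len(x))
            mu = ones @ Vinv @ x / (ones @ Vinv @ ones)
            sigma2 = (x - mu) @ Vinv @ (x - mu) / len(x)
            oracle = multivariate_normal.logpdf(x, mean=mu * ones, cov=sigma2 * Vl)
            assert est.loglik(trait, lam) == pytest.approx(oracle, abs=1e-8)

    def test_recovery_at_high_lambda(self, tree120):
        df = simulate_bm_many(tree120, 1.0, 30, lam=1.0, seed=3)
        est = PagelLambdaEstimator(tree120)
        lams = [est.fit(df.iloc[:, i].to_numpy()).lambda_ for i in range(30)]
        assert np.mean([l >= 0.95 for l in lams]) >= 0.9

    def test_permuted_labels_destroy_signal(self, tree120, rng):
        df = simulate_bm_many(tree120, 1.0, 20, lam=1.0, seed=4)
        est = PagelLambdaEstimator(tree120)
        low = 0
        for i in range(20):
            x = df.iloc[:, i].to_numpy().copy()
            rng.shuffle(x)
            low += est.fit(x).lambda_ <= 0.1
        assert low >= 18

    def test_zero_variance_flagged_missing(self, balanced4):
        fit = pagel_lambda_ml(balanced4, {t: 1.0 for t in "ABCD"})
        assert fit.lambda_ is None and not fit.converged

    def test_missing_taxa_dropped_and_counted(self, tree120):
        trait = simulate_bm(tree120, 1.0, seed=5)
        sub = dict(list(trait.items())[:100])
        fit = pagel_lambda_ml(tree120, sub)
        assert fit.n == 100 and fit.missing_dropped == 20

    def test_mle_at_least_boundary_likelihoods(self, tree120):
        trait = simulate_bm(tree120, 1.0, lam=0.7, seed=6)
        est = PagelLambdaEstimator(tree120)
        fit = est.fit(trait)
        assert fit.loglik >= est.loglik(trait, 0.0) - 1e-9
        assert fit.loglik >= est.loglik(trait, 1.0) - 1e-9


class TestPGLS:
    def test_exact_linear_relation(self, balanced4):
        x = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        y = {k: 2 * v + 1 for k, v in x.items()}
        res = pgls_residuals(balanced4, y, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert all(abs(r) < 1e-9 for r in res.residuals.values())

    def test_gls_closed_form_oracle(self):
        t = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        y = {"A": 0.2, "B": 0.5, "C": 1.9, "D": 1.1}
        x = {"A": 1.0, "B": 1.4, "C": 3.0, "D": 2.2}
        labels, V = bm_covariance(t)
        X = np.column_stack([np.ones(4), [x[l] for l in labels]])
        yv = np.array([y[l] for l in labels])
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ yv)
        res = pgls_residuals(t, y, x)
        assert res.intercept == pytest.approx(beta[0])
        assert res.slope == pytest.approx(beta[1])

    def test_shift_invariance_up_to_intercept(self, balanced4, rng):
        x = {t: float(rng.random()) for t in "ABCD"}
        y = {t: float(rng.random()) for t in "ABCD"}
        r1 = pgls_residuals(balanced4, y, x)
        y2 = {t: v + 10 for t, v in y.items()}
        r2 = pgls_residuals(balanced4, y2, x)
        assert r2.intercept == pytest.approx(r1.intercept + 10)
        for t in "ABCD":
            assert r2.residuals[t] == pytest.approx(r1.residuals[t], abs=1e-9)

    def test_singular_design_error(self, balanced4):
        x = {t: 1.0 for t in "ABCD"}
        y = {t: 2.0 for t in "ABCD"}
        with pytest.raises(ValueError, match="singular"):
            pgls_residuals(balanced4, y, x)


class TestPerturbations:
    def test_zero_fraction_identity(self, tree120):
        out, moved = perturb_misplacement(tree120, 0.0, seed=1)
        assert moved == [] and out.bipartitions() == tree120.bipartitions()

    def test_moved_count_and_ultrametricity(self, tree120):
        out, moved = perturb_misplacement(tree120, 0.2, seed=2)
        assert len(moved) == round(0.2 * 120)
        assert out.taxa == tree120.taxa
        depths = out.depths()
        tips = [depths[t] for t in out.leaves()]
        assert max(tips) - min(tips) < 1e-9 * max(tips)

    def test_lambda_nonincreasing_in_misplacement(self, tree120):
        est_cache = {}
        means = []
        for frac in (0.0, 0.05, 0.2):
            vals = []
            for rep in range(10):
                trait = simulate_bm(tree120, 1.0, lam=0.96, seed=700 + rep)
                pert, _ = perturb_misplacement(tree120, frac, seed=800 + rep)
                vals.append(pagel_lambda_ml(pert, trait).lambda_)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_convergence_pairs(self, rng):
        trait = {f"t{i}": float(i) for i in range(20)}
        ga = [f"t{i}" for i in range(10)]
        gb = [f"t{i}" for i in range(10, 20)]
        out, pairs = perturb_convergence(trait, ga, gb, 0.5, seed=3)
        assert len(pairs) == round(0.5 * 20 / 2)
        for a, b in pairs:
            assert out[b] == out[a] == trait[a]
        untouched = set(trait) - {b for _, b in pairs}
        assert all(out[t] == trait[t] for t in untouched)


class TestAncestral:
    def test_constant_trait_flat(self, balanced4):
        states = ancestral_bm_states(balanced4, {t: 2.0 for t in "ABCD"})
        assert all(v == pytest.approx(2.0) for v in states.values())
        pts, binned = ancestral_bm_trajectory(balanced4, {t: 2.0 for t in "ABCD"})
        assert np.allclose(binned["mean"].dropna(), 2.0)

    def test_root_state_is_gls_mean(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        trait = {"A": 1.0, "B": 2.0, "C": 4.0}
        labels, V = bm_covariance(t)
        x = np.array([trait[l] for l in labels])
        Vinv = np.linalg.inv(V)
        ones = np.ones(3)
        mu = ones @ Vinv @ x / (ones @ Vinv @ ones)
        states = ancestral_bm_states(t, trait)
        assert states[frozenset({"A", "B", "C"})] == pytest.approx(mu)

    def test_trajectory_under_bm_is_flat_on_average(self, tree120):
        """No systematic trend through time when the trait is plain BM."""
        slopes = []
        for rep in range(10):
            trait = simulate_bm(tree120, 1.0, seed=900 + rep)
            pts, binned = ancestral_bm_trajectory(tree120, trait)
            ok = binned.dropna()
            mids = 0.5 * (ok["bin_start"] + ok["bin_end"])
            slopes.append(np.polyfit(mids, ok["mean"], 1)[0])
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / math.sqrt(10) + 0.05
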