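"""Phylogenetic covariance, λ-signal estimation and PGLS regression.

The λ-profile machinery is checked against independent routes: explicit
dense GLS solves, a closed-form grid oracle, ordinary least squares on
independence structures, and (on one small dataset) the reference R
implementations (phytools::phylosig, nlme::gls + ape::corPagel).
"""

import shutil
import subprocess

import numpy as np
import pytest

from thermocrispr import (
    estimate_lambda_signal,
    lambda_transform,
    pgls_fit,
    phylo_covariance,
    read_tree,
    simulate_tree,
)
from thermocrispr.simulate import CorrelatedSampler


class TestPhyloCovariance:
    def test_star_tree_has_no_shared_history(self):
        cov = phylo_covariance(read_tree("(A:1,B:1,C:1,D:1):0;"))
        assert np.allclose(cov.matrix, np.eye(4))

    def test_two_tip_closed_form(self):
        cov = phylo_covariance(read_tree("(A:0.3,B:0.7):0;"))
        order = cov.tip_order
        expected = np.diag([0.3 if l == "A" else 0.7 for l in order])
        assert np.allclose(cov.matrix, expected)

    def test_balanced_tree_matches_hand_summed_paths(self, balanced_tree):
        cov = phylo_covariance(balanced_tree)
        idx = {l: i for i, l in enumerate(cov.tip_order)}
        C = cov.matrix
        assert C[idx["A"], idx["A"]] == pytest.approx(1.5)
        assert C[idx["A"], idx["B"]] == pytest.approx(0.5)
        assert C[idx["C"], idx["D"]] == pytest.approx(0.8)
        assert C[idx["A"], idx["C"]] == pytest.approx(0.0)
        assert C[idx["C"], idx["C"]] == pytest.approx(1.5)

    def test_brute_force_pairwise_path_summation(self):
        # independent oracle: depth of MRCA from tip-to-root ancestor paths
        tree = read_tree("(((A:0.2,B:0.4):0.3,C:0.9):0.1,(D:0.5,E:0.6):0.7):0;")
        cov = phylo_covariance(tree)

        paths = {}
        for leaf in tree.leaf_node_iter():
            anc, node, d = [], leaf, 0.0
            while node is not None:
                anc.append((id(node), d))
                d += node.edge.length or 0.0
                node = node.parent_node
            total = d
            paths[leaf.taxon.label] = (dict(anc), total)
        for i, a in enumerate(cov.tip_order):
            for j, b in enumerate(cov.tip_order):
                anc_a, tot_a = paths[a]
                anc_b, tot_b = paths[b]
                shared = [
                    tot_a - d_a for nid, d_a in anc_a.items() if nid in anc_b
                ]
                mrca_depth = max(shared) if i != j else tot_a
                assert cov.matrix[i, j] == pytest.approx(mrca_depth, abs=1e-12)

    def test_negative_branch_length_rejected(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,B:-0.5):0;", schema="newick")
        with pytest.raises(ValueError, match="negative"):
            from thermocrispr.io_data import validate_tree

            validate_tree(tree)


class TestLambdaTransform:
    def test_limits_and_scaling(self, balanced_tree):
        cov = phylo_covariance(balanced_tree)
        v0 = lambda_transform(cov, 0.0)
        assert np.allclose(v0, np.diag(np.diag(cov.matrix)))
        assert np.allclose(lambda_transform(cov, 1.0), cov.matrix)
        v_half = lambda_transform(cov, 0.5)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(v_half[off], 0.5 * cov.matrix[off])

    def test_out_of_bounds_rejected(self, balanced_tree):
        cov = phylo_covariance(balanced_tree)
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError):
                lambda_transform(cov, bad)


def _random_instance(seed, n_lo=10, n_hi=50):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    tree = simulate_tree(n, seed=seed)
    cov = phylo_covariance(tree)
    x = rng.normal(size=n)
    L = np.linalg.cholesky(cov.matrix + 1e-10 * np.eye(n))
    y = 1.0 + 0.5 * x + L @ rng.normal(size=n)
    return cov, x, y


class TestPGLS:
    def test_lambda0_on_ultrametric_tree_is_ols(self):
        for seed in range(5):
            cov, x, y = _random_instance(seed)
            fit = pgls_fit(y, x, cov, fixed_lambda=0.0)
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_lambda1_matches_explicit_gls_solve(self):
        for seed in range(5):
            cov, x, y = _random_instance(seed)
            fit = pgls_fit(y, x, cov, fixed_lambda=1.0)
            X = np.column_stack([np.ones_like(x), x])
            Vinv = np.linalg.inv(cov.matrix + 1e-10 * np.eye(len(y)))
            beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_star_tree_reduces_to_ols_for_any_lambda(self):
        rng = np.random.default_rng(1)
        n = 20
        cov = phylo_covariance(
            read_tree("(" + ",".join(f"t{i}:1" for i in range(n)) + "):0;")
        )
        x = rng.normal(size=n)
        y = 2.0 - 0.3 * x + rng.normal(size=n)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for lam in (0.0, 0.4, 1.0):
            fit = pgls_fit(y, x, cov, fixed_lambda=lam)
            assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_profile_maximum_beats_lambda_grid(self):
        grid = np.linspace(0, 1, 101)
        for seed in range(5):
            cov, x, y = _random_instance(seed + 100)
            fit = pgls_fit(y, x, cov)
            grid_best = max(
                pgls_fit(y, x, cov, fixed_lambda=l).loglik for l in grid
            )
            assert fit.loglik >= grid_best - 1e-6

    def test_invariant_to_tip_permutation(self):
        cov, x, y = _random_instance(3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        from thermocrispr.phylo import PhyloCovariance

        cov_p = PhyloCovariance(
            cov.matrix[np.ix_(perm, perm)], [cov.tip_order[i] for i in perm]
        )
        a = pgls_fit(y, x, cov)
        b = pgls_fit(y[perm], x[perm], cov_p)
        assert a.slope == pytest.approx(b.slope, rel=1e-8)
        assert a.lambda_hat == pytest.approx(b.lambda_hat, abs=1e-5)

    def test_constant_covariate_rejected(self, medium_cov):
        n = len(medium_cov.tip_order)
        with pytest.raises(ValueError, match="constant"):
            pgls_fit(np.random.default_rng(0).normal(size=n), np.ones(n), medium_cov)


class TestSignal:
    def test_iid_noise_has_no_signal(self, medium_cov):
        rng = np.random.default_rng(11)
        lams = [
            estimate_lambda_signal(rng.normal(size=len(medium_cov.tip_order)), medium_cov).lambda_hat
            for _ in range(10)
        ]
        assert np.mean(lams) < 0.1

    def test_brownian_trait_has_full_signal(self, medium_cov):
        rng = np.random.default_rng(13)
        sampler = CorrelatedSampler(medium_cov.matrix, 1.0)
        lams = [
            estimate_lambda_signal(sampler.draw(rng), medium_cov).lambda_hat
            for _ in range(10)
        ]
        assert np.mean(lams) > 0.9

    def test_loglik_at_hat_dominates_zero_and_p_in_range(self, medium_cov):
        rng = np.random.default_rng(5)
        est = estimate_lambda_signal(
            CorrelatedSampler(medium_cov.matrix, 0.7).draw(rng), medium_cov
        )
        assert est.loglik_at_hat >= est.loglik_at_zero - 1e-8
        assert 0 <= est.p_value <= 1

    def test_constant_trait_rejected(self, medium_cov):
        with pytest.raises(ValueError, match="zero-variance"):
            estimate_lambda_signal(np.ones(len(medium_cov.tip_order)), medium_cov)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_cross_check_against_r_reference(tmp_path):
    """λ̂ and PGLS slope agree with phytools::phylosig and nlme::gls+corPagel."""
    n = 50
    tree = simulate_tree(n, seed=77)
    cov = phylo_covariance(tree)
    rng = np.random.default_rng(77)
    sampler = CorrelatedSampler(cov.matrix, 0.8)
    x = rng.uniform(0, 10, n)
    y = 0.5 * x + 2.0 * sampler.draw(rng)
    est = estimate_lambda_signal(y, cov)
    fit = pgls_fit(y, x, cov)

    tree.write(path=str(tmp_path / "tree.nwk"), schema="newick", suppress_rooting=True)
    with open(tmp_path / "data.csv", "w") as fh:
        fh.write("species,x,y\n")
        for s, xi, yi in zip(cov.tip_order, x, y):
            fh.write(f"{s},{float(xi)!r},{float(yi)!r}\n")
    # nlme's corPagel optimizes lambda unbounded (it can go negative), so to
    # cross-check the bounded-ML model we profile fixed-lambda gls fits over
    # a grid in [0, 1] and take the best.
    rcode = """
    suppressMessages({library(ape); library(phytools); library(nlme)})
    tr <- read.tree(commandArgs(TRUE)[1])
    d <- read.csv(commandArgs(TRUE)[2], row.names=1)
    d <- d[tr$tip.label,]
    sig <- phylosig(tr, setNames(d$y, tr$tip.label), method="lambda")
    grid <- seq(0, 1, by=0.01)
    fits <- lapply(grid, function(l) gls(y ~ x, data=d,
        correlation=corPagel(l, tr, form=~1, fixed=TRUE), method="ML"))
    lls <- sapply(fits, logLik)
    best <- which.max(lls)
    cat(sig$lambda, grid[best], coef(fits[[best]])[2], "\\n")
    """
    rfile = tmp_path / "check.R"
    rfile.write_text(rcode)
    out = subprocess.run(
        ["Rscript", str(rfile), str(tmp_path / "tree.nwk"), str(tmp_path / "data.csv")],
        capture_output=True, text=True, timeout=300,
    )
    assert out.returncode == 0, out.stderr
    vals = out.stdout.split()
    r_sig_lambda, r_pgls_lambda, r_slope = (float(v) for v in vals[:3])
    assert est.lambda_hat == pytest.approx(r_sig_lambda, abs=0.05)
    assert fit.lambda_hat == pytest.approx(r_pgls_lambda, abs=0.02)
    assert fit.slope == pytest.approx(r_slope, rel=0.02)
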