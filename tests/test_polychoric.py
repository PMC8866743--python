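"""Polychoric estimation: thresholds, pairwise ML, matrix, weights."""

import numpy as np
import pytest
from shortscale.instrument import ResponseMatrix
from shortscale.polychoric import (
    _cell_probs,
    bvn_cdf,
    polychoric_matrix,
    polychoric_pair,
    thresholds_from_margins,
)
from shortscale.simulate import generate_responses, implied_item_correlation


def _simulate_table(rho, tau1, tau2, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(tau1, z[:, 0])
    y = np.searchsorted(tau2, z[:, 1])
    table = np.zeros((len(tau1) + 1, len(tau2) + 1))
    np.add.at(table, (x, y), 1.0)
    return table


class TestThresholds:
    def test_quartile_counts_give_quartile_probits(self):
        tau = thresholds_from_margins(np.array([25, 25, 25, 25]))
        assert np.allclose(tau, [-0.6745, 0.0, 0.6745], atol=1e-4)

    def test_even_binary_split(self):
        assert thresholds_from_margins(np.array([50, 50])) == pytest.approx([0.0])

    def test_empty_category_collapsed_and_logged(self):
        table = np.diag([10.0, 0.0, 10.0, 10.0]) + 1
        table[:, 1] = 0  # empty column category
        rho = polychoric_pair(table)
        assert -1 < rho < 1  # estimable after collapse

    def test_matrix_collapse_logging(self, toy_spec, toy_sample):
        resp, _ = toy_sample
        data = resp.data.copy()
        data.loc[data["F1_i1"] == 3, "F1_i1"] = 2  # kill top category
        poly = polychoric_matrix(ResponseMatrix(data=data), toy_spec, compute_weights=False)
        assert any("F1_i1" in line for line in poly.collapse_log)
        assert len(poly.tau["F1_i1"]) == 2


class TestPairEstimation:
    def test_independence_table(self):
        assert abs(polychoric_pair(np.array([[25.0, 25], [25, 25]]))) < 1e-6

    def test_perfect_concordance_clamps(self):
        assert polychoric_pair(np.diag([10.0, 10, 10, 10])) == 0.999

    def test_symmetry_under_transpose(self):
        table = _simulate_table(0.37, [-0.3, 0.5], [-0.6, 0.2, 1.0], 5000, 11)
        assert polychoric_pair(table) == pytest.approx(polychoric_pair(table.T), abs=1e-6)

    def test_recovery_and_grid_oracle_agreement(self):
        """rho_hat at n=1e6 recovers 0.5 and agrees with a brute-force
        likelihood grid scan to 1e-4."""
        tau = np.array([-0.6745, 0.0, 0.6745])
        table = _simulate_table(0.5, tau, tau, 10**6, 21)
        t1 = thresholds_from_margins(table.sum(axis=1))
        t2 = thresholds_from_margins(table.sum(axis=0))
        rho = polychoric_pair(table, t1, t2)
        assert rho == pytest.approx(0.5, abs=0.005)
        # independent coarse-to-fine grid scan of the same likelihood
        grid = np.linspace(-0.99, 0.99, 397)
        nll = [-np.sum(table * np.log(_cell_probs(t1, t2, r))) for r in grid]
        best = grid[int(np.argmin(nll))]
        fine = np.linspace(best - 0.01, best + 0.01, 2001)
        nll_f = [-np.sum(table * np.log(_cell_probs(t1, t2, r))) for r in fine]
        assert rho == pytest.approx(fine[int(np.argmin(nll_f))], abs=1e-4)

    def test_monotone_in_diagonal_mass(self):
        """Moving mass from off-diagonal to diagonal never decreases rho."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            table = rng.integers(5, 60, size=(3, 3)).astype(float)
            rho0 = polychoric_pair(table)
            shifted = table.copy()
            shifted[0, 2] -= 4
            shifted[0, 0] += 4
            assert polychoric_pair(shifted) >= rho0 - 1e-9

    def test_rmse_at_moderate_n(self):
        tau = np.array([-0.2, 0.6, 1.4])
        errs = []
        for rep in range(50):
            table = _simulate_table(0.5, tau, tau, 2000, 100 + rep)
            errs.append(polychoric_pair(table) - 0.5)
        assert np.sqrt(np.mean(np.square(errs))) < 0.03


class TestMatrixAndWeights:
    def test_matrix_close_to_implied(self, toy_config, toy_sample):
        resp, _ = toy_sample
        poly = polychoric_matrix(resp, toy_config.spec)
        implied = implied_item_correlation(toy_config)
        # n = 1500: sampling SD per estimate is ~0.028, 28 estimates
        assert np.max(np.abs(poly.R - implied)) < 0.12
        off = np.abs(poly.R - implied)[np.triu_indices(8, k=1)]
        assert np.mean(off) < 0.035

    def test_duplicated_rows_identical_matrix(self, toy_config, toy_sample):
        import pandas as pd

        resp, _ = toy_sample
        poly1 = polychoric_matrix(resp, toy_config.spec, compute_weights=False)
        doubled = ResponseMatrix(data=pd.concat([resp.data, resp.data], ignore_index=True))
        poly2 = polychoric_matrix(doubled, toy_config.spec, compute_weights=False)
        assert np.allclose(poly1.R, poly2.R, atol=1e-6)

    def test_weights_scale_inversely_with_n(self, toy_config):
        from dataclasses import replace

        w_small, w_large = [], []
        for rep in range(5):
            r1, _ = generate_responses(replace(toy_config, n=1000), seed=200 + rep)
            r2, _ = generate_responses(replace(toy_config, n=2000), seed=300 + rep)
            w_small.append(polychoric_matrix(r1, toy_config.spec).w)
            w_large.append(polychoric_matrix(r2, toy_config.spec).w)
        ratio = np.mean(np.concatenate(w_large)) / np.mean(np.concatenate(w_small))
        assert 0.4 < ratio < 0.6

    def test_independent_items_weight_near_pearson_analogue(self, toy_spec, toy_config):
        from dataclasses import replace

        cfg = replace(toy_config, lam={i: 0.0 for i in toy_spec.items}, n=2000)
        resp, _ = generate_responses(cfg, seed=8)
        poly = polychoric_matrix(resp, toy_spec)
        assert np.all(poly.w > 1 / (2 * 2000))
        assert np.all(poly.w < 2 / 2000 * 2)

    def test_small_sample_unit_weight_fallback(self, toy_spec, toy_sample):
        resp, _ = toy_sample
        small = ResponseMatrix(data=resp.data.iloc[:40].copy())
        with pytest.warns(UserWarning, match="unit"):
            poly = polychoric_matrix(small, toy_spec)
        assert np.all(poly.w == 1.0)

    def test_psd_repair_flagged(self, toy_spec, toy_sample):
        resp, _ = toy_sample
        poly = polychoric_matrix(resp, toy_spec, compute_weights=False)
        assert np.linalg.eigvalsh(poly.R).min() > 0
        assert not poly.smoothed

    def test_subset_consistency(self, bf_config, bf_poly):
        keep = list(bf_config.spec.items[:6])
        sub = bf_poly.subset(keep)
        for i, a in enumerate(keep):
            for j, b in enumerate(keep):
                ia = bf_poly.items.index(a)
                ib = bf_poly.items.index(b)
                assert sub.R[i, j] == bf_poly.R[ia, ib]


def test_bvn_cdf_against_quadrature_identities():
    rng = np.random.default_rng(0)
    h, k = rng.normal(size=5), rng.normal(size=5)
    # rho = 0 factorizes
    from scipy.special import ndtr

    assert np.allclose(bvn_cdf(h, k, 0.0), ndtr(h) * ndtr(k), atol=1e-14)
    # symmetry in the arguments
    assert np.allclose(bvn_cdf(h, k, 0.6), bvn_cdf(k, h, 0.6), atol=1e-12)
    # perfect dependence: P(X<=h, X<=k) = Phi(min(h, k))
    assert np.allclose(bvn_cdf(h, k, 0.9999), ndtr(np.minimum(h, k)), atol=1e-3)
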