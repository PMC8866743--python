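"""DWLS engine: implied matrices, fitting, scaled statistics, fit indices."""

import itertools

import numpy as np
import pytest
from scipy import stats

from shortscale.cfa import (
    CFAParams,
    ModelSpec,
    OrdinalFactorModel,
    _build_index,
    _congeneric_objective,
    _rmsea_ci,
    detect_heywood,
    fit_indices,
    implied_corr,
    scaled_chisq,
)
from shortscale.instrument import InstrumentSpec
from shortscale.polychoric import PolychoricResult, polychoric_matrix
from shortscale.simulate import implied_item_correlation


def _perfect_poly(R, spec, n=2000):
    p = R.shape[0]
    return PolychoricResult(
        R=R,
        tau={i: np.array([-0.2, 0.6, 1.4]) for i in spec.items},
        w=np.full(p * (p - 1) // 2, 1.0 / n),
        items=tuple(spec.items),
        n=n,
    )


class TestImpliedCorr:
    def test_single_facet_tau_equivalent(self):
        spec = InstrumentSpec(
            items=("a", "b"),
            item_to_facet={"a": "F", "b": "F"},
            facet_to_domain={"F": "D"},
        )
        v = 0.49
        params = CFAParams(
            mode="tau_equivalent",
            a=np.array([np.sqrt(v), np.sqrt(v)]),
            g=np.array([1.0]),
            phi=np.eye(1),
        )
        S = implied_corr(params, ModelSpec(spec=spec))
        assert S[0, 1] == pytest.approx(v)

    def test_congeneric_same_facet(self, toy_spec):
        params = CFAParams(
            mode="congeneric",
            a=np.full(8, 0.8),
            g=np.full(4, 0.8),
            phi=np.array([[1.0, 0.4], [0.4, 1.0]]),
        )
        S = implied_corr(params, ModelSpec(spec=toy_spec, mode="congeneric"))
        assert S[0, 1] == pytest.approx(0.64)

    def test_matches_generator_path_tracing(self, bf_config):
        """Truth parameters reproduce the generator's implied matrix."""
        spec = bf_config.spec
        params = CFAParams(
            mode="congeneric",
            a=np.array([bf_config.lam[i] for i in spec.items]),
            g=np.array([bf_config.gamma[f] for f in spec.facets]),
            phi=bf_config.phi,
        )
        S = implied_corr(params, ModelSpec(spec=spec, mode="congeneric"))
        assert np.max(np.abs(S - implied_item_correlation(bf_config))) < 1e-12


class TestFitDWLS:
    def test_perfect_input_perfect_fit(self, bf_config):
        R = implied_item_correlation(bf_config)
        poly = _perfect_poly(R, bf_config.spec)
        for mode in ("tau_equivalent", "congeneric"):
            res = OrdinalFactorModel(poly, bf_config.spec, mode=mode).fit()
            assert res.F < 1e-10
            assert res.scaled_chisq < 1e-6
            assert res.cfi == 1.0
            assert res.rmsea == 0.0
            assert res.srmr < 1e-6
            assert not res.heywood

    def test_congeneric_recovers_truth_from_exact_input(self, bf_config):
        R = implied_item_correlation(bf_config)
        res = OrdinalFactorModel(_perfect_poly(R, bf_config.spec), bf_config.spec, "congeneric").fit()
        assert np.max(np.abs(res.params.a - 0.8)) < 1e-6
        assert np.max(np.abs(res.params.g - 0.8)) < 1e-6
        assert np.max(np.abs(res.params.phi - bf_config.phi)) < 1e-6

    def test_congeneric_recovery_from_data(self, bf_config, bf_poly):
        res = OrdinalFactorModel(bf_poly, bf_config.spec, mode="congeneric").fit()
        assert res.converged
        assert np.max(np.abs(res.params.a - 0.8)) < 0.05
        assert np.max(np.abs(res.params.g - 0.8)) < 0.05

    def test_tau_equivalent_matches_grid_oracle(self, toy_spec, toy_sample):
        """Closed-form block means equal an exhaustive coarse-to-fine grid
        search over the free parameters on a 2-facet toy model."""
        sub_items = [i for i in toy_spec.items if i.startswith(("F1", "F2"))]
        sub = toy_spec.subset(sub_items)
        resp, _ = toy_sample
        poly = polychoric_matrix(resp, sub)
        res = OrdinalFactorModel(poly, sub, mode="tau_equivalent").fit()
        s, w = poly.vech(), poly.w
        ix = _build_index(sub)

        def F_of(t1, t2, psi):
            sigma = np.empty(len(s))
            for j, b in enumerate(ix.pair_block):
                kind = ix.block_param[b][0]
                sigma[j] = {0: t1, 1: t2}[ix.block_param[b][1]] if kind == "facet" else psi
            return np.sum((s - sigma) ** 2 / w)

        best = None
        grid = np.linspace(0.1, 0.9, 33)
        for t1, t2, psi in itertools.product(grid, grid, grid):
            val = F_of(t1, t2, psi)
            if best is None or val < best[0]:
                best = (val, t1, t2, psi)
        # refine around the coarse optimum
        fine = lambda c: np.linspace(c - 0.03, c + 0.03, 61)
        for t1, t2, psi in itertools.product(fine(best[1]), fine(best[2]), fine(best[3])):
            val = F_of(t1, t2, psi)
            if val < best[0]:
                best = (val, t1, t2, psi)
        t_fit = res.params.psi[0] + res.params.zeta  # facet variances
        assert t_fit[0] == pytest.approx(best[1], abs=1e-3)
        assert t_fit[1] == pytest.approx(best[2], abs=1e-3)
        assert res.params.psi[0] == pytest.approx(best[3], abs=1e-3)
        assert res.F <= best[0] + 1e-10

    def test_analytic_gradient_matches_finite_differences(self, bf_config, bf_poly):
        ix = _build_index(bf_config.spec)
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.uniform(0.4, 0.9, 34), rng.uniform(0.4, 0.9, 17), rng.uniform(-0.3, 0.5, 15)]
        )
        s, invw = bf_poly.vech(), 1.0 / bf_poly.w
        _, grad = _congeneric_objective(x, s, invw, ix)
        fd = np.empty_like(x)
        for k in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[k] += 1e-6
            xm[k] -= 1e-6
            fd[k] = (
                _congeneric_objective(xp, s, invw, ix)[0]
                - _congeneric_objective(xm, s, invw, ix)[0]
            ) / 2e-6
        assert np.max(np.abs(grad - fd)) / np.max(np.abs(fd)) < 1e-6


class TestScaledStatistics:
    def test_identity_case_no_projection(self):
        """With Gamma = W and no model projection, c = 1 and T_s = T."""
        w = np.full(10, 0.002)
        T, c, Ts = scaled_chisq(5.0, 1001, w, w / 1000, None, 10)
        assert c == pytest.approx(1.0)
        assert Ts == pytest.approx(T)

    def test_perfect_fit_statistic_zero(self, bf_config):
        R = implied_item_correlation(bf_config)
        res = OrdinalFactorModel(_perfect_poly(R, bf_config.spec), bf_config.spec).fit()
        assert res.scaled_chisq == pytest.approx(0.0, abs=1e-6)

    def test_saturated_model_defined_as_zero(self):
        T, c, Ts = scaled_chisq(0.5, 100, np.ones(3), np.ones(3), None, 0)
        assert Ts == 0.0


class TestFitIndices:
    def test_chisq_equal_df_is_clean(self):
        idx = fit_indices(100.0, 100, 500.0, 120, 1001, np.zeros(10))
        assert idx["rmsea"] == 0.0
        assert idx["cfi"] == 1.0

    def test_rmsea_formula(self):
        idx = fit_indices(200.0, 100, 5000.0, 120, 1001, np.zeros(10))
        assert idx["rmsea"] == pytest.approx(np.sqrt(100 / (100 * 1000)), abs=1e-12)

    def test_rmsea_ci_against_bisection_oracle(self):
        ts, df, n = 180.0, 100, 500
        lo, hi = _rmsea_ci(ts, df, n)

        def bisect(prob):
            a, b = 0.0, 1000.0
            for _ in range(80):
                mid = (a + b) / 2
                if stats.ncx2.cdf(ts, df, mid) > prob:
                    a = mid
                else:
                    b = mid
            return (a + b) / 2

        lam_lo, lam_hi = bisect(0.95), bisect(0.05)
        assert lo == pytest.approx(np.sqrt(lam_lo / (df * (n - 1))), abs=1e-4)
        assert hi == pytest.approx(np.sqrt(lam_hi / (df * (n - 1))), abs=1e-4)
        assert lo <= np.sqrt(max(ts - df, 0) / (df * (n - 1))) <= hi

    def test_srmr_is_rms_residual(self):
        res = np.array([0.02, -0.02, 0.04])
        idx = fit_indices(10.0, 5, 50.0, 10, 100, res)
        assert idx["srmr"] == pytest.approx(np.sqrt(np.mean(res**2)))


class TestStandardizedAndHeywood:
    def test_tau_equivalent_standardization(self, toy_spec, toy_sample):
        resp, _ = toy_sample
        res = OrdinalFactorModel.from_responses(resp, toy_spec).fit()
        for f, facet in enumerate(toy_spec.facets):
            tf = res.params.zeta[f] + res.params.psi[[0, 0, 1, 1][f]]
            item_idx = [k for k, it in enumerate(toy_spec.items) if toy_spec.item_to_facet[it] == facet]
            for k in item_idx:
                assert res.params.a[k] == pytest.approx(np.sqrt(tf), abs=1e-12)

    def test_no_flags_on_admissible_params(self):
        params = CFAParams(
            mode="congeneric", a=np.array([0.7, 0.8]), g=np.array([0.9]), phi=np.eye(1)
        )
        assert detect_heywood(params) == []

    def test_negative_disturbance_flagged_with_facet(self):
        params = CFAParams(
            mode="tau_equivalent",
            a=np.array([0.7, 0.7]),
            g=np.array([1.01]),
            phi=np.eye(1),
            zeta=np.array([-0.05]),
        )
        flags = detect_heywood(params)
        assert any("facet 0" in f and "disturbance" in f for f in flags)

    def test_out_of_range_latent_correlation_flagged(self):
        params = CFAParams(
            mode="congeneric",
            a=np.array([0.7, 0.7]),
            g=np.array([0.8, 0.8]),
            phi=np.array([[1.0, 1.03], [1.03, 1.0]]),
        )
        assert any("1.030" in f for f in detect_heywood(params))


def test_fit_index_contract_on_well_specified_data(bf_config, bf_poly):
    """The study's own thresholds hold on well-specified synthetic data."""
    res = OrdinalFactorModel(bf_poly, bf_config.spec).fit()
    assert res.cfi > 0.95
    assert res.rmsea < 0.05
    assert res.srmr < 0.07
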