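"""Synthetic-data generator: structure, determinism, implied correlations."""

import numpy as np
import pytest

from shortscale.polychoric import polychoric_matrix
from shortscale.simulate import (
    POOL_SIZES,
    _PHI,
    generate_responses,
    implied_item_correlation,
    inject_careless,
    inject_missing,
    inject_noninvariance,
    make_default_config,
)


class TestDefaultConfigs:
    def test_short_form_template(self):
        cfg = make_default_config("pid5bfplus", n=100)
        assert cfg.spec.n_items == 34
        assert all(cfg.lam[i] == 0.8 for i in cfg.spec.items)
        assert all(cfg.gamma[f] == 0.8 for f in cfg.spec.facets)

    def test_pool_template_plants_two_good_items(self):
        cfg = make_default_config("pid5pool", n=100)
        for f in cfg.spec.facets:
            lams = [cfg.lam[i] for i in cfg.spec.facet_items(f)]
            assert lams[:2] == [0.8, 0.8]
            assert all(l == 0.4 for l in lams[2:])
        assert [len(cfg.spec.facet_items(f)) for f in cfg.spec.facets] == POOL_SIZES

    def test_mean_interdomain_correlation(self):
        off = _PHI[np.triu_indices(6, k=1)]
        assert np.mean(off) == pytest.approx(0.32, abs=0.005)
        assert off.min() >= 0.06 and off.max() <= 0.48
        assert np.linalg.eigvalsh(_PHI).min() > 0

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="unknown template"):
            make_default_config("nope", n=10)

    def test_indefinite_phi_rejected(self, toy_config):
        from dataclasses import replace

        bad = np.array([[1.0, 0.99], [0.99, 1.0]])
        bad[0, 1] = bad[1, 0] = 1.2  # forces a negative eigenvalue
        with pytest.raises(ValueError, match="positive definite"):
            replace(toy_config, phi=bad)


class TestGeneration:
    def test_same_seed_identical(self, toy_config):
        r1, _ = generate_responses(toy_config, seed=5)
        r2, _ = generate_responses(toy_config, seed=5)
        assert np.array_equal(r1.data.to_numpy(), r2.data.to_numpy())

    def test_zero_loadings_give_independent_items(self, toy_spec, toy_config):
        from dataclasses import replace

        cfg = replace(toy_config, lam={i: 0.0 for i in toy_spec.items}, n=3000)
        resp, _ = generate_responses(cfg, seed=2)
        R = np.corrcoef(resp.data.to_numpy(), rowvar=False)
        off = R[np.triu_indices(8, k=1)]
        assert np.max(np.abs(off)) < 3 / np.sqrt(cfg.n)

    def test_empirical_polychorics_match_implied(self):
        """Generator self-consistency: sample polychorics converge to
        lambda_i lambda_j corr(facet_i, facet_j)."""
        cfg = make_default_config("pid5bfplus", n=100_000)
        resp, _ = generate_responses(cfg, seed=9)
        poly = polychoric_matrix(resp, cfg.spec, compute_weights=False)
        implied = implied_item_correlation(cfg)
        assert np.max(np.abs(poly.R - implied)) < 0.02

    def test_criterion_variables_track_their_domains(self, toy_config):
        """A criterion defined as a weighted sum of domain factors plus
        noise correlates with those factors as the weights dictate."""
        from dataclasses import replace

        cfg = replace(
            toy_config,
            n=5000,
            criteria={"distress": ({"D1": 1.0}, 1.0)},
        )
        resp, truth = generate_responses(cfg, seed=8)
        c = resp.criteria["distress"]
        r_d1 = np.corrcoef(c, truth.domains["D1"])[0, 1]
        # Var(criterion) = 1 (weight) + 1 (noise) -> corr with D1 ~ 1/sqrt(2)
        assert r_d1 == pytest.approx(1 / np.sqrt(2), abs=0.03)
        r_d2 = np.corrcoef(c, truth.domains["D2"])[0, 1]
        assert r_d2 < r_d1 - 0.2  # only via the inter-domain correlation

    def test_truth_record_consistent(self, toy_config):
        resp, truth = generate_responses(toy_config, seed=5)
        assert truth.domains.shape == (toy_config.n, 2)
        assert truth.facets.shape == (toy_config.n, 4)
        # items discretize lam*facet + noise: category counts ordered by facet score
        hi = truth.facets["F1"] > 1
        assert resp.data.loc[hi.to_numpy(), "F1_i1"].mean() > resp.data["F1_i1"].mean()


class TestInjections:
    def test_zero_shift_keeps_distribution(self, toy_config):
        cfg = inject_noninvariance(toy_config, "g2", threshold_shift=0.0, n=2000)
        resp, _ = generate_responses(cfg, seed=3)
        a = resp.data[resp.group == "ref"].mean()
        b = resp.data[resp.group == "g2"].mean()
        assert np.max(np.abs(a - b)) < 0.15

    def test_threshold_shift_moves_mass_to_low_categories(self, toy_config):
        cfg = inject_noninvariance(toy_config, "g2", threshold_shift=0.5, n=4000)
        resp, _ = generate_responses(cfg, seed=3)
        ref = resp.data[resp.group == "ref"]
        shifted = resp.data[resp.group == "g2"]
        # raised thresholds -> lower observed categories, by the probit mass
        assert (shifted.mean() < ref.mean() - 0.05).all()

    def test_loading_delta_attenuates_polychorics(self, toy_spec, toy_config):
        from dataclasses import replace

        cfg = replace(toy_config, n=20_000)
        cfg = inject_noninvariance(
            cfg, "g2", loading_delta=-0.5, items=toy_spec.facet_items("F1"), n=20_000
        )
        resp, _ = generate_responses(cfg, seed=4)
        from shortscale.polychoric import polychoric_pair, _pair_table

        def rho(group):
            sub = resp.data[resp.group == group]
            t = _pair_table(sub["F1_i1"].to_numpy(), sub["F1_i2"].to_numpy(), 4, 4)
            return polychoric_pair(t)

        # lambda scaled by 0.5 -> implied within-facet r scaled by 0.25
        assert rho("ref") == pytest.approx(0.64, abs=0.03)
        assert rho("g2") == pytest.approx(0.16, abs=0.03)

    def test_invalid_loading_delta_rejected(self, toy_config):
        with pytest.raises(ValueError, match="outside"):
            inject_noninvariance(toy_config, "g2", loading_delta=0.5)

    def test_careless_fraction_zero_is_identity(self, toy_sample):
        resp, _ = toy_sample
        out, idx = inject_careless(resp, 0.0, kind="longstring")
        assert len(idx) == 0
        assert np.array_equal(out.data.to_numpy(), resp.data.to_numpy(), equal_nan=True)

    def test_longstring_rows_are_constant(self, toy_sample):
        resp, _ = toy_sample
        out, idx = inject_careless(resp, 0.1, kind="longstring", seed=1)
        assert len(idx) == round(0.1 * resp.n)
        for r in idx:
            row = out.data.iloc[r].to_numpy()
            assert len(np.unique(row)) == 1

    def test_missingness_rate(self, bf_sample):
        resp, _ = bf_sample
        out = inject_missing(resp, 0.05, seed=3)
        frac = np.isnan(out.data.to_numpy()).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_heavy_missingness_fails_inclusion_rule(self, toy_sample):
        resp, _ = toy_sample
        out = inject_missing(resp, 0.5, seed=3)
        frac_bad = (np.isnan(out.data.to_numpy()).mean(axis=1) >= 0.10).mean()
        assert frac_bad > 0.95

    def test_rate_zero_identity(self, toy_sample):
        resp, _ = toy_sample
        assert inject_missing(resp, 0.0) is resp
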