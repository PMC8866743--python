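"""Shared fixtures: small instruments and synthetic samples.

Expensive fixtures are session-scoped so the polychoric matrices and
fits are computed once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from shortscale.instrument import InstrumentSpec
from shortscale.polychoric import polychoric_matrix
from shortscale.simulate import DEFAULT_TAU, GenConfig, generate_responses, make_default_config


@pytest.fixture(scope="session")
def toy_spec() -> InstrumentSpec:
    """2 domains x 2 facets x 2 items (8 items)."""
    items, i2f = [], {}
    for f, d in [("F1", "D1"), ("F2", "D1"), ("F3", "D2"), ("F4", "D2")]:
        for j in (1, 2):
            it = f"{f}_i{j}"
            items.append(it)
            i2f[it] = f
    return InstrumentSpec(
        items=tuple(items),
        item_to_facet=i2f,
        facet_to_domain={"F1": "D1", "F2": "D1", "F3": "D2", "F4": "D2"},
        n_categories=4,
    )


@pytest.fixture(scope="session")
def toy_config(toy_spec) -> GenConfig:
    return GenConfig(
        spec=toy_spec,
        phi=np.array([[1.0, 0.4], [0.4, 1.0]]),
        gamma={f: 0.8 for f in toy_spec.facets},
        lam={i: 0.8 for i in toy_spec.items},
        tau={i: DEFAULT_TAU for i in toy_spec.items},
        n=1500,
    )


@pytest.fixture(scope="session")
def toy_sample(toy_config):
    resp, truth = generate_responses(toy_config, seed=7)
    return resp, truth


@pytest.fixture(scope="session")
def bf_config():
    """34-item short-form template at n=2000."""
    return make_default_config("pid5bfplus", n=2000)


@pytest.fixture(scope="session")
def bf_sample(bf_config):
    resp, truth = generate_responses(bf_config, seed=42)
    return resp, truth


@pytest.fixture(scope="session")
def bf_poly(bf_config, bf_sample):
    resp, _ = bf_sample
    return polychoric_matrix(resp, bf_config.spec)


@pytest.fixture(scope="session")
def pool_spec():
    """4-facet selection pool {4,4,5,5} with smoothly varying loadings."""
    items, i2f = [], {}
    for f, k in zip(["F1", "F2", "F3", "F4"], [4, 4, 5, 5]):
        for j in range(k):
            it = f"{f}_i{j}"
            items.append(it)
            i2f[it] = f
    spec = InstrumentSpec(
        items=tuple(items),
        item_to_facet=i2f,
        facet_to_domain={"F1": "D1", "F2": "D1", "F3": "D2", "F4": "D2"},
        n_categories=4,
    )
    lrng = np.random.default_rng(123)
    lam = {it: float(l) for it, l in zip(items, lrng.uniform(0.5, 0.85, len(items)))}
    cfg = GenConfig(
        spec=spec,
        phi=np.array([[1.0, 0.4], [0.4, 1.0]]),
        gamma={f: 0.8 for f in spec.facets},
        lam=lam,
        tau={i: DEFAULT_TAU for i in spec.items},
        n=1000,
    )
    return spec, cfg
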