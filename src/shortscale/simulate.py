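"""Synthetic ordinal response data with a second-order factor structure.

The generator mirrors the measurement model the analysis machinery
assumes: multivariate-normal domain factors, facet factors regressed on
their domain, normal item latents regressed on their facet, and probit
(normal-ogive) discretization into ordered categories.  Because the
discretization matches the polychoric/DWLS estimation assumption, the
implied polychoric correlation between items i and j is exactly

    rho_ij = lambda_i * lambda_j * corr(facet_i, facet_j),

with corr(facet_f, facet_g) = gamma_f * gamma_g * Phi_{d(f), d(g)} for
different facets and 1 within a facet.  This makes parameter recovery an
exact self-consistency check for the whole pipeline.

Two built-in templates emulate the study conditions of a 17-facet /
6-domain maladaptive-trait inventory: ``pid5bfplus`` (the 34-item short
form: 2 items per facet, loadings ~.80, mean inter-domain correlation
.32) and ``pid5pool`` (the 141-item selection pool with two high-loading
"planted" items per facet among weaker distractors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "GenConfig",
    "GroupEffect",
    "make_default_config",
    "generate_responses",
    "inject_noninvariance",
    "inject_careless",
    "inject_missing",
    "implied_item_correlation",
]

#: facet names (abbreviated labels) in reporting order, with their domains
_FACETS = [
    ("EmoLability", "NegativeAffectivity"),
    ("Anxiousness", "NegativeAffectivity"),
    ("SepInsecurity", "NegativeAffectivity"),
    ("Withdrawal", "Detachment"),
    ("Anhedonia", "Detachment"),
    ("IntimAvoidance", "Detachment"),
    ("Manipulativeness", "Antagonism"),
    ("Deceitfulness", "Antagonism"),
    ("Grandiosity", "Antagonism"),
    ("Irresponsibility", "Disinhibition"),
    ("Impulsivity", "Disinhibition"),
    ("Distractibility", "Disinhibition"),
    ("UnusualBeliefs", "Psychoticism"),
    ("Eccentricity", "Psychoticism"),
    ("PercDysregulation", "Psychoticism"),
    ("Perseveration", "Anankastia"),
    ("RigidPerfectionism", "Anankastia"),
]

#: original-instrument item-pool size per facet (sums to 141)
POOL_SIZES = [7, 9, 7, 10, 7, 6, 5, 10, 6, 7, 6, 9, 8, 13, 12, 9, 10]

_DOMAINS = [
    "NegativeAffectivity",
    "Detachment",
    "Antagonism",
    "Disinhibition",
    "Psychoticism",
    "Anankastia",
]

# fixed inter-domain correlation matrix: off-diagonal mean .32, entries
# spanning roughly .06 (Antagonism-NegativeAffectivity) to .48
# (Anankastia-NegativeAffectivity)
_PHI = np.array(
    [
        [1.00, 0.35, 0.06, 0.30, 0.40, 0.48],
        [0.35, 1.00, 0.25, 0.30, 0.40, 0.35],
        [0.06, 0.25, 1.00, 0.40, 0.35, 0.18],
        [0.30, 0.30, 0.40, 1.00, 0.45, 0.20],
        [0.40, 0.40, 0.35, 0.45, 1.00, 0.33],
        [0.48, 0.35, 0.18, 0.20, 0.33, 1.00],
    ]
)

#: default probit thresholds, right-skewed as typical for maladaptive traits
DEFAULT_TAU = (-0.2, 0.6, 1.4)
SYMMETRIC_TAU = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class GroupEffect:
    """Per-group deviations from the reference generating parameters."""

    n: int
    threshold_shift: float = 0.0
    loading_delta: float = 0.0  # lambda scaled by (1 + loading_delta)
    items: tuple[str, ...] | None = None  # affected items; None = all
    domain_mean_shift: float = 0.0  # added to every domain factor mean


@dataclass(frozen=True)
class GenConfig:
    """Full generating recipe for one synthetic study."""

    spec: InstrumentSpec
    phi: np.ndarray  # domain correlation matrix
    gamma: Mapping[str, float]  # facet-on-domain standardized loading
    lam: Mapping[str, float]  # item-on-facet standardized loading
    tau: Mapping[str, tuple[float, ...]]  # per-item increasing thresholds
    n: int = 1000
    groups: Mapping[str, GroupEffect] = field(default_factory=dict)
    careless_fraction: float = 0.0
    careless_kind: str = "random"
    missing_rate: float = 0.0
    criteria: Mapping[str, tuple[Mapping[str, float], float]] = field(default_factory=dict)
    # criteria: name -> (weights per domain, noise SD)

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (len(self.spec.domains),) * 2:
            raise ValueError("phi shape must match number of domains")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("phi must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("phi must be positive definite")
        for f in self.spec.facets:
            g = self.gamma[f]
            if not 0 < g <= 1:
                raise ValueError(f"gamma[{f!r}]={g} outside (0, 1]")
        for i in self.spec.items:
            l = self.lam[i]
            if not 0 <= l <= 1:
                raise ValueError(f"lambda[{i!r}]={l} outside [0, 1]")
            t = np.asarray(self.tau[i], dtype=float)
            if len(t) != self.spec.n_categories - 1 or np.any(np.diff(t) <= 0):
                raise ValueError(f"thresholds for {i!r} must be increasing, length n_categories-1")
        object.__setattr__(self, "phi", phi)


def _pool_spec(sizes: list[int]) -> InstrumentSpec:
    items, item_to_facet = [], {}
    for (facet, _), k in zip(_FACETS, sizes):
        for j in range(k):
            it = f"{facet}_{j + 1}"
            items.append(it)
            item_to_facet[it] = facet
    return InstrumentSpec(
        items=tuple(items),
        item_to_facet=item_to_facet,
        facet_to_domain=dict(_FACETS),
        n_categories=4,
    )


def make_default_config(template: str, n: int = 1000, seed: int | None = None) -> GenConfig:
    """Built-in generating configuration for a named template.

    ``pid5bfplus``: 34 items (2 per facet), all item loadings .80, facet
    loadings .80, inter-domain correlations averaging .32.  ``pid5pool``:
    the 141-item pool with the same structure but exactly two "good"
    (lambda = .80) items planted per facet among lambda = .40 distractors.
    The ``seed`` argument is accepted for interface symmetry; defaults
    are fully deterministic.
    """
    if template == "pid5bfplus":
        spec = _pool_spec([2] * len(_FACETS))
        lam = {i: 0.8 for i in spec.items}
    elif template == "pid5pool":
        spec = _pool_spec(POOL_SIZES)
        # the first two items of each facet are the planted high-loading pair
        lam = {}
        for f in spec.facets:
            for j, it in enumerate(spec.facet_items(f)):
                lam[it] = 0.8 if j < 2 else 0.4
    else:
        raise ValueError(f"unknown template {template!r}; use 'pid5bfplus' or 'pid5pool'")
    return GenConfig(
        spec=spec,
        phi=_PHI.copy(),
        gamma={f: 0.8 for f in spec.facets},
        lam=lam,
        tau={i: DEFAULT_TAU for i in spec.items},
        n=n,
    )


def facet_correlation(config: GenConfig) -> np.ndarray:
    """Implied correlation matrix of the facet factors."""
    spec = config.spec
    nd = {d: k for k, d in enumerate(spec.domains)}
    g = np.array([config.gamma[f] for f in spec.facets])
    dd = np.array([nd[spec.facet_to_domain[f]] for f in spec.facets])
    C = np.outer(g, g) * config.phi[np.ix_(dd, dd)]
    np.fill_diagonal(C, 1.0)
    return C


def implied_item_correlation(config: GenConfig) -> np.ndarray:
    """Population polychoric correlation matrix implied by the recipe."""
    spec = config.spec
    C = facet_correlation(config)
    fi = {f: k for k, f in enumerate(spec.facets)}
    ff = np.array([fi[spec.item_to_facet[i]] for i in spec.items])
    lam = np.array([config.lam[i] for i in spec.items])
    R = np.outer(lam, lam) * C[np.ix_(ff, ff)]
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class LatentTruth:
    """Latent factor draws and generating parameters, for recovery tests."""

    domains: pd.DataFrame
    facets: pd.DataFrame
    config: GenConfig
    group: pd.Series | None = None


def _generate_block(
    config: GenConfig,
    n: int,
    rng: np.random.Generator,
    effect: GroupEffect | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame | None]:
    spec = config.spec
    nd = len(spec.domains)
    L = np.linalg.cholesky(config.phi)
    dom = rng.standard_normal((n, nd)) @ L.T
    if effect is not None and effect.domain_mean_shift:
        dom = dom + effect.domain_mean_shift
    di = {d: k for k, d in enumerate(spec.domains)}
    fac = np.empty((n, len(spec.facets)))
    for k, f in enumerate(spec.facets):
        g = config.gamma[f]
        fac[:, k] = g * dom[:, di[spec.facet_to_domain[f]]] + np.sqrt(1 - g**2) * rng.standard_normal(n)
    fi = {f: k for k, f in enumerate(spec.facets)}
    X = np.empty((n, spec.n_items))
    affected = set(effect.items) if effect is not None and effect.items is not None else None
    for j, it in enumerate(spec.items):
        lam = config.lam[it]
        tau = np.asarray(config.tau[it], dtype=float)
        if effect is not None and (affected is None or it in affected):
            lam = lam * (1 + effect.loading_delta)
            tau = tau + effect.threshold_shift
        y = lam * fac[:, fi[spec.item_to_facet[it]]] + np.sqrt(max(1 - lam**2, 0.0)) * rng.standard_normal(n)
        X[:, j] = np.searchsorted(tau, y)
    crit = None
    if config.criteria:
        crit = pd.DataFrame(index=range(n))
        for name, (weights, noise_sd) in config.criteria.items():
            w = np.array([weights.get(d, 0.0) for d in spec.domains])
            crit[name] = dom @ w + noise_sd * rng.standard_normal(n)
    return X, dom, fac, crit


def generate_responses(config: GenConfig, seed: int) -> tuple[ResponseMatrix, LatentTruth]:
    """Draw a response matrix (plus latent truth) from a generating recipe.

    The reference population contributes ``config.n`` respondents;
    each entry of ``config.groups`` appends its own block with the
    group's parameter deviations applied.  Same config and seed yield
    bitwise-identical output.
    """
    rng = np.random.default_rng(seed)
    spec = config.spec
    blocks, dom_blocks, fac_blocks, crit_blocks, labels = [], [], [], [], []
    X, dom, fac, crit = _generate_block(config, config.n, rng)
    blocks.append(X)
    dom_blocks.append(dom)
    fac_blocks.append(fac)
    crit_blocks.append(crit)
    labels += ["ref"] * config.n
    for gname, effect in config.groups.items():
        X, dom, fac, crit = _generate_block(config, effect.n, rng, effect)
        blocks.append(X)
        dom_blocks.append(dom)
        fac_blocks.append(fac)
        crit_blocks.append(crit)
        labels += [gname] * effect.n
    data = pd.DataFrame(np.vstack(blocks), columns=list(spec.items))
    group = pd.Series(labels, index=data.index, name="sample") if config.groups else None
    criteria = None
    if config.criteria:
        criteria = pd.concat([c for c in crit_blocks], ignore_index=True)
        criteria.index = data.index
    resp = ResponseMatrix(data=data, group=group, criteria=criteria)
    truth = LatentTruth(
        domains=pd.DataFrame(np.vstack(dom_blocks), columns=list(spec.domains), index=data.index),
        facets=pd.DataFrame(np.vstack(fac_blocks), columns=list(spec.facets), index=data.index),
        config=config,
        group=group,
    )
    return resp, truth


def inject_noninvariance(
    config: GenConfig,
    group: str,
    threshold_shift: float = 0.0,
    loading_delta: float = 0.0,
    n: int | None = None,
    items: tuple[str, ...] | None = None,
) -> GenConfig:
    """Add (or update) a group whose parameters deviate from the reference.

    ``threshold_shift`` is added to the affected items' thresholds;
    their loadings are scaled by ``1 + loading_delta``.
    """
    check_items = items if items is not None else config.spec.items
    for it in check_items:
        lam = config.lam[it] * (1 + loading_delta)
        if not 0 < lam <= 1:
            raise ValueError(f"loading_delta drives lambda[{it!r}] to {lam:.3f}, outside (0, 1]")
    groups = dict(config.groups)
    prev = groups.get(group)
    groups[group] = GroupEffect(
        n=n if n is not None else (prev.n if prev else config.n),
        threshold_shift=threshold_shift,
        loading_delta=loading_delta,
        items=items,
    )
    return replace(config, groups=groups)


def inject_careless(
    resp: ResponseMatrix,
    fraction: float,
    kind: str = "random",
    seed: int = 0,
    n_categories: int = 4,
) -> tuple[ResponseMatrix, np.ndarray]:
    """Replace a random subset of respondents with careless-response rows.

    ``longstring`` rows are constant (a single random category repeated);
    ``random`` rows are uniform iid draws over the categories.  Returns
    the modified matrix and the integer positions of affected rows.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = resp.n
    k = int(round(fraction * n))
    idx = rng.choice(n, size=k, replace=False)
    data = resp.data.copy()
    p = data.shape[1]
    if kind == "longstring":
        vals = rng.integers(0, n_categories, size=k)
        for r, v in zip(idx, vals):
            data.iloc[r, :] = float(v)
    elif kind == "random":
        for r in idx:
            data.iloc[r, :] = rng.integers(0, n_categories, size=p).astype(float)
    else:
        raise ValueError("kind must be 'longstring' or 'random'")
    return ResponseMatrix(data=data, group=resp.group, criteria=resp.criteria), np.sort(idx)


def inject_missing(resp: ResponseMatrix, rate: float, seed: int = 0) -> ResponseMatrix:
    """Set each observed cell missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return resp
    rng = np.random.default_rng(seed)
    data = resp.data.copy()
    mask = rng.random(data.shape) < rate
    arr = data.to_numpy()
    arr[mask] = np.nan
    return ResponseMatrix(
        data=pd.DataFrame(arr, columns=data.columns, index=data.index),
        group=resp.group,
        criteria=resp.criteria,
    )
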