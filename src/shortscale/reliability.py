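"""Model-based reliability (McDonald's omega) and facet intercorrelations.

Omega is computed on the latent-response (polychoric) metric, consistent
with the DWLS estimation: for a composite of k items with standardized
loadings lambda_i and uniquenesses theta_i = 1 - lambda_i^2,

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta).

For a domain composite two variants are reported: ``omega_hierarchical``
counts only domain-factor variance (item loading on the domain =
lambda_i * gamma_f) as true score, while ``omega_total`` additionally
counts facet-specific variance.  The total variant is the headline
figure; in a model with strong second-order loadings the two are close.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cfa import CFAResults
from .instrument import InstrumentSpec, ScaleScores

__all__ = [
    "OmegaReport",
    "omega_composite",
    "omega_facet",
    "omega_domain",
    "omega_report",
    "raw_score_omega",
    "within_domain_corr",
]


def omega_composite(loadings: np.ndarray, uniquenesses: np.ndarray | None = None) -> float:
    """Omega of a unidimensional composite from standardized loadings."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) > 1 + 1e-12):
        raise ValueError("standardized loadings must lie in [-1, 1]")
    theta = 1.0 - lam**2 if uniquenesses is None else np.asarray(uniquenesses, dtype=float)
    num = lam.sum() ** 2
    return float(num / (num + theta.sum())) if num + theta.sum() > 0 else 0.0


def _check_involved(fit: CFAResults, item_idx: list[int], facet_idx: list[int]) -> None:
    a = fit.params.a
    g = fit.params.g
    bad = [i for i in item_idx if not np.isfinite(a[i]) or abs(a[i]) > 1 + 1e-8]
    bad_f = [f for f in facet_idx if not np.isfinite(g[f]) or abs(g[f]) > 1 + 1e-8]
    if bad or bad_f:
        raise ValueError(
            f"inadmissible (Heywood) parameters involved: items {bad}, facets {bad_f}"
        )


def omega_facet(fit: CFAResults, facet: str, strict: bool = True) -> float:
    """Omega of one facet composite from its fitted item loadings.

    With ``strict`` (default), inadmissible (Heywood) loadings raise;
    otherwise undefined loadings are treated as 0 and out-of-range ones
    clipped, for use as a search heuristic.
    """
    spec = fit.model.spec
    idx = [k for k, it in enumerate(spec.items) if spec.item_to_facet[it] == facet]
    if strict:
        _check_involved(fit, idx, [])
    lam = np.clip(np.nan_to_num(fit.params.a[idx], nan=0.0), -1.0, 1.0)
    return omega_composite(lam)


def omega_domain(fit: CFAResults, domain: str, strict: bool = True) -> tuple[float, float]:
    """(omega_total, omega_hierarchical) for one domain composite."""
    spec = fit.model.spec
    facets = list(spec.domain_facets(domain))
    f_idx = [list(spec.facets).index(f) for f in facets]
    i_idx = [k for k, it in enumerate(spec.items) if spec.item_domain(it) == domain]
    if strict:
        _check_involved(fit, i_idx, f_idx)
    a = np.clip(np.nan_to_num(fit.params.a, nan=0.0), -1.0, 1.0)
    g = np.clip(np.nan_to_num(fit.params.g, nan=0.0), -1.0, 1.0)
    fmap = {f: j for j, f in enumerate(spec.facets)}
    # composite variance of the unit-weighted sum, from the implied matrix
    S = fit.implied[np.ix_(i_idx, i_idx)]
    var_sum = float(S.sum())
    gen_load = sum(
        a[k] * g[fmap[spec.item_to_facet[spec.items[k]]]] for k in i_idx
    )
    theta = sum(1.0 - a[k] ** 2 for k in i_idx)
    omega_h = float(gen_load**2 / var_sum)
    omega_t = float((var_sum - theta) / var_sum)
    return omega_t, omega_h


@dataclass
class OmegaReport:
    """Facet and domain reliabilities of one fitted model."""

    facet: dict[str, float]
    domain_total: dict[str, float]
    domain_hierarchical: dict[str, float]

    @property
    def mean_facet(self) -> float:
        return float(np.mean(list(self.facet.values())))

    @property
    def mean_domain(self) -> float:
        return float(np.mean(list(self.domain_total.values())))

    @property
    def mean_overall(self) -> float:
        """Mean of facet- and domain-level reliabilities (selection objective)."""
        return float(np.mean(list(self.facet.values()) + list(self.domain_total.values())))


def raw_score_omega(resp, spec: InstrumentSpec, mode: str = "tau_equivalent") -> OmegaReport:
    """Raw-score (Pearson-based) omega variant.

    Fits the same factor model to the Pearson correlation matrix of the
    observed category scores instead of the polychorics.  Raw-score
    omegas are attenuated relative to the latent-response default; both
    are legitimate, they answer different questions (reliability of the
    observed composite vs of the latent response composite).
    """
    import pandas as pd

    from .polychoric import PolychoricResult

    X = resp.data[list(spec.items)]
    R = X.corr().to_numpy()
    p = len(spec.items)
    poly = PolychoricResult(
        R=R,
        tau={i: np.zeros(spec.n_categories - 1) for i in spec.items},
        w=np.full(p * (p - 1) // 2, 1.0 / max(resp.n, 2)),
        items=tuple(spec.items),
        n=resp.n,
    )
    from .cfa import OrdinalFactorModel

    fit = OrdinalFactorModel(poly, spec, mode=mode).fit(fast=True)
    return omega_report(fit, strict=False)


def omega_report(fit: CFAResults, strict: bool = True) -> OmegaReport:
    spec = fit.model.spec
    facet = {f: omega_facet(fit, f, strict=strict) for f in spec.facets}
    dt, dh = {}, {}
    for d in spec.domains:
        dt[d], dh[d] = omega_domain(fit, d, strict=strict)
    return OmegaReport(facet=facet, domain_total=dt, domain_hierarchical=dh)


def within_domain_corr(scores: ScaleScores, spec: InstrumentSpec | None = None) -> dict[str, float]:
    """Mean pairwise Pearson correlation of facet scores within each domain."""
    spec = spec or scores.spec
    out: dict[str, float] = {}
    for d in spec.domains:
        facets = list(spec.domain_facets(d))
        if len(facets) < 2:
            continue
        sub = scores.facet[facets].dropna()
        if len(sub) < 3:
            raise ValueError(f"domain {d!r}: fewer than 3 complete respondents")
        sd = sub.std(ddof=1)
        if (sd == 0).any():
            raise ValueError(f"domain {d!r}: zero-variance facet score")
        C = sub.corr().to_numpy()
        iu = np.triu_indices(len(facets), k=1)
        out[d] = float(C[iu].mean())
    return out
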