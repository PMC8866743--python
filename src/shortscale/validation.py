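"""Criterion-validity and group-contrast statistics.

Correlations from several samples are pooled on the Fisher-z scale.
Differences between two dependent, overlapping correlations (short and
long form of a scale against the same criterion) get the Zou-style
confidence interval built from the individual Fisher CIs and the
estimated correlation between the two correlation estimates.  Group
contrasts use the classical Cohen's d with a noncentral-t confidence
interval.  Profile tables assemble z-standardized scale means per group
with between-group and short-vs-long within-group effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instrument import ScaleScores, z_standardize

__all__ = [
    "fisher_avg",
    "zou_ci_dependent",
    "cohens_d",
    "profile_table",
    "ValidationReport",
    "convergent_matrix",
]


def fisher_avg(rs, ns=None) -> float:
    """Pool correlations via Fisher's z (unweighted by default).

    With ``ns`` given, averages with weights ``n - 3``.
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(np.abs(rs) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = np.arctanh(rs)
    if ns is None:
        zb = z.mean()
    else:
        w = np.asarray(ns, dtype=float) - 3
        zb = float(np.sum(w * z) / np.sum(w))
    return float(np.tanh(zb))


def _corr_between_estimates(r1: float, r2: float, r12: float) -> float:
    """Correlation between two overlapping correlation estimates.

    ``r1 = r(x, y)``, ``r2 = r(x, z)`` share variable ``x``;
    ``r12 = r(y, z)``.
    """
    num = (r12 - 0.5 * r1 * r2) * (1 - r1**2 - r2**2 - r12**2) + r12**3
    den = (1 - r1**2) * (1 - r2**2)
    return num / den


def zou_ci_dependent(r1: float, r2: float, r12: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for ``r1 - r2`` when the correlations share one variable.

    Combines the individual Fisher CIs for ``r1`` and ``r2`` with the
    estimated correlation between the two estimates.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    R = np.array([[1, r1, r2], [r1, 1, r12], [r2, r12, 1]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("infeasible correlation triple (not positive semidefinite)")
    zcrit = stats.norm.ppf(0.5 + level / 2)
    se = 1.0 / np.sqrt(n - 3)
    l1, u1 = np.tanh(np.arctanh(r1) + np.array([-1, 1]) * zcrit * se)
    l2, u2 = np.tanh(np.arctanh(r2) + np.array([-1, 1]) * zcrit * se)
    c = _corr_between_estimates(r1, r2, r12)
    d = r1 - r2
    lo = d - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2))
    hi = d + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2))
    return float(lo), float(hi)


def cohens_d(x1, x2, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Classical Cohen's d with a noncentral-t confidence interval.

    ``d = (mean1 - mean2) / s_pooled`` with the df-weighted pooled SD.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1 = x1[~np.isnan(x1)]
    x2 = x2[~np.isnan(x2)]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 observations")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("zero pooled SD")
    d = float((x1.mean() - x2.mean()) / sp)
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    t_obs = d * scale
    df = n1 + n2 - 2
    a = (1 - level) / 2

    def _nc(prob: float) -> float:
        # the CDF is decreasing in the noncentrality; expand the bracket in
        # small steps (large |nc| arguments are numerically unstable)
        f = lambda nc: stats.nct.cdf(t_obs, df, nc) - prob
        lo, hi = t_obs - 2.0, t_obs + 2.0
        for _ in range(60):
            v = f(lo)
            if np.isfinite(v) and v > 0:
                break
            lo -= 2.0
        for _ in range(60):
            v = f(hi)
            if np.isfinite(v) and v < 0:
                break
            hi += 2.0
        return float(optimize.brentq(f, lo, hi, xtol=1e-8))

    lo = _nc(1 - a) / scale
    hi = _nc(a) / scale
    return d, (float(lo), float(hi))


def convergent_matrix(
    scores_short: ScaleScores, scores_long: ScaleScores, level: str = "facet"
) -> pd.DataFrame:
    """Pearson correlations between short- and long-form scale scores.

    Note: when the short form's items are a subset of the long form's,
    shared items inflate these correlations; interpret accordingly.
    """
    a = getattr(scores_short, level)
    b = getattr(scores_long, level)
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for i in a.columns:
        for j in b.columns:
            ok = a[i].notna() & b[j].notna()
            out.loc[i, j] = float(np.corrcoef(a[i][ok], b[j][ok])[0, 1])
    return out


@dataclass
class ValidationReport:
    """Collected validity statistics of a short form against its parent."""

    convergent_facet: pd.DataFrame | None = None
    convergent_domain: pd.DataFrame | None = None
    criterion_table: pd.DataFrame | None = None
    profile: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def mean_convergent_facet(self) -> float:
        return float(np.mean(np.diag(self.convergent_facet.to_numpy())))

    @property
    def mean_convergent_domain(self) -> float:
        return float(np.mean(np.diag(self.convergent_domain.to_numpy())))


def profile_table(
    scores_short: ScaleScores,
    scores_long: ScaleScores,
    groups: pd.Series,
    reference: dict[str, tuple[float, float]],
    contrasts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-group z-profile with between- and within-group effect sizes.

    For every domain scale and group: mean z-score (against the
    reference norms) and quartiles on the short form; Cohen's d (with
    CI) between the groups of each requested contrast; and the
    within-group short-vs-long d per scale.
    """
    zs = z_standardize(scores_short, reference)
    zl = z_standardize(scores_long, reference)
    labels = [g for g in groups.dropna().unique()]
    rows = []
    for d in scores_short.domain.columns:
        for g in labels:
            m = groups == g
            if m.sum() == 0:
                raise ValueError(f"empty group {g!r}")
            vals = zs.domain.loc[m, d].dropna()
            short_raw = scores_short.domain.loc[m, d]
            long_raw = scores_long.domain.loc[m, d]
            within = np.nan
            if not np.allclose(
                short_raw.dropna(), long_raw[short_raw.notna()], equal_nan=True
            ):
                within, _ = cohens_d(short_raw.dropna(), long_raw.dropna())
            rows.append(
                {
                    "scale": d,
                    "group": g,
                    "n": int(m.sum()),
                    "z_mean": float(vals.mean()),
                    "q25": float(vals.quantile(0.25)),
                    "q50": float(vals.quantile(0.50)),
                    "q75": float(vals.quantile(0.75)),
                    "short_vs_long_d": 0.0 if np.isnan(within) else within,
                }
            )
    table = pd.DataFrame(rows)
    if contrasts:
        extra = []
        for g1, g2 in contrasts:
            for d in scores_short.domain.columns:
                x1 = zs.domain.loc[groups == g1, d].dropna()
                x2 = zs.domain.loc[groups == g2, d].dropna()
                d_val, (lo, hi) = cohens_d(x1, x2)
                extra.append(
                    {
                        "scale": d,
                        "group": f"{g1} vs {g2}",
                        "n": int(len(x1) + len(x2)),
                        "z_mean": np.nan,
                        "d": d_val,
                        "d_lo": lo,
                        "d_hi": hi,
                    }
                )
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)
    return table
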