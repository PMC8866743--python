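"""Careless-responding indices and the sample inclusion rule.

Respondents are screened on (a) fraction of missing items, (b) average
long string — the mean length of maximal runs of identical consecutive
responses, (c) squared Mahalanobis distance of the item-response vector,
and (d) even–odd consistency — the Spearman–Brown-corrected correlation
between facet scores built from even- and odd-positioned items.  A
respondent is included iff fewer than 10% of items are missing and each
index lies within 2.5 reference SDs of the reference (community) mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "ScreeningReport",
    "longstring_avg",
    "mahalanobis_sq",
    "even_odd_consistency",
    "apply_inclusion",
    "index_reference",
]

MISSING_LIMIT = 0.10
Z_LIMIT = 2.5


def longstring_avg(row: np.ndarray) -> float:
    """Mean length of maximal runs of identical consecutive responses.

    Missing entries break runs and are not counted.
    """
    row = np.asarray(row, dtype=float)
    runs: list[int] = []
    cur = None
    cur_len = 0
    for v in row:
        if np.isnan(v):
            if cur_len:
                runs.append(cur_len)
            cur, cur_len = None, 0
        elif v == cur:
            cur_len += 1
        else:
            if cur_len:
                runs.append(cur_len)
            cur, cur_len = v, 1
    if cur_len:
        runs.append(cur_len)
    if not runs:
        raise ValueError("all-missing row")
    return float(np.mean(runs))


def mahalanobis_sq(resp, ridge: float | None = None) -> np.ndarray:
    """Squared Mahalanobis distance of each respondent's item vector.

    Accepts a :class:`ResponseMatrix` or a plain DataFrame/array.
    Missing cells are mean-imputed for the distance computation.  The
    sample covariance is ridge-regularized (default ``1e-6 * trace/p``)
    because few-category items can make it near-singular.
    """
    X = resp.data.to_numpy(dtype=float) if isinstance(resp, ResponseMatrix) else np.asarray(
        resp, dtype=float
    )
    mu = np.nanmean(X, axis=0)
    Xi = np.where(np.isnan(X), mu, X)
    C = np.cov(Xi, rowvar=False)
    p = C.shape[0]
    eps = ridge if ridge is not None else 1e-6 * np.trace(C) / p
    C = C + eps * np.eye(p)
    D = Xi - mu
    sol = np.linalg.solve(C, D.T)
    return np.einsum("ij,ji->i", D, sol)


def even_odd_consistency(row: np.ndarray, spec: InstrumentSpec) -> float:
    """Spearman–Brown-corrected even–odd half correlation across facets.

    Items are split within facet by position (even index vs odd index in
    spec order); facets contribute a pair of half scores when both
    halves have at least one observed item.
    """
    row = np.asarray(row, dtype=float)
    pos = {it: j for j, it in enumerate(spec.items)}
    even_half, odd_half = [], []
    for f in spec.facets:
        its = spec.facet_items(f)
        ev = [row[pos[it]] for k, it in enumerate(its) if k % 2 == 0]
        od = [row[pos[it]] for k, it in enumerate(its) if k % 2 == 1]
        ev = [v for v in ev if not np.isnan(v)]
        od = [v for v in od if not np.isnan(v)]
        if ev and od:
            even_half.append(np.mean(ev))
            odd_half.append(np.mean(od))
    if len(even_half) < 3:
        raise ValueError("fewer than 3 facets with both halves observed")
    e = np.asarray(even_half)
    o = np.asarray(odd_half)
    if e.std() == 0 or o.std() == 0:
        r = 1.0 if np.allclose(e, o) else 0.0
    else:
        r = float(np.corrcoef(e, o)[0, 1])
    sb = 2 * r / (1 + r) if r > -1 else -1.0
    return float(min(max(sb, -1.0), 1.0))


@dataclass
class ScreeningReport:
    """Per-respondent data-quality indices and the inclusion decision."""

    table: pd.DataFrame  # missing_frac, longstring, mahalanobis, even_odd, included
    reference: dict[str, tuple[float, float]]

    @property
    def included(self) -> np.ndarray:
        return self.table["included"].to_numpy(dtype=bool)


def screening_indices(resp: ResponseMatrix, spec: InstrumentSpec) -> pd.DataFrame:
    X = resp.data[list(spec.items)].to_numpy(dtype=float)
    sub = ResponseMatrix(data=resp.data[list(spec.items)])
    maha = mahalanobis_sq(sub)
    rows = []
    for r in range(X.shape[0]):
        row = X[r]
        rows.append(
            {
                "missing_frac": float(np.isnan(row).mean()),
                "longstring": longstring_avg(row) if not np.all(np.isnan(row)) else np.nan,
                "mahalanobis": float(maha[r]),
                "even_odd": even_odd_consistency(row, spec),
            }
        )
    return pd.DataFrame(rows, index=resp.data.index)


def index_reference(indices: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Reference (mean, SD) of the three indices, e.g. from a community sample."""
    ref = {}
    for c in ("longstring", "mahalanobis", "even_odd"):
        ref[c] = (float(indices[c].mean()), float(indices[c].std(ddof=1)))
    return ref


def apply_inclusion(
    resp: ResponseMatrix,
    spec: InstrumentSpec,
    reference: dict[str, tuple[float, float]] | None = None,
) -> ScreeningReport:
    """Inclusion mask: <10% missing and all indices within 2.5 reference SDs.

    ``reference`` holds (mean, SD) per index from a designated reference
    sample; by default the screened sample serves as its own reference.
    """
    idx = screening_indices(resp, spec)
    ref = reference if reference is not None else index_reference(idx)
    ok = idx["missing_frac"] < MISSING_LIMIT
    for c in ("longstring", "mahalanobis", "even_odd"):
        mu, sd = ref[c]
        if sd <= 0:
            raise ValueError(f"reference SD for {c} must be > 0")
        ok &= (idx[c] - mu).abs() <= Z_LIMIT * sd
    idx["included"] = ok
    return ScreeningReport(table=idx, reference=ref)
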