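"""Polychoric correlations, thresholds, and diagonal asymptotic weights.

Two-step estimation: item thresholds come from the univariate category
margins (probit of cumulative proportions); each correlation then
maximizes the bivariate-normal cell likelihood with thresholds held
fixed.  The diagonal of the asymptotic covariance of the estimates is
obtained from the observed information of the pairwise likelihoods and
feeds the diagonally weighted least squares (DWLS) discrepancy.

Zero-frequency categories are collapsed into the adjacent lower
category (logged), so instruments with sparse extreme categories can be
analysed without switching estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from .instrument import InstrumentSpec, ResponseMatrix

__all__ = [
    "PolychoricResult",
    "thresholds_from_margins",
    "polychoric_pair",
    "polychoric_matrix",
    "acov_diag",
    "bvn_cdf",
]

RHO_CLAMP = 0.999
WEIGHT_FLOOR = 1e-8

# Gauss-Legendre nodes for the single integral representation of the
# bivariate normal CDF (Drezner-Wesolowsky form)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Uses the exact single-integral identity
    ``F(h,k;rho) = Phi(h)Phi(k) + (2pi)^{-1} int_0^rho
    exp(-(h^2 - 2 t h k + k^2) / (2(1-t^2))) / sqrt(1-t^2) dt``
    evaluated by fixed Gauss-Legendre quadrature; vectorized over h, k.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base
    # map nodes from [-1, 1] to [0, rho]
    t = 0.5 * rho * (_GL_NODES + 1.0)
    wt = 0.5 * rho * _GL_WEIGHTS
    hh = h[..., None]
    kk = k[..., None]
    om = 1.0 - t**2
    with np.errstate(invalid="ignore"):
        integrand = np.exp(-(hh**2 - 2.0 * t * hh * kk + kk**2) / (2.0 * om)) / np.sqrt(om)
    # +/- inf arguments: exp term is 0 there, fix the nan from inf*0
    integrand = np.where(np.isfinite(hh) & np.isfinite(kk), integrand, 0.0)
    return base + (integrand @ wt) / (2.0 * np.pi)


@dataclass
class PolychoricResult:
    """Pairwise polychoric correlations with thresholds and DWLS weights.

    ``inf_funcs`` holds per-respondent influence contributions ``U``
    (n x n_pairs) scaled so that ``U.T @ U`` estimates the asymptotic
    covariance of the correlations; its diagonal equals ``w``.
    """

    R: np.ndarray  # correlation matrix, unit diagonal
    tau: dict[str, np.ndarray]  # per-item thresholds (probit scale)
    w: np.ndarray  # per-pair asymptotic variance (vech order, i<j)
    items: tuple[str, ...]
    n: int  # number of respondents the matrix is based on
    pairwise_n: np.ndarray | None = None
    collapse_log: list[str] = field(default_factory=list)
    smoothed: bool = False
    inf_funcs: np.ndarray | None = None  # n x n_pairs, float32

    @property
    def n_items(self) -> int:
        return len(self.items)

    def vech(self) -> np.ndarray:
        """Lower-triangle correlations in (i < j) order matching ``w``."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.R[iu]

    def _pair_columns(self, idx: list[int]) -> np.ndarray:
        """vech-order column indices for all pairs within item subset ``idx``."""
        col = getattr(self, "_col_lookup", None)
        if col is None:
            p_full = self.n_items
            col = np.zeros((p_full, p_full), dtype=int)
            iu = np.triu_indices(p_full, k=1)
            col[iu] = np.arange(len(iu[0]))
            col = col + col.T
            object.__setattr__(self, "_col_lookup", col)
        sub = np.array(idx)
        return col[np.ix_(sub, sub)][np.triu_indices(len(sub), k=1)]

    def subset(self, keep: list[str], with_inf: bool = True) -> "PolychoricResult":
        """Result restricted to a subset of items (order follows ``keep``)."""
        idx = [self.items.index(i) for i in keep]
        cols = self._pair_columns(idx)
        inf = self.inf_funcs[:, cols] if (with_inf and self.inf_funcs is not None) else None
        return PolychoricResult(
            R=self.R[np.ix_(idx, idx)],
            tau={i: self.tau[i] for i in keep},
            w=self.w[cols],
            items=tuple(keep),
            n=self.n,
            collapse_log=list(self.collapse_log),
            smoothed=self.smoothed,
            inf_funcs=inf,
        )


def _collapse_counts(counts: np.ndarray, label: str, log: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Merge zero-count categories into the adjacent lower category.

    Returns the collapsed counts and a recode map old-code -> new-code.
    """
    counts = np.asarray(counts, dtype=float)
    recode = np.arange(len(counts))
    keep = counts > 0
    if keep.all():
        return counts, recode
    new_code = -1
    out = []
    for c, k in enumerate(keep):
        if k:
            new_code += 1
            out.append(counts[c])
        else:
            log.append(f"{label}: empty category {c} collapsed into lower neighbour")
        recode[c] = max(new_code, 0)
    if len(out) < 2:
        raise ValueError(f"{label}: fewer than 2 nonempty categories")
    return np.asarray(out), recode


def thresholds_from_margins(counts: np.ndarray) -> np.ndarray:
    """Probit thresholds from category counts (assumed all positive)."""
    counts = np.asarray(counts, dtype=float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    if np.any(cum <= 0) or np.any(cum >= 1):
        raise ValueError("degenerate cumulative proportion (collapse categories first)")
    return ndtri(cum)


def _cell_probs(tau1: np.ndarray, tau2: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities on the threshold grid."""
    a = np.concatenate(([-np.inf], tau1, [np.inf]))
    b = np.concatenate(([-np.inf], tau2, [np.inf]))
    A, B = np.meshgrid(a, b, indexing="ij")
    F = bvn_cdf(A, B, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-12, None)


def _pair_nll(rho: float, table: np.ndarray, tau1: np.ndarray, tau2: np.ndarray) -> float:
    return -float(np.sum(table * np.log(_cell_probs(tau1, tau2, rho))))


def polychoric_pair(
    table: np.ndarray,
    tau1: np.ndarray | None = None,
    tau2: np.ndarray | None = None,
) -> float:
    """Two-step ML polychoric correlation from a two-way contingency table.

    Thresholds default to the probit of the table's margins; the
    estimate is clamped to ``+/-0.999``.
    """
    table = np.asarray(table, dtype=float)
    log: list[str] = []
    if tau1 is None or tau2 is None:
        r1, rec1 = _collapse_counts(table.sum(axis=1), "rows", log)
        r2, rec2 = _collapse_counts(table.sum(axis=0), "cols", log)
        if len(r1) < len(table) or len(r2) < table.shape[1]:
            coll = np.zeros((len(r1), len(r2)))
            for a in range(table.shape[0]):
                for b in range(table.shape[1]):
                    coll[rec1[a], rec2[b]] += table[a, b]
            table = coll
        tau1 = thresholds_from_margins(table.sum(axis=1))
        tau2 = thresholds_from_margins(table.sum(axis=0))
    res = minimize_scalar(
        _pair_nll,
        bounds=(-RHO_CLAMP, RHO_CLAMP),
        args=(table, tau1, tau2),
        method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    if rho > RHO_CLAMP - 1e-4:
        rho = RHO_CLAMP
    elif rho < -RHO_CLAMP + 1e-4:
        rho = -RHO_CLAMP
    return rho


def _pair_table(x: np.ndarray, y: np.ndarray, k1: int, k2: int) -> np.ndarray:
    ok = ~np.isnan(x) & ~np.isnan(y)
    xi = x[ok].astype(int)
    yi = y[ok].astype(int)
    table = np.zeros((k1, k2))
    np.add.at(table, (xi, yi), 1.0)
    return table


def _dP_dtau(tau1: np.ndarray, tau2: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic derivative of every cell probability w.r.t. each threshold.

    Returns ``(d1, d2)``: ``d1[c]`` is the cell-probability derivative
    matrix for ``tau1[c]`` and likewise ``d2`` for ``tau2``.
    """
    s = np.sqrt(1.0 - rho**2)
    b = np.concatenate(([-np.inf], tau2, [np.inf]))
    a = np.concatenate(([-np.inf], tau1, [np.inf]))
    # g1[c, j] = phi(tau1_c) * [Phi((b_{j+1}-rho tau1_c)/s) - Phi((b_j - rho tau1_c)/s)]
    ph1 = np.exp(-0.5 * tau1**2) / np.sqrt(2 * np.pi)
    z1 = (b[None, :] - rho * tau1[:, None]) / s
    cnd1 = ndtr(z1)
    g1 = ph1[:, None] * (cnd1[:, 1:] - cnd1[:, :-1])  # K1 x (K2+1)
    ph2 = np.exp(-0.5 * tau2**2) / np.sqrt(2 * np.pi)
    z2 = (a[None, :] - rho * tau2[:, None]) / s
    cnd2 = ndtr(z2)
    g2 = ph2[:, None] * (cnd2[:, 1:] - cnd2[:, :-1])  # K2 x (K1+1)
    K1, K2 = len(tau1), len(tau2)
    d1 = np.zeros((K1, K1 + 1, K2 + 1))
    for c in range(K1):
        d1[c, c, :] += g1[c]
        d1[c, c + 1, :] -= g1[c]
    d2 = np.zeros((K2, K1 + 1, K2 + 1))
    for c in range(K2):
        d2[c, :, c] += g2[c]
        d2[c, :, c + 1] -= g2[c]
    return d1, d2


def _pair_influence(
    xa: np.ndarray,
    xb: np.ndarray,
    tau1: np.ndarray,
    tau2: np.ndarray,
    rho: float,
    eps: float = 1e-4,
) -> np.ndarray:
    """Per-respondent influence contributions for one polychoric estimate.

    Accounts for the two-step procedure: the returned vector combines the
    correlation score with the propagated influence of the estimated
    thresholds.  Missing entries contribute zero; the scaling is such
    that the sum of squares estimates ``Var(rho_hat)``.
    """
    n_all = len(xa)
    ok = ~np.isnan(xa) & ~np.isnan(xb)
    ia = xa[ok].astype(int)
    ib = xb[ok].astype(int)
    n = ok.sum()
    rho = min(max(rho, -RHO_CLAMP + eps), RHO_CLAMP - eps)
    P = _cell_probs(tau1, tau2, rho)
    P_hi = _cell_probs(tau1, tau2, rho + eps)
    P_lo = _cell_probs(tau1, tau2, rho - eps)
    score = (np.log(P_hi) - np.log(P_lo)) / (2 * eps)  # dlogP/drho per cell
    table = np.zeros_like(P)
    np.add.at(table, (ia, ib), 1.0)
    info = float(np.sum(table * score**2)) / n  # per-observation information
    if info <= 0:
        return np.zeros(n_all)
    s_r = score[ia, ib]
    # threshold correction: H_k = d(mean score)/d tau_k, by FD over rho of
    # the analytic dlogP/dtau
    d1_hi, d2_hi = _dP_dtau(tau1, tau2, rho + eps)
    d1_lo, d2_lo = _dP_dtau(tau1, tau2, rho - eps)
    phat = table / n
    corr = np.zeros(n)
    for (d_hi, d_lo, taus, x, margin_axis) in (
        (d1_hi, d1_lo, tau1, ia, 1),
        (d2_hi, d2_lo, tau2, ib, 0),
    ):
        cum = np.cumsum(np.sum(phat, axis=margin_axis))[:-1]
        dens = np.exp(-0.5 * taus**2) / np.sqrt(2 * np.pi)
        for c in range(len(taus)):
            dlog_hi = d_hi[c] / P_hi
            dlog_lo = d_lo[c] / P_lo
            H = float(np.sum(phat * (dlog_hi - dlog_lo) / (2 * eps)))
            if_tau = ((x <= c).astype(float) - cum[c]) / dens[c]
            corr += H * if_tau
    psi = (s_r + corr) / info
    out = np.zeros(n_all)
    out[ok] = psi / n
    return out


def _nearest_psd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, eps, None)
    S = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


def polychoric_matrix(
    resp: ResponseMatrix,
    spec: InstrumentSpec,
    compute_weights: bool = True,
) -> PolychoricResult:
    """Full polychoric correlation matrix under pairwise deletion.

    Non-positive-semidefinite matrices are eigenvalue-clipped to the
    nearest PSD correlation matrix (logged via ``smoothed``).
    """
    resp.validate_against(spec)
    items = tuple(spec.items)
    X = resp.data[list(items)].to_numpy()
    n, p = X.shape
    log: list[str] = []
    # recode each item after collapsing empty categories
    tau: dict[str, np.ndarray] = {}
    ncat: dict[str, int] = {}
    Xr = X.copy()
    for j, it in enumerate(items):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"item {it!r} has no observed responses")
        counts = np.bincount(obs.astype(int), minlength=spec.n_categories).astype(float)
        coll, recode = _collapse_counts(counts, it, log)
        if len(coll) < 2:
            raise ValueError(f"item {it!r} has <2 observed categories")
        if len(coll) < len(counts):
            m = ~np.isnan(col)
            Xr[m, j] = recode[col[m].astype(int)]
        tau[it] = thresholds_from_margins(coll)
        ncat[it] = len(coll)
    R = np.eye(p)
    pairwise_n = np.full((p, p), float(n))
    iu = np.triu_indices(p, k=1)
    m = len(iu[0])
    inf = np.zeros((n, m), dtype=np.float32) if (compute_weights and n >= 50) else None
    if compute_weights and inf is None:
        warnings.warn("n < 50: unit DWLS weights substituted", stacklevel=2)
    for idx, (a, b) in enumerate(zip(*iu)):
        it_a, it_b = items[a], items[b]
        table = _pair_table(Xr[:, a], Xr[:, b], ncat[it_a], ncat[it_b])
        pairwise_n[a, b] = pairwise_n[b, a] = table.sum()
        rho = polychoric_pair(table, tau[it_a], tau[it_b])
        R[a, b] = R[b, a] = rho
        if inf is not None:
            inf[:, idx] = _pair_influence(Xr[:, a], Xr[:, b], tau[it_a], tau[it_b], rho)
    smoothed = False
    if np.linalg.eigvalsh(R).min() < 1e-6:
        R = _nearest_psd(R)
        smoothed = True
        log.append("correlation matrix not PSD; eigenvalue-clipped")
    if inf is not None:
        w = np.maximum(np.einsum("ij,ij->j", inf, inf, dtype=np.float64), WEIGHT_FLOOR)
    else:
        w = np.ones(m)
    return PolychoricResult(
        R=R,
        tau=tau,
        w=w,
        items=items,
        n=n,
        pairwise_n=pairwise_n,
        collapse_log=log,
        smoothed=smoothed,
        inf_funcs=inf,
    )


def acov_diag(resp: ResponseMatrix, poly: PolychoricResult) -> np.ndarray:
    """Per-correlation asymptotic variances (diagonal of the acov matrix).

    Estimated from per-respondent influence functions of the two-step
    estimator (correlation score plus propagated threshold influence),
    so the ``1/n`` scaling holds by construction.  Below ``n = 50``
    unit weights are substituted with a warning.
    """
    items = poly.items
    p = len(items)
    if poly.n < 50:
        warnings.warn("n < 50: unit DWLS weights substituted", stacklevel=2)
        return np.ones(p * (p - 1) // 2)
    X = resp.data[list(items)].to_numpy()
    iu = np.triu_indices(p, k=1)
    w = np.ones(len(iu[0]))
    for idx, (a, b) in enumerate(zip(*iu)):
        u = _pair_influence(X[:, a], X[:, b], poly.tau[items[a]], poly.tau[items[b]], poly.R[a, b])
        w[idx] = max(float(u @ u), WEIGHT_FLOOR)
    return w
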