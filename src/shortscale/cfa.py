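"""DWLS estimation of hierarchical ordinal factor models.

The measurement model is second-order: items load on facet factors,
facets load on domain factors, domains correlate freely.  Estimation is
on the correlation (latent-response) metric: the polychoric correlation
matrix is fitted by diagonally weighted least squares,

    F(theta) = sum_j (s_j - sigma_j(theta))^2 / w_j,

with ``s`` the non-redundant polychorics and ``w`` their asymptotic
variances.  Two identification modes are supported:

``tau_equivalent``
    All unstandardized first- and second-order loadings fixed to 1;
    domain variances, facet disturbances and domain covariances free.
    On the correlation metric the implied matrix is then block-constant
    (same facet: psi_d + zeta_f; same domain: psi_d; across domains:
    c_de), so the DWLS objective separates and its exact minimizer is a
    set of weighted block means, computed in closed form.

``congeneric``
    Loadings free, latent variances fixed to 1 (an identity rescaling of
    the marker parameterization); estimated by bounded L-BFGS-B with an
    analytic gradient.

Test statistics follow the mean-scaled chi-square convention:
``T = (n-1) F`` divided by ``c = tr(U Gamma) / df`` where ``Gamma`` is
the (diagonal) asymptotic covariance of the polychorics and ``U`` the
residual-projection weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instrument import InstrumentSpec
from .polychoric import PolychoricResult

__all__ = [
    "ModelSpec",
    "CFAParams",
    "CFAResults",
    "OrdinalFactorModel",
    "implied_corr",
    "fit_dwls",
    "scaled_chisq",
    "fit_indices",
    "standardized_solution",
    "detect_heywood",
]

Mode = Literal["tau_equivalent", "congeneric"]


@dataclass(frozen=True)
class ModelSpec:
    """Structure (item -> facet -> domain) plus identification mode."""

    spec: InstrumentSpec
    mode: Mode = "tau_equivalent"

    def __post_init__(self) -> None:
        if self.mode not in ("tau_equivalent", "congeneric"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class _Index:
    """Precomputed index arrays for one model structure."""

    fmap: np.ndarray  # item -> facet index
    dmap: np.ndarray  # facet -> domain index
    p: int
    nf: int
    nd: int
    iu: tuple[np.ndarray, np.ndarray]  # upper-triangle pair indices
    pair_kind: np.ndarray  # 0 same facet, 1 same domain, 2 cross domain
    pair_block: np.ndarray  # block id per pair (within kind-specific numbering)
    n_blocks: int
    block_param: list[tuple[str, int, int]]  # (kind, idx1, idx2) per block
    multi_facet_domain: np.ndarray  # bool per domain


def _build_index(spec: InstrumentSpec) -> _Index:
    fi = {f: k for k, f in enumerate(spec.facets)}
    di = {d: k for k, d in enumerate(spec.domains)}
    fmap_t = tuple(fi[spec.item_to_facet[i]] for i in spec.items)
    dmap_t = tuple(di[spec.facet_to_domain[f]] for f in spec.facets)
    # the index depends only on the facet/domain pattern, which is identical
    # for every 2-items-per-facet selection from one pool
    return _index_from_maps(fmap_t, dmap_t)


@lru_cache(maxsize=512)
def _index_from_maps(fmap_t: tuple, dmap_t: tuple) -> _Index:
    fmap = np.array(fmap_t)
    dmap = np.array(dmap_t)
    p, nf, nd = len(fmap), len(dmap), int(dmap.max()) + 1
    iu = np.triu_indices(p, k=1)
    fi_a, fi_b = fmap[iu[0]], fmap[iu[1]]
    di_a, di_b = dmap[fi_a], dmap[fi_b]
    same_facet = fi_a == fi_b
    same_domain = (di_a == di_b) & ~same_facet
    kind = np.where(same_facet, 0, np.where(same_domain, 1, 2))
    # block ids: facet blocks, domain blocks (multi-facet only), domain-pair blocks
    facet_count = np.bincount(dmap, minlength=nd)
    multi = facet_count >= 2
    blocks: list[tuple[str, int, int]] = []
    block_of: dict[tuple[str, int, int], int] = {}

    def _bid(key: tuple[str, int, int]) -> int:
        if key not in block_of:
            block_of[key] = len(blocks)
            blocks.append(key)
        return block_of[key]

    for f in range(nf):
        _bid(("facet", f, -1))
    for d in range(nd):
        if multi[d]:
            _bid(("domain", d, -1))
    for d in range(nd):
        for e in range(d + 1, nd):
            _bid(("dompair", d, e))
    pair_block = np.empty(len(iu[0]), dtype=int)
    for j in range(len(iu[0])):
        if kind[j] == 0:
            pair_block[j] = block_of[("facet", fi_a[j], -1)]
        elif kind[j] == 1:
            pair_block[j] = block_of[("domain", di_a[j], -1)]
        else:
            d, e = sorted((di_a[j], di_b[j]))
            pair_block[j] = block_of[("dompair", d, e)]
    return _Index(
        fmap=fmap,
        dmap=dmap,
        p=p,
        nf=nf,
        nd=nd,
        iu=iu,
        pair_kind=kind,
        pair_block=pair_block,
        n_blocks=len(blocks),
        block_param=blocks,
        multi_facet_domain=multi,
    )


@dataclass
class CFAParams:
    """Point estimates of one fitted (or constructed) model.

    Standardized quantities: ``a`` item-on-facet loadings, ``g``
    facet-on-domain loadings, ``phi`` domain correlations.  For the
    tau-equivalent mode the raw variance parameters are kept as well:
    ``psi`` domain variances, ``zeta`` facet disturbances, ``c`` domain
    covariances (``t = psi + zeta`` is the facet variance).
    """

    mode: Mode
    a: np.ndarray
    g: np.ndarray
    phi: np.ndarray
    psi: np.ndarray | None = None
    zeta: np.ndarray | None = None
    c: np.ndarray | None = None  # full nd x nd covariance (tau-equivalent)


def _implied_from_std(a: np.ndarray, g: np.ndarray, phi: np.ndarray, ix: _Index) -> np.ndarray:
    C = np.outer(g, g) * phi[np.ix_(ix.dmap, ix.dmap)]
    np.fill_diagonal(C, 1.0)
    S = np.outer(a, a) * C[np.ix_(ix.fmap, ix.fmap)]
    np.fill_diagonal(S, 1.0)
    return S


def implied_corr(params: CFAParams, model: ModelSpec) -> np.ndarray:
    """Model-implied correlation matrix (unit diagonal by construction).

    Communalities above 1 (|a| > 1 or out-of-range latent correlations)
    are legal inputs here; they are surfaced by :func:`detect_heywood`,
    not silently clipped.
    """
    ix = _build_index(model.spec)
    return _implied_from_std(np.asarray(params.a, float), np.asarray(params.g, float), np.asarray(params.phi, float), ix)


def detect_heywood(params: CFAParams) -> list[str]:
    """Flags for negative variances and out-of-range standardized values."""
    flags: list[str] = []
    a = np.asarray(params.a, float)
    for i, v in enumerate(a):
        if abs(v) > 1 + 1e-8:
            flags.append(f"item {i}: standardized loading {v:.3f} > 1 (negative uniqueness)")
    g = np.asarray(params.g, float)
    for f, v in enumerate(g):
        if np.isnan(v):
            flags.append(f"facet {f}: standardized loading undefined (negative variance)")
        elif abs(v) > 1 + 1e-8:
            flags.append(f"facet {f}: standardized loading {v:.3f} > 1 (negative disturbance)")
    phi = np.asarray(params.phi, float)
    nd = phi.shape[0]
    for d in range(nd):
        for e in range(d + 1, nd):
            if np.isnan(phi[d, e]):
                flags.append(f"domains ({d},{e}): latent correlation undefined")
            elif abs(phi[d, e]) > 1 + 1e-8:
                flags.append(f"domains ({d},{e}): latent correlation {phi[d, e]:.3f} outside [-1, 1]")
    if params.zeta is not None:
        for f, v in enumerate(params.zeta):
            if v < -1e-10:
                flags.append(f"facet {f}: negative disturbance variance {v:.4f}")
    if params.psi is not None:
        for d, v in enumerate(params.psi):
            if v < -1e-10:
                flags.append(f"domain {d}: negative variance {v:.4f}")
    return flags


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _fit_tau_equivalent(s: np.ndarray, w: np.ndarray, ix: _Index) -> tuple[CFAParams, np.ndarray, int]:
    """Exact DWLS minimizer for the tau-equivalent mode (weighted block means)."""
    invw = 1.0 / w
    num = np.bincount(ix.pair_block, weights=s * invw, minlength=ix.n_blocks)
    den = np.bincount(ix.pair_block, weights=invw, minlength=ix.n_blocks)
    vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    t = np.empty(ix.nf)
    psi = np.zeros(ix.nd)
    C = np.zeros((ix.nd, ix.nd))
    for b, (kind, i1, i2) in enumerate(ix.block_param):
        if kind == "facet":
            t[i1] = vals[b]
        elif kind == "domain":
            psi[i1] = vals[b]
        else:
            C[i1, i2] = C[i2, i1] = vals[b]
    # single-facet domains: psi tied to the facet variance (gamma = 1)
    for d in range(ix.nd):
        if not ix.multi_facet_domain[d]:
            f = int(np.where(ix.dmap == d)[0][0])
            psi[d] = t[f]
    np.fill_diagonal(C, psi)
    zeta = t - psi[ix.dmap]
    with np.errstate(invalid="ignore", divide="ignore"):
        a_f = np.sqrt(np.where(t >= 0, t, np.nan))
        g = np.sqrt(np.where((psi[ix.dmap] >= 0) & (t > 0), psi[ix.dmap] / t, np.nan))
        denom = np.sqrt(np.outer(psi, psi))
        phi = np.where(denom > 0, C / denom, np.nan)
    np.fill_diagonal(phi, 1.0)
    a = a_f[ix.fmap]
    # implied vector from block values directly (valid even if t < 0)
    sigma = vals[ix.pair_block]
    n_free = ix.n_blocks - int((~ix.multi_facet_domain).sum())  # tied psi are not free
    params = CFAParams(mode="tau_equivalent", a=a, g=g, phi=phi, psi=psi, zeta=zeta, c=C)
    return params, sigma, n_free


def _pack_congeneric(a, g, phi_od, ix: _Index) -> np.ndarray:
    return np.concatenate([a, g, phi_od])


def _unpack_congeneric(x: np.ndarray, ix: _Index):
    a = x[: ix.p]
    g = x[ix.p : ix.p + ix.nf]
    phi = np.eye(ix.nd)
    od = x[ix.p + ix.nf :]
    iu = np.triu_indices(ix.nd, k=1)
    phi[iu] = od
    phi[(iu[1], iu[0])] = od
    return a, g, phi


def _congeneric_objective(x: np.ndarray, s: np.ndarray, invw: np.ndarray, ix: _Index):
    a, g, phi = _unpack_congeneric(x, ix)
    C = np.outer(g, g) * phi[np.ix_(ix.dmap, ix.dmap)]
    np.fill_diagonal(C, 1.0)
    Cexp = C[np.ix_(ix.fmap, ix.fmap)]
    sigma = (np.outer(a, a) * Cexp)[ix.iu]
    e = s - sigma
    F = float(np.sum(e * e * invw))
    # gradient
    M = np.zeros((ix.p, ix.p))
    M[ix.iu] = e * invw
    M = M + M.T
    grad_a = -2.0 * ((M * Cexp) @ a)
    Amat = np.zeros((ix.p, ix.nf))
    Amat[np.arange(ix.p), ix.fmap] = a
    T = Amat.T @ M @ Amat  # facet-aggregated weighted residuals
    PhiD = phi[np.ix_(ix.dmap, ix.dmap)]
    Tp = T * PhiD
    np.fill_diagonal(Tp, 0.0)  # same-facet terms carry no g dependence
    grad_g = -2.0 * (Tp @ g)
    Gmat = np.zeros((ix.nf, ix.nd))
    Gmat[np.arange(ix.nf), ix.dmap] = g
    Tg = T.copy()
    np.fill_diagonal(Tg, 0.0)
    U = Gmat.T @ Tg @ Gmat
    iu_d = np.triu_indices(ix.nd, k=1)
    grad_phi = -2.0 * U[iu_d]
    return F, np.concatenate([grad_a, grad_g, grad_phi])


def _fit_congeneric(
    s: np.ndarray, w: np.ndarray, ix: _Index, start_loading: float = 0.7
) -> tuple[CFAParams, np.ndarray, int, bool]:
    invw = 1.0 / w
    n_phi = ix.nd * (ix.nd - 1) // 2
    x0 = np.concatenate(
        [np.full(ix.p, start_loading), np.full(ix.nf, start_loading), np.full(n_phi, 0.2)]
    )
    bounds = [(1e-3, 1.5)] * (ix.p + ix.nf) + [(-0.999, 0.999)] * n_phi
    res = optimize.minimize(
        _congeneric_objective,
        x0,
        args=(s, invw, ix),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    converged = bool(res.success)
    a, g, phi = _unpack_congeneric(res.x, ix)
    zeta = 1.0 - g**2
    params = CFAParams(
        mode="congeneric", a=a.copy(), g=g.copy(), phi=phi, psi=np.ones(ix.nd), zeta=zeta
    )
    sigma = _implied_from_std(a, g, phi, ix)[ix.iu]
    return params, sigma, len(x0), converged


def _jacobian_tau(ix: _Index) -> np.ndarray:
    """Free-parameter Jacobian for the tau-equivalent block design."""
    free_blocks = [
        b
        for b, (kind, i1, _) in enumerate(ix.block_param)
        if not (kind == "domain" and not ix.multi_facet_domain[i1])
    ]
    col_of = {b: j for j, b in enumerate(free_blocks)}
    m = len(ix.pair_block)
    J = np.zeros((m, len(free_blocks)))
    for j, b in enumerate(ix.pair_block):
        if b in col_of:
            J[j, col_of[b]] = 1.0
    return J


def _jacobian_fd(x: np.ndarray, ix: _Index, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the congeneric implied vector."""

    def _sig(xv):
        a, g, phi = _unpack_congeneric(xv, ix)
        return _implied_from_std(a, g, phi, ix)[ix.iu]

    m = len(ix.iu[0])
    J = np.empty((m, len(x)))
    for k in range(len(x)):
        xp = x.copy()
        xp[k] += eps
        xm = x.copy()
        xm[k] -= eps
        J[:, k] = (_sig(xp) - _sig(xm)) / (2 * eps)
    return J


def scaled_chisq(
    F: float,
    n: int,
    w_fit: np.ndarray,
    gamma: np.ndarray,
    J: np.ndarray | None,
    df: int,
    inf_funcs: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Mean-scaled test statistic ``(T, c, T_s)``.

    ``T = (n-1) F``; the scaling factor is ``c = tr(U Gamma)/df`` with
    ``Gamma = (n-1) * acov`` the asymptotic covariance of the fitted
    statistics and ``U = W - W J (J'WJ)^{-1} J'W`` the residual-
    projection weight (``W = diag(1/w_fit)``).  ``gamma`` supplies the
    acov diagonal; when the per-respondent influence matrix is available
    the projection term uses the full acov (``Gamma = IF'IF``) without
    materializing it, otherwise the diagonal approximation is used.
    When the fitting weights equal the asymptotic variances and Gamma is
    diagonal this reduces to ``T_s = F * df / (m - q)``.
    """
    T = (n - 1) * F
    if df <= 0:
        return T, 1.0, 0.0
    invw = 1.0 / w_fit
    g_scaled = (n - 1) * gamma
    tr_WG = float(np.sum(invw * g_scaled))
    tr_proj = 0.0
    if J is not None and J.size:
        A = J.T @ (invw[:, None] * J)
        if inf_funcs is not None:
            B = inf_funcs.astype(np.float64) @ (invw[:, None] * J)
            K = (n - 1) * (B.T @ B)
        else:
            K = J.T @ ((invw**2 * g_scaled)[:, None] * J)
        tr_proj = float(np.trace(np.linalg.solve(A, K)))
    c = max((tr_WG - tr_proj) / df, 1e-12)
    return T, c, T / c


def fit_indices(
    ts: float,
    df: int,
    ts_base: float,
    df_base: int,
    n: int,
    residuals: np.ndarray,
    compute_ci: bool = True,
) -> dict[str, float]:
    """CFI, RMSEA (with 90% CI by noncentral-chi-square inversion), SRMR."""
    d = max(ts - df, 0.0)
    d_b = max(ts_base - df_base, 0.0)
    cfi = 1.0 - (d / d_b if d_b > 0 else (0.0 if d == 0 else 1.0))
    cfi = float(min(max(cfi, 0.0), 1.0))
    lo = hi = 0.0
    if df > 0:
        rmsea = float(np.sqrt(d / (df * (n - 1))))
        if compute_ci:
            lo, hi = _rmsea_ci(ts, df, n)
    else:
        rmsea = 0.0
    srmr = float(np.sqrt(np.mean(residuals**2)))
    return {"cfi": cfi, "rmsea": rmsea, "rmsea_lo": lo, "rmsea_hi": hi, "srmr": srmr}


def _rmsea_ci(ts: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square CDF for the RMSEA 90% CI."""
    a = (1 - level) / 2

    def _nc(prob_target: float) -> float:
        # largest nc with cdf(ts; df, nc) >= prob_target (lower) etc.
        f = lambda nc: stats.ncx2.cdf(ts, df, nc) - prob_target
        if f(0.0) < 0:
            return 0.0
        hi = max(ts, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                break
        try:
            return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))
        except ValueError:
            return 0.0

    lam_lo = _nc(1 - a) if stats.chi2.cdf(ts, df) > 1 - a else 0.0
    lam_hi = _nc(a)
    scale = df * (n - 1)
    return float(np.sqrt(max(lam_lo, 0) / scale)), float(np.sqrt(max(lam_hi, 0) / scale))


def standardized_solution(params: CFAParams, model: ModelSpec | None = None) -> pd.DataFrame:
    """Standardized loadings table (items then facets); NaN where a
    negative variance makes standardization undefined (Heywood)."""
    rows = []
    for i, v in enumerate(params.a):
        rows.append({"level": "item", "index": i, "loading": float(v) if np.isfinite(v) else np.nan})
    for f, v in enumerate(params.g):
        rows.append({"level": "facet", "index": f, "loading": float(v) if np.isfinite(v) else np.nan})
    return pd.DataFrame(rows)


@dataclass
class CFAResults:
    """Estimates, fit statistics and diagnostics of one DWLS fit."""

    model: ModelSpec
    params: CFAParams
    F: float
    chisq: float
    scaling: float
    scaled_chisq: float
    df: int
    n: int
    indices: dict[str, float]
    residuals: np.ndarray
    implied: np.ndarray
    heywood: list[str]
    converged: bool

    @property
    def cfi(self) -> float:
        return self.indices["cfi"]

    @property
    def rmsea(self) -> float:
        return self.indices["rmsea"]

    @property
    def rmsea_ci(self) -> tuple[float, float]:
        if self.df > 0 and self.indices.get("rmsea_lo") is None:
            lo, hi = _rmsea_ci(self.scaled_chisq, self.df, self.n)
            self.indices["rmsea_lo"], self.indices["rmsea_hi"] = lo, hi
        return (self.indices.get("rmsea_lo") or 0.0, self.indices.get("rmsea_hi") or 0.0)

    @property
    def srmr(self) -> float:
        return self.indices["srmr"]

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Ordinal factor model (DWLS on polychoric correlations)",
            f"  mode: {self.model.mode}   items: {spec.n_items}   facets: {len(spec.facets)}"
            f"   domains: {len(spec.domains)}   n: {self.n}",
            f"  scaled chi2({self.df}) = {self.scaled_chisq:.2f}   scaling c = {self.scaling:.3f}",
            f"  CFI = {self.cfi:.3f}   RMSEA = {self.rmsea:.3f} "
            f"[{self.indices['rmsea_lo']:.3f}, {self.indices['rmsea_hi']:.3f}]   SRMR = {self.srmr:.3f}",
            f"  converged: {self.converged}   Heywood flags: {len(self.heywood)}",
        ]
        lines.append("  standardized item loadings (by facet):")
        for f, facet in enumerate(spec.facets):
            idx = [k for k, it in enumerate(spec.items) if spec.item_to_facet[it] == facet]
            lams = ", ".join(f"{self.params.a[k]:.3f}" for k in idx)
            lines.append(f"    {facet:<22} gamma={self.params.g[f]:.3f}  lambda=[{lams}]")
        for fl in self.heywood:
            lines.append(f"  ! {fl}")
        return "\n".join(lines)


class OrdinalFactorModel:
    """Second-order ordinal CFA, statsmodels-style.

    Parameters
    ----------
    poly : PolychoricResult
        Input statistics (polychoric correlations, thresholds, DWLS
        weights), e.g. from :func:`shortscale.polychoric.polychoric_matrix`.
    spec : InstrumentSpec
        Item/facet/domain structure to fit (must match ``poly.items``).
    mode : {"tau_equivalent", "congeneric"}

    Examples
    --------
    >>> poly = polychoric_matrix(resp, spec)           # doctest: +SKIP
    >>> res = OrdinalFactorModel(poly, spec).fit()     # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, poly: PolychoricResult, spec: InstrumentSpec, mode: Mode = "tau_equivalent"):
        if tuple(poly.items) != tuple(spec.items):
            poly = poly.subset(list(spec.items))
        self.poly = poly
        self.model_spec = ModelSpec(spec=spec, mode=mode)
        self._ix = _build_index(spec)

    @classmethod
    def from_responses(cls, resp, spec: InstrumentSpec, mode: Mode = "tau_equivalent"):
        from .polychoric import polychoric_matrix

        return cls(polychoric_matrix(resp, spec), spec, mode=mode)

    def fit(self, fast: bool = False) -> CFAResults:
        """Estimate the model.

        With ``fast=True`` the scaling factor uses the diagonal
        asymptotic-covariance approximation and the RMSEA CI is deferred
        until first access — appropriate inside search loops where only
        the relative ordering of fit indices matters.
        """
        ix = self._ix
        s = self.poly.vech()
        w = self.poly.w
        n = self.poly.n
        m = len(s)
        converged = True
        if self.model_spec.mode == "tau_equivalent":
            params, sigma, q = _fit_tau_equivalent(s, w, ix)
            J = None if fast else _jacobian_tau(ix)
        else:
            params, sigma, q, converged = _fit_congeneric(s, w, ix)
            if not converged:  # one deterministic fallback restart
                params2, sigma2, q, conv2 = _fit_congeneric(s, w, ix, start_loading=0.4)
                if conv2:
                    params, sigma, converged = params2, sigma2, True
            if fast:
                J = None
            else:
                x = _pack_congeneric(params.a, params.g, params.phi[np.triu_indices(ix.nd, k=1)], ix)
                J = _jacobian_fd(x, ix)
        e = s - sigma
        F = float(np.sum(e * e / w))
        df = m - q
        F_b = float(np.sum(s * s / w))
        df_b = m
        if fast:
            # with fitting weights equal to the acov diagonal and the diagonal
            # Gamma approximation the scaling collapses to T_s = F exactly
            T, c, Ts = (n - 1) * F, float(n - 1), F
            Ts_b = F_b
        else:
            T, c, Ts = scaled_chisq(F, n, w, w, J, df, inf_funcs=self.poly.inf_funcs)
            _, _, Ts_b = scaled_chisq(F_b, n, w, w, None, df_b)
        idx = fit_indices(Ts, df, Ts_b, df_b, n, e, compute_ci=not fast)
        if fast:
            idx["rmsea_lo"] = idx["rmsea_hi"] = None
        heywood = detect_heywood(params)
        implied = np.eye(ix.p)
        implied[ix.iu] = sigma
        implied = implied + implied.T - np.eye(ix.p)
        return CFAResults(
            model=self.model_spec,
            params=params,
            F=F,
            chisq=T,
            scaling=c,
            scaled_chisq=Ts,
            df=df,
            n=n,
            indices=idx,
            residuals=e,
            implied=implied,
            heywood=heywood,
            converged=converged,
        )


def fit_dwls(poly: PolychoricResult, model: ModelSpec) -> CFAResults:
    """Functional wrapper: fit ``model`` to precomputed polychoric statistics."""
    return OrdinalFactorModel(poly, model.spec, mode=model.mode).fit()
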