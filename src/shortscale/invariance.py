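"""Measurement-invariance ladder for multi-group ordinal factor models.

Four nested models of increasing cross-group restriction are fitted to
each group's polychoric correlations *and* probit thresholds:

1. **Configural** — structure equal, all parameters group-specific;
   thresholds saturated.  (Identification: latent variances fixed to 1
   per group, an identity rescaling of marker loadings.)
2. **Equal thresholds** (and latent intercepts) — one shared threshold
   vector; non-reference groups gain free item scale factors and latent
   domain means.
3. **+ equal loadings** — first- and second-order loadings shared (in
   the reference group's metric); non-reference groups gain free latent
   (co)variances instead.
4. **+ equal item residual variances** — item uniquenesses shared, so
   the non-reference scale factors become model-implied.

A level "passes" relative to the previous one iff Delta-CFI < .01,
Delta-SRMR < .01 and the two RMSEA 90% CIs overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr

from .cfa import ModelSpec, OrdinalFactorModel, _build_index, _implied_from_std
from .instrument import InstrumentSpec, ResponseMatrix
from .polychoric import PolychoricResult, polychoric_matrix

__all__ = ["InvarianceLadder", "InvarianceReport", "fit_ladder", "compare_levels"]

LEVEL_NAMES = {
    1: "configural",
    2: "equal thresholds",
    3: "equal thresholds + loadings",
    4: "equal thresholds + loadings + residuals",
}


@dataclass
class _GroupStats:
    label: str
    poly: PolychoricResult
    tauhat: np.ndarray  # concatenated per-item thresholds
    wtau: np.ndarray  # their variances
    inf_ext: np.ndarray | None  # n x (n_pairs + n_thresh) influence matrix
    n: int


def _threshold_influence(X: np.ndarray, tau: dict[str, np.ndarray], items) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold estimates' influence contributions, variances, and values."""
    cols = []
    taus = []
    n = X.shape[0]
    for j, it in enumerate(items):
        x = X[:, j]
        obs = ~np.isnan(x)
        nj = obs.sum()
        t = tau[it]
        dens = np.exp(-0.5 * t**2) / np.sqrt(2 * np.pi)
        cum = ndtr(t)
        for c, tc in enumerate(t):
            u = np.zeros(n)
            u[obs] = ((x[obs] <= c).astype(float) - cum[c]) / (dens[c] * nj)
            cols.append(u)
            taus.append(tc)
    U = np.column_stack(cols)
    w = np.einsum("ij,ij->j", U, U)
    return np.asarray(taus), np.maximum(w, 1e-10), U


def _group_stats(resp: ResponseMatrix, spec: InstrumentSpec, label: str) -> _GroupStats:
    poly = polychoric_matrix(resp, spec)
    K = spec.n_categories - 1
    for it in spec.items:
        if len(poly.tau[it]) != K:
            raise ValueError(
                f"group {label!r}: item {it!r} has collapsed categories; the invariance "
                "ladder requires every category observed in every group"
            )
    X = resp.data[list(spec.items)].to_numpy()
    tauhat, wtau, U_tau = _threshold_influence(X, poly.tau, spec.items)
    inf_ext = None
    if poly.inf_funcs is not None:
        inf_ext = np.column_stack([poly.inf_funcs.astype(np.float64), U_tau])
    return _GroupStats(label=label, poly=poly, tauhat=tauhat, wtau=wtau, inf_ext=inf_ext, n=resp.n)


@dataclass
class _LevelFit:
    level: int
    F: float
    df: int
    chisq: float
    scaling: float
    scaled_chisq: float
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    converged: bool
    heywood: list[str] = field(default_factory=list)
    params: np.ndarray | None = None


@dataclass
class InvarianceReport:
    """Per-level fits, adjacent-level deltas and verdicts."""

    levels: dict[int, _LevelFit]
    deltas: dict[int, dict[str, float]] = field(default_factory=dict)
    verdicts: dict[int, bool] = field(default_factory=dict)

    @property
    def highest_level_passed(self) -> int:
        out = 1
        for lv in (2, 3, 4):
            if self.verdicts.get(lv):
                out = lv
            else:
                break
        return out

    def nesting_ok(self, rtol: float = 1e-6) -> bool:
        """Discrepancy must be non-decreasing up the ladder."""
        Fs = [self.levels[lv].F for lv in sorted(self.levels)]
        return all(Fs[k + 1] >= Fs[k] - rtol * (1 + Fs[k]) for k in range(len(Fs) - 1))

    def summary(self) -> str:
        lines = ["Measurement-invariance ladder (ordinal, DWLS)"]
        for lv in sorted(self.levels):
            f = self.levels[lv]
            lines.append(
                f"  M{lv} {LEVEL_NAMES[lv]:<40} chi2s({f.df})={f.scaled_chisq:8.1f}  "
                f"CFI={f.cfi:.3f}  RMSEA={f.rmsea:.3f} [{f.rmsea_ci[0]:.3f},{f.rmsea_ci[1]:.3f}]  "
                f"SRMR={f.srmr:.3f}"
            )
            if lv in self.verdicts:
                d = self.deltas[lv]
                lines.append(
                    f"      dCFI={d['cfi']:+.4f} dSRMR={d['srmr']:+.4f} "
                    f"CI overlap={d['ci_overlap'] == 1.0}  -> {'pass' if self.verdicts[lv] else 'FAIL'}"
                )
        lines.append(f"  highest level passed: {self.highest_level_passed}")
        return "\n".join(lines)


class InvarianceLadder:
    """Fit the four-model invariance ladder across respondent groups.

    Parameters
    ----------
    resp : ResponseMatrix
        Responses with a group label per respondent (``resp.group``), or
        pass ``groups`` explicitly.
    spec : InstrumentSpec
        The (short-form) structure whose invariance is examined.
    """

    def __init__(
        self,
        resp: ResponseMatrix,
        spec: InstrumentSpec,
        groups: np.ndarray | None = None,
    ):
        labels = groups if groups is not None else (None if resp.group is None else resp.group.to_numpy())
        if labels is None:
            raise ValueError("group labels required (resp.group or groups=)")
        labels = np.asarray(labels)
        self.spec = spec
        self.ix = _build_index(spec)
        self.group_labels = [str(v) for v in _unique_stable(labels)]
        if len(self.group_labels) < 2:
            raise ValueError("need >= 2 groups")
        self.stats: list[_GroupStats] = []
        for gl in self.group_labels:
            sub = resp.subset_rows(labels == gl)
            self.stats.append(_group_stats(sub, spec, gl))
        self.N = sum(st.n for st in self.stats)

    # -- parameter bookkeeping ----------------------------------------------
    def _layout(self, level: int):
        ix = self.ix
        p, nf, nd = ix.p, ix.nf, ix.nd
        npair = len(ix.iu[0])
        nphi = nd * (nd - 1) // 2
        K = self.spec.n_categories - 1
        nt = p * K
        G = len(self.stats)
        blocks: list[tuple[str, int, tuple[float, float], float]] = []

        def add(name, size, bounds, start):
            blocks.append((name, size, bounds, start))

        if level == 2:
            for g in range(G):
                add(f"a{g}", p, (1e-3, 1.5), 0.7)
                add(f"g{g}", nf, (1e-3, 1.5), 0.7)
                add(f"phi{g}", nphi, (-0.999, 0.999), 0.2)
        else:  # levels 3 and 4: shared loadings in reference metric
            add("a0", p, (1e-3, 1.5), 0.7)
            add("g0", nf, (1e-3, 1.5), 0.7)
            add("phi0", nphi, (-0.999, 0.999), 0.2)
            for g in range(1, G):
                add(f"psi{g}", nd, (1e-4, 5.0), 1.0)
                add(f"zeta{g}", nf, (-0.5, 5.0), 0.4)
                add(f"phi{g}", nphi, (-0.999, 0.999), 0.2)
        add("t", nt, (-6.0, 6.0), 0.0)
        for g in range(1, G):
            if level < 4:
                add(f"s{g}", p, (0.2, 5.0), 1.0)
            add(f"alpha{g}", nd, (-3.0, 3.0), 0.0)
        slices = {}
        off = 0
        for name, size, _, _ in blocks:
            slices[name] = slice(off, off + size)
            off += size
        return blocks, slices, off, npair, nt

    def _implied(self, x: np.ndarray, level: int, slices):
        """Per-group (implied correlations vech, implied thresholds)."""
        ix = self.ix
        p, nf = ix.p, ix.nf
        K = self.spec.n_categories - 1
        G = len(self.stats)
        t = x[slices["t"]]
        out = []
        if level == 2:
            for g in range(G):
                a = x[slices[f"a{g}"]]
                gg = x[slices[f"g{g}"]]
                phi = _phi_mat(x[slices[f"phi{g}"]], ix.nd)
                sigma = _implied_from_std(a, gg, phi, ix)[ix.iu]
                if g == 0:
                    tim = t
                else:
                    s = x[slices[f"s{g}"]]
                    alpha = x[slices[f"alpha{g}"]]
                    m = a * gg[ix.fmap] * alpha[ix.dmap[ix.fmap]]
                    tim = (t.reshape(p, K) / s[:, None] - m[:, None]).ravel()
                out.append((sigma, tim))
            return out
        # levels 3-4
        b = x[slices["a0"]]
        h = x[slices["g0"]]
        phi0 = _phi_mat(x[slices["phi0"]], ix.nd)
        sigma0 = _implied_from_std(b, h, phi0, ix)[ix.iu]
        out.append((sigma0, t))
        for g in range(1, G):
            psi = x[slices[f"psi{g}"]]
            zeta = x[slices[f"zeta{g}"]]
            phi = _phi_mat(x[slices[f"phi{g}"]], ix.nd)
            alpha = x[slices[f"alpha{g}"]]
            covd = np.sqrt(np.outer(psi, psi)) * phi
            np.fill_diagonal(covd, psi)
            C = np.outer(h, h) * covd[np.ix_(ix.dmap, ix.dmap)]
            vfac = h**2 * psi[ix.dmap] + zeta
            np.fill_diagonal(C, vfac)
            cov_items = np.outer(b, b) * C[np.ix_(ix.fmap, ix.fmap)]
            if level == 4:
                s = np.sqrt(np.maximum(b**2 * vfac[ix.fmap] + (1.0 - b**2), 1e-6))
            else:
                s = x[slices[f"s{g}"]]
            sigma = (cov_items / np.outer(s, s))[ix.iu]
            m = b * h[ix.fmap] * alpha[ix.dmap[ix.fmap]]
            tim = ((t.reshape(p, K) - m[:, None]) / s[:, None]).ravel()
            out.append((sigma, tim))
        return out

    def _objective(self, x: np.ndarray, level: int, slices) -> float:
        F = 0.0
        for st, (sigma, tim) in zip(self.stats, self._implied(x, level, slices)):
            e = st.poly.vech() - sigma
            F += float(np.sum(e * e / st.poly.w))
            et = st.tauhat - tim
            F += float(np.sum(et * et / st.wtau))
        return F

    # -- fitting -------------------------------------------------------------
    def _fit_configural(self) -> tuple[_LevelFit, list]:
        from .cfa import scaled_chisq

        fits = []
        F = 0.0
        df = 0
        T = 0.0
        tr = 0.0
        T_b = 0.0
        tr_b = 0.0
        df_b = 0
        res_all = []
        for st in self.stats:
            r = OrdinalFactorModel(st.poly, self.spec, mode="congeneric").fit()
            fits.append(r)
            F += r.F
            df += r.df
            T += r.chisq
            tr += r.scaling * r.df
            s = st.poly.vech()
            Fb_g = float(np.sum(s * s / st.poly.w))
            T_b += (st.n - 1) * Fb_g
            df_b += len(s)
            _, c_bg, _ = scaled_chisq(Fb_g, st.n, st.poly.w, st.poly.w, None, len(s), st.poly.inf_funcs)
            tr_b += c_bg * len(s)
            res_all.append(r.residuals)
        c = max(tr / df, 1e-12)
        Ts = T / c
        c_b = max(tr_b / df_b, 1e-12)
        Ts_b = T_b / c_b
        idx = _combined_indices(Ts, df, Ts_b, df_b, self.N, np.concatenate(res_all))
        heywood = [f"{st.label}: {fl}" for st, r in zip(self.stats, fits) for fl in r.heywood]
        lf = _LevelFit(
            level=1,
            F=F,
            df=df,
            chisq=T,
            scaling=c,
            scaled_chisq=Ts,
            cfi=idx["cfi"],
            rmsea=idx["rmsea"],
            rmsea_ci=(idx["rmsea_lo"], idx["rmsea_hi"]),
            srmr=idx["srmr"],
            converged=all(r.converged for r in fits),
        )
        lf.heywood = heywood
        self._baseline = (Ts_b, df_b)
        return lf, fits

    def _start(self, level: int, blocks, slices, nparams, configural_fits, prev: np.ndarray | None, prev_level: int | None, prev_slices) -> np.ndarray:
        x0 = np.empty(nparams)
        for name, size, _, start in blocks:
            x0[slices[name]] = start
        # thresholds: precision-weighted mean of the group estimates
        num = sum(st.tauhat / st.wtau for st in self.stats)
        den = sum(1.0 / st.wtau for st in self.stats)
        x0[slices["t"]] = num / den
        if level == 2:
            for g, r in enumerate(configural_fits):
                x0[slices[f"a{g}"]] = np.clip(r.params.a, 1e-3, 1.5)
                x0[slices[f"g{g}"]] = np.clip(np.nan_to_num(r.params.g, nan=0.7), 1e-3, 1.5)
                x0[slices[f"phi{g}"]] = np.clip(
                    r.params.phi[np.triu_indices(self.ix.nd, k=1)], -0.999, 0.999
                )
        else:
            r0 = configural_fits[0]
            x0[slices["a0"]] = np.clip(r0.params.a, 1e-3, 1.5)
            x0[slices["g0"]] = np.clip(np.nan_to_num(r0.params.g, nan=0.7), 1e-3, 1.5)
            x0[slices["phi0"]] = np.clip(r0.params.phi[np.triu_indices(self.ix.nd, k=1)], -0.999, 0.999)
            for g in range(1, len(self.stats)):
                x0[slices[f"zeta{g}"]] = np.clip(
                    1.0 - np.nan_to_num(configural_fits[g].params.g, nan=0.7) ** 2, -0.4, 5.0
                )
                x0[slices[f"phi{g}"]] = np.clip(
                    configural_fits[g].params.phi[np.triu_indices(self.ix.nd, k=1)], -0.999, 0.999
                )
        if prev is not None and prev_slices is not None:
            # carry identically-named blocks over from the previous level
            for name, size, _, _ in blocks:
                if name in prev_slices and prev_slices[name].stop - prev_slices[name].start == size:
                    x0[slices[name]] = prev[prev_slices[name]]
        return x0

    def _stage_thresholds(self, x0: np.ndarray, level: int, slices) -> np.ndarray:
        """Cheap pre-optimization of the threshold block (t, s, alpha).

        The threshold residuals couple to the correlation parameters only
        through the latent-mean paths, so optimizing them alone (loadings
        held at their configural values) lands very close to the joint
        optimum and makes the joint polish fast.
        """
        ix = self.ix
        p = ix.p
        K = self.spec.n_categories - 1
        G = len(self.stats)
        names = ["t"] + [f"s{g}" for g in range(1, G) if f"s{g}" in slices] + [
            f"alpha{g}" for g in range(1, G)
        ]
        sl_local = {}
        off = 0
        for nm in names:
            size = slices[nm].stop - slices[nm].start
            sl_local[nm] = slice(off, off + size)
            off += size
        # loading products per item for the latent-mean path, per group
        ell = []
        for g in range(G):
            if level == 2:
                a = x0[slices[f"a{g}"]]
                gg = x0[slices[f"g{g}"]]
            else:
                a = x0[slices["a0"]]
                gg = x0[slices["g0"]]
            ell.append(a * gg[ix.fmap])

        def fth(z):
            t = z[sl_local["t"]]
            F = float(np.sum((self.stats[0].tauhat - t) ** 2 / self.stats[0].wtau))
            for g in range(1, G):
                s = z[sl_local[f"s{g}"]] if f"s{g}" in sl_local else np.ones(p)
                alpha = z[sl_local[f"alpha{g}"]]
                m = ell[g] * alpha[ix.dmap[ix.fmap]]
                tim = (t.reshape(p, K) / s[:, None] - m[:, None]).ravel()
                et = self.stats[g].tauhat - tim
                F += float(np.sum(et * et / self.stats[g].wtau))
            return F

        z0 = np.concatenate([x0[slices[nm]] for nm in names])
        bounds = []
        for nm in names:
            if nm == "t":
                bounds += [(-6.0, 6.0)] * (sl_local[nm].stop - sl_local[nm].start)
            elif nm.startswith("s"):
                bounds += [(0.2, 5.0)] * (sl_local[nm].stop - sl_local[nm].start)
            else:
                bounds += [(-3.0, 3.0)] * (sl_local[nm].stop - sl_local[nm].start)
        res = optimize.minimize(
            fth, z0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500, "ftol": 1e-12}
        )
        out = x0.copy()
        for nm in names:
            out[slices[nm]] = res.x[sl_local[nm]]
        return out

    def _fit_level(self, level: int, configural_fits, prev=None, prev_level=None, prev_slices=None) -> tuple[_LevelFit, np.ndarray, dict]:
        blocks, slices, nparams, npair, nt = self._layout(level)
        x0 = self._start(level, blocks, slices, nparams, configural_fits, prev, prev_level, prev_slices)
        x0 = self._stage_thresholds(x0, level, slices)
        bounds = []
        for name, size, bnd, _ in blocks:
            bounds += [bnd] * size
        res = optimize.minimize(
            self._objective,
            x0,
            args=(level, slices),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 400, "maxfun": 300000, "ftol": 1e-9, "gtol": 1e-7},
        )
        x = res.x
        F = float(res.fun)
        m_tot = len(self.stats) * (npair + nt)
        df = m_tot - nparams
        T = (self.N - 1) * F
        c, srmr = self._scaling_and_srmr(x, level, slices, nparams, df)
        Ts = T / c
        Ts_b, df_b = self._baseline
        res_corr = []
        for st, (sigma, _) in zip(self.stats, self._implied(x, level, slices)):
            res_corr.append(st.poly.vech() - sigma)
        idx = _combined_indices(Ts, df, Ts_b, df_b, self.N, np.concatenate(res_corr))
        heywood = self._heywood(x, level, slices)
        lf = _LevelFit(
            level=level,
            F=F,
            df=df,
            chisq=T,
            scaling=c,
            scaled_chisq=Ts,
            cfi=idx["cfi"],
            rmsea=idx["rmsea"],
            rmsea_ci=(idx["rmsea_lo"], idx["rmsea_hi"]),
            srmr=idx["srmr"],
            converged=bool(res.success),
            heywood=heywood,
            params=x,
        )
        return lf, x, slices

    def _heywood(self, x, level, slices) -> list[str]:
        flags = []
        if level >= 3:
            b = x[slices["a0"]]
            for g in range(1, len(self.stats)):
                psi = x[slices[f"psi{g}"]]
                zeta = x[slices[f"zeta{g}"]]
                vfac = x[slices["g0"]] ** 2 * psi[self.ix.dmap] + zeta
                if level == 4:
                    s = np.sqrt(np.maximum(b**2 * vfac[self.ix.fmap] + (1.0 - b**2), 1e-6))
                else:
                    s = x[slices[f"s{g}"]]
                theta = s**2 - b**2 * vfac[self.ix.fmap]
                for i in np.where(theta < -1e-8)[0]:
                    flags.append(f"group {g}: item {i} negative residual variance {theta[i]:.4f}")
                for f in np.where(zeta < -1e-8)[0]:
                    flags.append(f"group {g}: facet {f} negative disturbance {zeta[f]:.4f}")
        return flags

    def _scaling_and_srmr(self, x, level, slices, nparams, df) -> tuple[float, float]:
        # FD Jacobian of the stacked implied vector
        eps = 1e-6
        m_g = []

        def stacked(xv):
            segs = []
            for (sigma, tim) in self._implied(xv, level, slices):
                segs.append(sigma)
                segs.append(tim)
            return np.concatenate(segs)

        base = stacked(x)
        J = np.empty((len(base), nparams))
        for k in range(nparams):
            xp = x.copy()
            xp[k] += eps
            J[:, k] = (stacked(xp) - base) / eps
        w_all = []
        for st in self.stats:
            w_all.append(st.poly.w)
            w_all.append(st.wtau)
        w = np.concatenate(w_all)
        invw = 1.0 / w
        A = J.T @ (invw[:, None] * J)
        tr_WG = 0.0
        Ksum = np.zeros((nparams, nparams))
        off = 0
        for st in self.stats:
            mg = len(st.poly.w) + len(st.wtau)
            Jg = J[off : off + mg]
            invw_g = invw[off : off + mg]
            gamma_g = w[off : off + mg]  # acov estimates; fitting weights equal them
            tr_WG += (self.N - 1) * float(np.sum(invw_g * gamma_g))
            if st.inf_ext is not None:
                B = st.inf_ext @ (invw_g[:, None] * Jg)
                Ksum += (self.N - 1) * (B.T @ B)
            else:
                Ksum += Jg.T @ ((invw_g**2 * gamma_g * (self.N - 1))[:, None] * Jg)
            off += mg
        try:
            tr_proj = float(np.trace(np.linalg.solve(A, Ksum)))
        except np.linalg.LinAlgError:
            tr_proj = float(np.trace(np.linalg.lstsq(A, Ksum, rcond=None)[0]))
        c = max((tr_WG - tr_proj) / df, 1e-12)
        # SRMR over correlation residuals only
        res_corr = []
        for st, (sigma, _) in zip(self.stats, self._implied(x, level, slices)):
            res_corr.append(st.poly.vech() - sigma)
        srmr = float(np.sqrt(np.mean(np.concatenate(res_corr) ** 2)))
        return c, srmr

    def fit(self, levels: tuple[int, ...] = (1, 2, 3, 4)) -> InvarianceReport:
        """Fit the requested ladder levels (adjacent, starting at 1).

        Fitting only ``(1, 2)`` is enough to test threshold invariance
        and is much cheaper than the full ladder.
        """
        lf1, configural_fits = self._fit_configural()
        out = {1: lf1}
        prev_x, prev_slices, prev_level = None, None, None
        for lv in (2, 3, 4):
            if lv not in levels:
                break
            lf, prev_x, prev_slices = self._fit_level(
                lv, configural_fits, prev=prev_x, prev_level=prev_level, prev_slices=prev_slices
            )
            prev_level = lv
            out[lv] = lf
            if not lf.converged:
                warnings.warn(f"level {lv} did not fully converge; ladder continues", stacklevel=2)
        report = InvarianceReport(levels=out)
        compare_levels(report)
        return report


def compare_levels(report: InvarianceReport) -> dict[int, bool]:
    """Apply the Delta criteria between adjacent levels (in place)."""
    for lv in (2, 3, 4):
        if lv not in report.levels or (lv - 1) not in report.levels:
            continue
        prev, cur = report.levels[lv - 1], report.levels[lv]
        dcfi = prev.cfi - cur.cfi
        dsrmr = cur.srmr - prev.srmr
        lo1, hi1 = prev.rmsea_ci
        lo2, hi2 = cur.rmsea_ci
        overlap = (lo1 <= hi2) and (lo2 <= hi1)
        report.deltas[lv] = {"cfi": dcfi, "srmr": dsrmr, "ci_overlap": float(overlap)}
        report.verdicts[lv] = (dcfi < 0.01) and (dsrmr < 0.01) and overlap
    return report.verdicts


def fit_ladder(
    resp: ResponseMatrix,
    spec: InstrumentSpec,
    groups: np.ndarray | None = None,
    model: ModelSpec | None = None,
) -> InvarianceReport:
    """Functional wrapper around :class:`InvarianceLadder`."""
    return InvarianceLadder(resp, spec, groups=groups).fit()


def _combined_indices(ts, df, ts_b, df_b, n, residuals) -> dict[str, float]:
    from .cfa import fit_indices

    return fit_indices(ts, df, ts_b, df_b, n, residuals)


def _phi_mat(od: np.ndarray, nd: int) -> np.ndarray:
    phi = np.eye(nd)
    iu = np.triu_indices(nd, k=1)
    phi[iu] = od
    phi[(iu[1], iu[0])] = od
    return phi


def _unique_stable(values: np.ndarray) -> list:
    seen = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen
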