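"""MAX-MIN ant system search over two-items-per-facet selections.

Every candidate short form picks exactly 2 items per facet from the item
pool.  Each item carries a pheromone level; an "ant" samples one pair
per facet with probability proportional to pheromone, the resulting
model is fitted by DWLS and scored by a weighted sum of logistic-
transformed psychometric statistics, and after each iteration pheromone
evaporates while the global-best solution deposits its objective value
on its items.  Pheromone is clamped to [phi_min, phi_max] with
``phi_max = best/(1-rho)``; the floor phi_min follows the standard
MAX-MIN schedule, chosen so the converged state reconstructs the
incumbent with a target probability (``p_best``), and pheromones are
re-initialized on stagnation, which prevents premature convergence.

Two stock objectives mirror common practice: objective A combines CFI,
RMSEA, SRMR and mean reliability (McDonald's omega); objective B
combines CFI, RMSEA, mean omega, the minimum first-/second-order
standardized loading and the mean part-whole correlation between the
short facet scales and their full-pool counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cfa import CFAResults, OrdinalFactorModel
from .instrument import InstrumentSpec, ResponseMatrix, score_scales
from .polychoric import PolychoricResult, polychoric_matrix

__all__ = [
    "LogisticComponent",
    "ObjectiveSpec",
    "ACOConfig",
    "PheromoneState",
    "SelectionSolution",
    "EvaluationContext",
    "sample_solution",
    "evaluate_objective",
    "update_pheromones",
    "run_aco",
]

Selection = dict[str, tuple[str, str]]


@dataclass(frozen=True)
class LogisticComponent:
    """One objective component: statistic, orientation, logistic transform."""

    stat: str  # cfi | rmsea | srmr | mean_omega | min_loading | part_whole
    midpoint: float
    slope: float
    increasing: bool
    weight: float = 1.0

    def transform(self, x: float) -> float:
        z = self.slope * (x - self.midpoint)
        if not self.increasing:
            z = -z
        # numerically safe logistic
        return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weighted sum of logistic-transformed components."""

    components: tuple[LogisticComponent, ...]
    name: str = "custom"

    @classmethod
    def objective_a(cls) -> "ObjectiveSpec":
        """Model fit (CFI, RMSEA, SRMR) plus mean facet/domain omega."""
        return cls(
            name="A",
            components=(
                LogisticComponent("cfi", 0.95, 100.0, True),
                LogisticComponent("rmsea", 0.05, 100.0, False),
                LogisticComponent("srmr", 0.06, 100.0, False),
                LogisticComponent("mean_omega", 0.70, 30.0, True),
            ),
        )

    @classmethod
    def objective_b(cls) -> "ObjectiveSpec":
        """Fit, reliability, minimum loading and part-whole correlation."""
        return cls(
            name="B",
            components=(
                LogisticComponent("cfi", 0.95, 100.0, True),
                LogisticComponent("rmsea", 0.05, 100.0, False),
                LogisticComponent("mean_omega", 0.70, 30.0, True),
                LogisticComponent("min_loading", 0.50, 20.0, True),
                LogisticComponent("part_whole", 0.80, 30.0, True),
            ),
        )

    @property
    def max_value(self) -> float:
        return float(sum(c.weight for c in self.components))

    def value(self, stats: dict[str, float]) -> float:
        return float(sum(c.weight * c.transform(stats[c.stat]) for c in self.components))


@dataclass(frozen=True)
class ACOConfig:
    """Search constants of the MAX-MIN ant system.

    ``p_best`` sets the pheromone floor: phi_min is chosen so that, at
    full convergence, the probability of reconstructing the incumbent
    solution is about ``p_best`` (the standard MAX-MIN floor schedule).
    With ``p_best=None`` the simpler ``phi_min = phi_max/(2*pool size)``
    floor is used instead; it explores more aggressively and is only
    suitable for small pools.
    """

    n_ants: int = 16
    max_iterations: int = 300
    evaporation_retention: float = 0.95  # phi <- rho * phi each iteration
    stagnation_window: int = 30  # iterations without improvement -> stop
    deposit: str = "global_best"  # or "iteration_best"
    p_best: float | None = 0.05
    max_restarts: int = 2  # pheromone re-initializations before giving up
    improvement_tol: float = 1e-3  # smaller gains do not reset stagnation

    def __post_init__(self) -> None:
        if not 0 < self.evaporation_retention < 1:
            raise ValueError("evaporation retention must be in (0, 1)")
        if self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if self.p_best is not None and not 0 < self.p_best < 1:
            raise ValueError("p_best must be in (0, 1)")

    def scaled_for(self, pool: InstrumentSpec) -> "ACOConfig":
        """Budget scaled to the search-space size (long horizons for
        large pools); returns self when the defaults already suffice."""
        n_choices = sum(len(pool.facet_items(f)) for f in pool.facets)
        if n_choices <= 2 * len(pool.facets) + 20:
            return self
        factor = max(1, n_choices // 30)
        return replace(
            self,
            max_iterations=max(self.max_iterations, 700 * factor),
            stagnation_window=max(self.stagnation_window, 60 * factor),
            max_restarts=max(self.max_restarts, 3),
        )


@dataclass
class PheromoneState:
    """Per-facet, per-candidate-item pheromone levels with MAX-MIN bounds."""

    pheromone: dict[str, np.ndarray]  # facet -> level per candidate item
    candidates: dict[str, tuple[str, ...]]
    phi_min: float = 0.02
    phi_max: float = 1.0
    iteration: int = 0
    best_value: float = -np.inf
    best_selection: Selection | None = None

    @classmethod
    def initial(cls, pool: InstrumentSpec) -> "PheromoneState":
        cands = {f: pool.facet_items(f) for f in pool.facets}
        for f, its in cands.items():
            if len(its) < 2:
                raise ValueError(f"facet {f!r} has fewer than 2 candidate items")
        return cls(
            pheromone={f: np.ones(len(its)) for f, its in cands.items()},
            candidates=cands,
        )

    def clamp(self) -> None:
        for f in self.pheromone:
            np.clip(self.pheromone[f], self.phi_min, self.phi_max, out=self.pheromone[f])


@dataclass
class SelectionSolution:
    """A 2-items-per-facet selection with its evaluation record."""

    selection: Selection
    objective: float
    components: dict[str, float] = field(default_factory=dict)
    train_fit: CFAResults | None = None
    test_fit: CFAResults | None = None
    omegas: dict[str, float] = field(default_factory=dict)
    part_whole: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def items(self) -> tuple[str, ...]:
        out: list[str] = []
        for f in self.selection:
            out.extend(self.selection[f])
        return tuple(out)


def _fast_mean_omega(fit: CFAResults) -> float:
    """Mean of facet and domain (total) omegas, vectorized and tolerant of
    inadmissible loadings (clipped) — the search-objective variant of
    :func:`shortscale.reliability.omega_report`."""
    from .cfa import _build_index

    ix = _build_index(fit.model.spec)
    a = np.clip(np.nan_to_num(fit.params.a, nan=0.0), -1.0, 1.0)
    suml = np.bincount(ix.fmap, weights=a, minlength=ix.nf)
    sumth = np.bincount(ix.fmap, weights=1 - a**2, minlength=ix.nf)
    om_f = suml**2 / (suml**2 + sumth)
    dmap_items = ix.dmap[ix.fmap]
    S = fit.implied
    om_d = np.empty(ix.nd)
    for d in range(ix.nd):
        idx = np.where(dmap_items == d)[0]
        var_sum = S[np.ix_(idx, idx)].sum()
        om_d[d] = (var_sum - np.sum(1 - a[idx] ** 2)) / var_sum
    return float(np.mean(np.concatenate([om_f, om_d])))


def sample_solution(state: PheromoneState, rng: np.random.Generator) -> Selection:
    """Draw 2 distinct items per facet, sequentially, proportional to pheromone."""
    sel: Selection = {}
    for f, its in state.candidates.items():
        phi = state.pheromone[f]
        p = phi / phi.sum()
        first = rng.choice(len(its), p=p)
        rest = np.delete(np.arange(len(its)), first)
        p2 = phi[rest] / phi[rest].sum()
        second = rest[rng.choice(len(rest), p=p2)]
        a, b = sorted((first, second))  # canonical pool order
        sel[f] = (its[a], its[b])
    return sel


class EvaluationContext:
    """Precomputed statistics shared by all objective evaluations.

    Holds the pool polychoric result, the full-pool facet scores (for
    part-whole correlations) and a cache keyed by the selected item set,
    so repeated solutions cost nothing.
    """

    def __init__(
        self,
        data: ResponseMatrix,
        pool: InstrumentSpec,
        mode: str = "tau_equivalent",
        poly: PolychoricResult | None = None,
    ):
        self.pool = pool
        self.mode = mode
        self.poly = poly if poly is not None else polychoric_matrix(data, pool)
        self.full_scores = score_scales(data, pool)
        self.item_data = data.data[list(pool.items)]
        self._X = self.item_data.to_numpy(dtype=float)
        self._col = {it: j for j, it in enumerate(pool.items)}
        self._facet_full = {
            f: self.full_scores.facet[f].to_numpy(dtype=float) for f in pool.facets
        }
        self._has_nan = bool(np.isnan(self._X).any())
        if not self._has_nan:
            # precompute centered Gram statistics so each part-whole
            # correlation is O(1): r = (d_i + d_j) / (|fc| sqrt(G_ii+2G_ij+G_jj))
            Xc = self._X - self._X.mean(axis=0)
            self._gram = Xc.T @ Xc
            self._dot = np.empty(len(pool.items))
            self._fnorm = {}
            for f in pool.facets:
                fc = self._facet_full[f] - self._facet_full[f].mean()
                self._fnorm[f] = float(np.sqrt(fc @ fc))
                for it in pool.facet_items(f):
                    j = self._col[it]
                    self._dot[j] = float(Xc[:, j] @ fc)
        self._cache: dict[tuple, tuple[float, dict, CFAResults | None]] = {}

    def part_whole(self, selection: Selection) -> dict[str, float]:
        out = {}
        for f, pair in selection.items():
            i, j = (self._col[it] for it in pair)
            if not self._has_nan:
                num = self._dot[i] + self._dot[j]
                den = self._fnorm[f] * np.sqrt(
                    self._gram[i, i] + 2 * self._gram[i, j] + self._gram[j, j]
                )
                out[f] = float(num / den)
                continue
            short = self._X[:, [i, j]].mean(axis=1)
            full = self._facet_full[f]
            ok = ~np.isnan(short) & ~np.isnan(full)
            short, full = short[ok], full[ok]
            sc = short - short.mean()
            fc = full - full.mean()
            out[f] = float((sc @ fc) / np.sqrt((sc @ sc) * (fc @ fc)))
        return out

    def evaluate(
        self, selection: Selection, objective: ObjectiveSpec
    ) -> tuple[float, dict[str, float], CFAResults | None]:
        key = (objective, frozenset(it for pair in selection.values() for it in pair))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        items = [it for f in self.pool.facets if f in selection for it in selection[f]]
        sub = self.pool.subset(items)
        fit = OrdinalFactorModel(
            self.poly.subset(list(sub.items), with_inf=False), sub, mode=self.mode
        ).fit(fast=True)
        if not fit.converged:
            result = (0.0, {"nonconverged": 1.0}, fit)
            self._cache[key] = result
            return result
        # Heywood solutions are scored (the components still rank them) and
        # flagged; the inadmissibility exclusion happens at final ranking.
        stats: dict[str, float] = {
            "cfi": fit.cfi,
            "rmsea": fit.rmsea,
            "srmr": fit.srmr,
        }
        needed = {c.stat for c in objective.components}
        if "mean_omega" in needed:
            stats["mean_omega"] = _fast_mean_omega(fit)
        if "min_loading" in needed:
            a = fit.params.a[np.isfinite(fit.params.a)]
            g = fit.params.g[np.isfinite(fit.params.g)]
            stats["min_loading"] = float(min(a.min() if a.size else 0.0, g.min() if g.size else 0.0))
        if "part_whole" in needed:
            stats["part_whole"] = float(np.mean(list(self.part_whole(selection).values())))
        value = objective.value(stats)
        if fit.heywood:
            stats = {**stats, "heywood": 1.0}
        result = (value, stats, fit)
        self._cache[key] = result
        return result


def evaluate_objective(
    sol: Selection,
    context: EvaluationContext,
    objective: ObjectiveSpec,
) -> tuple[float, dict[str, float], CFAResults | None]:
    """Objective value and component report for one selection.

    Non-converged or Heywood-flagged fits score the worst value (0).
    """
    return context.evaluate(sol, objective)


def update_pheromones(
    state: PheromoneState,
    iteration_best: tuple[Selection, float],
    global_best: tuple[Selection, float],
    config: ACOConfig,
) -> PheromoneState:
    """Evaporate, deposit on the best solution's items, clamp to bounds."""
    rho = config.evaporation_retention
    sel, value = global_best if config.deposit == "global_best" else iteration_best
    state.phi_max = value / (1 - rho) if value > 0 else state.phi_max
    if config.p_best is not None:
        # floor such that the converged state reconstructs the incumbent
        # with probability ~ p_best (q per item pick, 2 picks per facet)
        q = config.p_best ** (1.0 / (2 * len(state.candidates)))
        ratio = {
            f: (1 - q) / (q * max(len(c) - 2, 1)) for f, c in state.candidates.items()
        }
    else:
        ratio = {f: 1.0 / (2 * len(c)) for f, c in state.candidates.items()}
    phi_min_all = state.phi_max
    for f in state.pheromone:
        state.pheromone[f] *= rho
        phi_min_f = state.phi_max * min(ratio[f], 0.5)
        phi_min_all = min(phi_min_all, phi_min_f)
        if f in sel:
            for it in sel[f]:
                j = state.candidates[f].index(it)
                state.pheromone[f][j] += value
        np.clip(state.pheromone[f], phi_min_f, state.phi_max, out=state.pheromone[f])
    state.phi_min = phi_min_all
    state.iteration += 1
    return state


def run_aco(
    context: EvaluationContext,
    objective: ObjectiveSpec,
    config: ACOConfig = ACOConfig(),
    seed: int = 0,
) -> tuple[SelectionSolution, list[dict]]:
    """Full MAX-MIN ant system run; returns the global best and a trace.

    The trace records, per iteration, the iteration-best and global-best
    objective values.  A run stops after ``stagnation_window`` iterations
    without global-best improvement, or at ``max_iterations``.
    """
    rng = np.random.default_rng(seed)
    state = PheromoneState.initial(context.pool)
    trace: list[dict] = []
    since_improvement = 0
    restarts = 0
    # deposits follow the best solution since the last pheromone
    # re-initialization; the overall best across restarts is what is returned
    restart_best_val = -np.inf
    restart_best_sel: Selection | None = None
    degenerate = all(len(c) == 2 for c in state.candidates.values())
    for it in range(config.max_iterations):
        iter_best_val = -np.inf
        iter_best_sel: Selection | None = None
        for _ in range(config.n_ants):
            sel = sample_solution(state, rng)
            val, _, _ = context.evaluate(sel, objective)
            if val > iter_best_val:
                iter_best_val, iter_best_sel = val, sel
        # stagnation is judged against the current restart's own best, so a
        # re-initialized search gets a full horizon even when it has not yet
        # beaten the overall best; noise-level gains do not reset the clock
        if iter_best_val > restart_best_val:
            if iter_best_val > restart_best_val + config.improvement_tol:
                since_improvement = 0
            else:
                since_improvement += 1
            restart_best_val, restart_best_sel = iter_best_val, iter_best_sel
        else:
            since_improvement += 1
        if iter_best_val > state.best_value + 1e-12:
            state.best_value = iter_best_val
            state.best_selection = iter_best_sel
        update_pheromones(
            state, (iter_best_sel, iter_best_val), (restart_best_sel, restart_best_val), config
        )
        trace.append(
            {"iteration": it, "iteration_best": iter_best_val, "global_best": state.best_value}
        )
        if degenerate:
            break
        if since_improvement >= config.stagnation_window:
            if restarts >= config.max_restarts:
                break
            # re-initialize pheromones; the next deposits follow the new
            # restart's own best so the search is not pulled straight back
            restarts += 1
            since_improvement = 0
            restart_best_val, restart_best_sel = -np.inf, None
            for f in state.pheromone:
                state.pheromone[f] = np.full(len(state.candidates[f]), state.phi_max)
    value, components, fit = context.evaluate(state.best_selection, objective)
    return (
        SelectionSolution(
            selection=state.best_selection,
            objective=value,
            components=components,
            train_fit=fit,
            part_whole=context.part_whole(state.best_selection),
            provenance={"seed": seed, "iterations": len(trace), "objective": objective.name},
        ),
        trace,
    )
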