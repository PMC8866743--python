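"""End-to-end short-form construction.

The procedure mirrors standard algorithmic scale shortening: the sample
is split into stratified training and test partitions; two objective
variants of the ant-colony search are each run several times on the
training data; the runs' solutions are re-evaluated on the test data and
the best three are compared facet by facet; facet item-pairs replicated
at least twice are fixed, the remainder enumerated exhaustively
("brute force") over the candidate items occurring in the top solutions;
the resulting candidates are ranked on test-set fit, excluding any with
Heywood cases.  Semantic (content-validity) judgment of the top-ranked
candidates is deliberately left to the user.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .aco import (
    ACOConfig,
    EvaluationContext,
    ObjectiveSpec,
    Selection,
    SelectionSolution,
    run_aco,
)
from .cfa import OrdinalFactorModel
from .instrument import InstrumentSpec, ResponseMatrix
from .reliability import omega_report

__all__ = [
    "ConsensusReport",
    "PipelineResult",
    "ShortFormPipeline",
    "count_solution_space",
    "split_train_test",
    "run_multistart",
    "consensus",
    "brute_force_completion",
    "final_rank",
]


def count_solution_space(pool_sizes) -> int:
    """Exact number of 2-items-per-facet selections: prod C(size, 2)."""
    total = 1
    for k in pool_sizes:
        if k < 2:
            raise ValueError("every facet pool needs >= 2 items")
        total *= math.comb(k, 2)
    return total


def split_train_test(
    resp: ResponseMatrix,
    ratio: float = 0.30,
    strata: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train_mask, test_mask).

    ``ratio`` is the test fraction.  Within each stratum the test count
    follows largest-remainder rounding of ``ratio * n_stratum``, so the
    stratum composition of the full sample is preserved in both splits
    to within one respondent per stratum.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = resp.n
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    test = np.zeros(n, dtype=bool)
    labels = np.unique(strata)
    # largest-remainder allocation of the total test count across strata
    quotas = {}
    rema = {}
    total_test = int(round(ratio * n))
    for s in labels:
        ns = int((strata == s).sum())
        if ns < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 respondents")
        exact = ratio * ns
        quotas[s] = int(np.floor(exact))
        rema[s] = exact - np.floor(exact)
    short = total_test - sum(quotas.values())
    for s in sorted(rema, key=rema.get, reverse=True)[: max(short, 0)]:
        quotas[s] += 1
    for s in labels:
        idx = np.where(strata == s)[0]
        chosen = rng.choice(idx, size=quotas[s], replace=False)
        test[chosen] = True
    return ~test, test


@dataclass
class ConsensusReport:
    """Facet-level agreement among the top solutions."""

    resolved: dict[str, tuple[str, str]]  # facet -> replicated pair
    unresolved: dict[str, tuple[str, ...]]  # facet -> union of candidate items

    @property
    def all_resolved(self) -> bool:
        return not self.unresolved


def consensus(top_solutions: list[SelectionSolution]) -> ConsensusReport:
    """Fix facet pairs replicated in >= 2 of the top solutions.

    Unresolved facets carry the union of their items across the top
    solutions as the brute-force candidate set.
    """
    if len(top_solutions) < 2:
        raise ValueError("consensus needs >= 2 solutions")
    facets = list(top_solutions[0].selection)
    resolved: dict[str, tuple[str, str]] = {}
    unresolved: dict[str, tuple[str, ...]] = {}
    for f in facets:
        pairs = [frozenset(s.selection[f]) for s in top_solutions]
        counts: dict[frozenset, int] = {}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
        best_pair, best_count = max(counts.items(), key=lambda kv: kv[1])
        if best_count >= 2:
            resolved[f] = tuple(sorted(best_pair))
        else:
            cand = sorted({it for p in pairs for it in p})
            unresolved[f] = tuple(cand)
    return ConsensusReport(resolved=resolved, unresolved=unresolved)


def _solution_from_selection(
    sel: Selection,
    context: EvaluationContext,
    objective: ObjectiveSpec,
    provenance: dict,
) -> SelectionSolution:
    value, components, fit = context.evaluate(sel, objective)
    sol = SelectionSolution(
        selection=sel,
        objective=value,
        components=components,
        train_fit=fit,
        part_whole=context.part_whole(sel),
        provenance=provenance,
    )
    if fit is not None and fit.converged:
        sol.omegas = omega_report(fit, strict=False).facet
    return sol


def evaluate_on_test(
    sol: SelectionSolution, test_context: EvaluationContext
) -> SelectionSolution:
    """Attach the test-split fit of a solution's model."""
    items = list(sol.items)
    sub = test_context.pool.subset(items)
    sol.test_fit = OrdinalFactorModel(
        test_context.poly.subset(list(sub.items)), sub, mode=test_context.mode
    ).fit()
    return sol


def _test_sort_key(s: SelectionSolution):
    f = s.test_fit
    return (-f.cfi, f.rmsea, f.srmr)


def run_multistart(
    train_context: EvaluationContext,
    test_context: EvaluationContext,
    objectives: dict[str, ObjectiveSpec] | None = None,
    runs_per_algorithm: int = 3,
    seed: int = 0,
    config: ACOConfig = ACOConfig(),
) -> list[SelectionSolution]:
    """All algorithm x run searches, each evaluated on the test split.

    Returns the solutions sorted by test fit (CFI, then RMSEA, then
    SRMR).  Child seeds are spawned deterministically from ``seed``;
    identical child seeds (possible only through a custom config)
    trigger a misconfiguration warning.
    """
    if objectives is None:
        objectives = {"A": ObjectiveSpec.objective_a(), "B": ObjectiveSpec.objective_b()}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(objectives) * runs_per_algorithm)
    solutions = []
    k = 0
    seen: dict[tuple[str, int], None] = {}
    for name, obj in objectives.items():
        for run in range(runs_per_algorithm):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            if (name, child_seed) in seen:
                warnings.warn(f"duplicate seed {child_seed} within algorithm {name}", stacklevel=2)
            seen[(name, child_seed)] = None
            sol, _ = run_aco(train_context, obj, config=config, seed=child_seed)
            sol.provenance.update({"algorithm": name, "run": run})
            solutions.append(evaluate_on_test(sol, test_context))
    solutions.sort(key=_test_sort_key)
    return solutions


def brute_force_completion(
    context: EvaluationContext,
    report: ConsensusReport,
    objective: ObjectiveSpec,
    cap: int = 100_000,
) -> list[SelectionSolution]:
    """Enumerate every candidate-pair combination for unresolved facets.

    Resolved facets stay fixed; the Cartesian product over the
    unresolved facets' candidate pairs is fitted in full.  Exceeding
    ``cap`` combinations raises with advice to tighten candidates.
    """
    if report.all_resolved:
        sel = dict(report.resolved)
        return [_solution_from_selection(sel, context, objective, {"stage": "consensus"})]
    pair_options = {
        f: list(itertools.combinations(cands, 2)) for f, cands in report.unresolved.items()
    }
    n_comb = math.prod(len(v) for v in pair_options.values())
    if n_comb > cap:
        raise ValueError(
            f"{n_comb} combinations exceed the enumeration cap ({cap}); tighten the candidate sets"
        )
    facets = list(pair_options)
    out = []
    for combo in itertools.product(*(pair_options[f] for f in facets)):
        sel = dict(report.resolved)
        for f, pair in zip(facets, combo):
            sel[f] = pair
        out.append(
            _solution_from_selection(sel, context, objective, {"stage": "brute_force"})
        )
    return out


def final_rank(
    candidates: list[SelectionSolution], test_context: EvaluationContext
) -> list[SelectionSolution]:
    """Rank candidates on the test split, dropping Heywood-flagged fits.

    Order: CFI (desc), RMSEA (asc), mean facet omega (desc).  The
    content-validity judgment among the leading candidates is a human
    step and is not automated here.
    """
    fitted = [evaluate_on_test(s, test_context) for s in candidates]
    admissible = [s for s in fitted if s.test_fit is not None and not s.test_fit.heywood]
    if not admissible:
        warnings.warn("all candidates carry Heywood flags in the test data", stacklevel=2)
        return []

    def key(s: SelectionSolution):
        mean_omega = float(np.mean(list(s.omegas.values()))) if s.omegas else 0.0
        return (-s.test_fit.cfi, s.test_fit.rmsea, -mean_omega)

    return sorted(admissible, key=key)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    solutions: list[SelectionSolution]
    top3: list[SelectionSolution]
    consensus: ConsensusReport
    candidates: list[SelectionSolution]
    ranking: list[SelectionSolution]
    train_mask: np.ndarray
    test_mask: np.ndarray

    @property
    def best(self) -> SelectionSolution | None:
        return self.ranking[0] if self.ranking else None


class ShortFormPipeline:
    """Orchestrated search: split -> multi-run ACO -> consensus -> rank.

    Parameters
    ----------
    resp : ResponseMatrix
        Pool responses (all samples pooled; strata via ``resp.group``).
    pool : InstrumentSpec
        The full item pool with its facet/domain structure.
    mode : str
        CFA identification mode used throughout (default tau-equivalent,
        i.e. all unstandardized loadings fixed to 1).
    test_ratio : float
        Test fraction for the stratified split (default 0.30).
    """

    def __init__(
        self,
        resp: ResponseMatrix,
        pool: InstrumentSpec,
        mode: str = "tau_equivalent",
        test_ratio: float = 0.30,
        runs_per_algorithm: int = 3,
        aco_config: ACOConfig = ACOConfig(),
    ):
        self.resp = resp
        self.pool = pool
        self.mode = mode
        self.test_ratio = test_ratio
        self.runs_per_algorithm = runs_per_algorithm
        self.aco_config = aco_config

    def run(self, seed: int = 0) -> PipelineResult:
        strata = None if self.resp.group is None else self.resp.group.to_numpy()
        train_mask, test_mask = split_train_test(
            self.resp, ratio=self.test_ratio, strata=strata, seed=seed
        )
        train = self.resp.subset_rows(train_mask)
        test = self.resp.subset_rows(test_mask)
        train_context = EvaluationContext(train, self.pool, mode=self.mode)
        test_context = EvaluationContext(test, self.pool, mode=self.mode)
        solutions = run_multistart(
            train_context,
            test_context,
            runs_per_algorithm=self.runs_per_algorithm,
            seed=seed,
            config=self.aco_config,
        )
        top3 = solutions[:3]
        rep = consensus(top3)
        obj_a = ObjectiveSpec.objective_a()
        try:
            candidates = brute_force_completion(train_context, rep, obj_a)
        except ValueError:
            # candidate sets too wide to enumerate: tighten by dropping to
            # the best two solutions, then to the single best
            rep = consensus(top3[:2])
            try:
                candidates = brute_force_completion(train_context, rep, obj_a)
            except ValueError:
                rep = ConsensusReport(resolved=dict(top3[0].selection), unresolved={})
                candidates = brute_force_completion(train_context, rep, obj_a)
        ranking = final_rank(candidates, test_context)
        return PipelineResult(
            solutions=solutions,
            top3=top3,
            consensus=rep,
            candidates=candidates,
            ranking=ranking,
            train_mask=train_mask,
            test_mask=test_mask,
        )
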