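"""Instrument specifications, response matrices, and scale scoring.

An *instrument* is a hierarchical trait inventory: items are nested in
facets (first-order traits) and facets in domains (second-order traits).
Responses are ordinal category codes ``0 .. n_categories-1``; missing
responses are represented as ``NaN``.

Facet scores are means of observed item responses, domain scores are
unweighted means of facet scores, and the total score is the mean of all
facet scores.  Means (rather than sums) keep short and long forms of the
same instrument on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InstrumentSpec",
    "ResponseMatrix",
    "ScaleScores",
    "load_instrument",
    "read_responses",
    "score_scales",
    "z_standardize",
]

#: column-name prefixes distinguishing non-item columns in delimited files
GROUP_PREFIX = "group:"
CRITERION_PREFIX = "crit:"


@dataclass(frozen=True)
class InstrumentSpec:
    """Item -> facet -> domain hierarchy of an ordinal instrument.

    Parameters
    ----------
    items : sequence of str
        Item identifiers, in reporting order.
    item_to_facet : mapping
        Facet label for every item.
    facet_to_domain : mapping
        Domain label for every facet.
    n_categories : int
        Number of response categories; codes run ``0 .. n_categories-1``.
    """

    items: tuple[str, ...]
    item_to_facet: Mapping[str, str]
    facet_to_domain: Mapping[str, str]
    n_categories: int = 4
    facets: tuple[str, ...] = field(init=False)
    domains: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        items = tuple(self.items)
        if len(set(items)) != len(items):
            raise ValueError("duplicate item IDs in instrument spec")
        missing = [i for i in items if i not in self.item_to_facet]
        if missing:
            raise ValueError(f"items without a facet assignment: {missing}")
        extra = [i for i in self.item_to_facet if i not in set(items)]
        if extra:
            raise ValueError(f"facet assignment for unknown items: {extra}")
        # stable facet order: first appearance in item order
        facets: list[str] = []
        for it in items:
            f = self.item_to_facet[it]
            if f not in facets:
                facets.append(f)
        orphan = [f for f in facets if f not in self.facet_to_domain]
        if orphan:
            raise ValueError(f"facets without a domain assignment: {orphan}")
        unknown = [f for f in self.facet_to_domain if f not in facets]
        if unknown:
            raise ValueError(f"domain assignment for unknown facets: {unknown}")
        for f in facets:
            k = sum(1 for it in items if self.item_to_facet[it] == f)
            if k < 2:
                raise ValueError(f"facet {f!r} has {k} item(s); need >= 2")
        domains: list[str] = []
        for f in facets:
            d = self.facet_to_domain[f]
            if d not in domains:
                domains.append(d)
        object.__setattr__(self, "items", items)
        object.__setattr__(self, "facets", tuple(facets))
        object.__setattr__(self, "domains", tuple(domains))

    # -- convenience lookups -------------------------------------------------
    def facet_items(self, facet: str) -> tuple[str, ...]:
        return tuple(i for i in self.items if self.item_to_facet[i] == facet)

    def domain_facets(self, domain: str) -> tuple[str, ...]:
        return tuple(f for f in self.facets if self.facet_to_domain[f] == domain)

    def item_domain(self, item: str) -> str:
        return self.facet_to_domain[self.item_to_facet[item]]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def subset(self, keep_items: Sequence[str]) -> "InstrumentSpec":
        """Spec restricted to ``keep_items`` (e.g. a short-form selection)."""
        keep = set(keep_items)
        unknown = keep - set(self.items)
        if unknown:
            raise ValueError(f"unknown items: {sorted(unknown)}")
        items = tuple(i for i in self.items if i in keep)
        facets = {self.item_to_facet[i] for i in items}
        return InstrumentSpec(
            items=items,
            item_to_facet={i: self.item_to_facet[i] for i in items},
            facet_to_domain={f: d for f, d in self.facet_to_domain.items() if f in facets},
            n_categories=self.n_categories,
        )


@dataclass
class ResponseMatrix:
    """Respondent x item ordinal responses plus optional metadata.

    ``data`` holds one float column per item (integer category codes, NaN
    for missing); ``group`` is an optional per-respondent label and
    ``criteria`` optional continuous external criterion variables.
    """

    data: pd.DataFrame
    group: pd.Series | None = None
    criteria: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("response matrix needs >= 1 respondent")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        obs = vals[~np.isnan(vals)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise ValueError("responses must be non-negative integer category codes")
        if self.group is not None:
            self.group = pd.Series(self.group, index=self.data.index)
        if self.criteria is not None:
            self.criteria = pd.DataFrame(self.criteria, index=self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def items(self) -> list[str]:
        return list(self.data.columns)

    def validate_against(self, spec: InstrumentSpec) -> None:
        missing = [i for i in spec.items if i not in self.data.columns]
        if missing:
            raise ValueError(f"spec items absent from response matrix: {missing}")
        vals = self.data[list(spec.items)].to_numpy()
        obs = vals[~np.isnan(vals)]
        if obs.size and obs.max() > spec.n_categories - 1:
            raise ValueError("response codes exceed n_categories-1")

    def subset_rows(self, mask: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            data=self.data.loc[mask].copy(),
            group=None if self.group is None else self.group.loc[mask].copy(),
            criteria=None if self.criteria is None else self.criteria.loc[mask].copy(),
        )

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        raw = pd.read_csv(path, index_col=0)
        group_cols = [c for c in raw.columns if c.startswith(GROUP_PREFIX)]
        crit_cols = [c for c in raw.columns if c.startswith(CRITERION_PREFIX)]
        item_cols = [c for c in raw.columns if c not in group_cols + crit_cols]
        group = raw[group_cols[0]] if group_cols else None
        criteria = raw[crit_cols].rename(columns=lambda c: c[len(CRITERION_PREFIX):]) if crit_cols else None
        return cls(data=raw[item_cols], group=group, criteria=criteria)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.group is not None:
            out[GROUP_PREFIX + "sample"] = self.group
        if self.criteria is not None:
            for c in self.criteria.columns:
                out[CRITERION_PREFIX + c] = self.criteria[c]
        out.to_csv(path)


def read_responses(path) -> ResponseMatrix:
    """Read a delimited response file (header of item IDs, blank = missing)."""
    return ResponseMatrix.from_csv(path)


@dataclass
class ScaleScores:
    """Facet, domain and total scores per respondent (category-scale units)."""

    facet: pd.DataFrame
    domain: pd.DataFrame
    total: pd.Series
    spec: InstrumentSpec


def load_instrument(spec_doc) -> InstrumentSpec:
    """Build a validated :class:`InstrumentSpec` from a config document.

    ``spec_doc`` may be a mapping or a path to a YAML file with keys
    ``n_categories`` and ``structure`` (domain -> facet -> [item IDs]),
    or flat keys ``items`` / ``item_to_facet`` / ``facet_to_domain``.
    """
    if not isinstance(spec_doc, Mapping):
        with open(spec_doc) as fh:
            spec_doc = yaml.safe_load(fh)
    n_categories = int(spec_doc.get("n_categories", 4))
    if "structure" in spec_doc:
        items: list[str] = []
        item_to_facet: dict[str, str] = {}
        facet_to_domain: dict[str, str] = {}
        for domain, facets in spec_doc["structure"].items():
            for facet, its in facets.items():
                if facet in facet_to_domain:
                    raise ValueError(f"facet {facet!r} assigned to two domains")
                facet_to_domain[facet] = domain
                for it in its:
                    if it in item_to_facet:
                        raise ValueError(f"item {it!r} assigned to two facets")
                    item_to_facet[it] = facet
                    items.append(it)
    else:
        items = list(spec_doc["items"])
        item_to_facet = dict(spec_doc["item_to_facet"])
        facet_to_domain = dict(spec_doc["facet_to_domain"])
    return InstrumentSpec(
        items=tuple(items),
        item_to_facet=item_to_facet,
        facet_to_domain=facet_to_domain,
        n_categories=n_categories,
    )


def instrument_to_doc(spec: InstrumentSpec) -> dict:
    """Inverse of :func:`load_instrument` (nested ``structure`` form)."""
    structure: dict[str, dict[str, list[str]]] = {}
    for d in spec.domains:
        structure[d] = {f: list(spec.facet_items(f)) for f in spec.domain_facets(d)}
    return {"n_categories": spec.n_categories, "structure": structure}


def score_scales(
    resp: ResponseMatrix,
    spec: InstrumentSpec,
    min_item_coverage: float = 0.5,
) -> ScaleScores:
    """Facet/domain/total scores with a per-facet coverage rule.

    A facet score is the mean of that facet's observed items if the
    observed fraction is at least ``min_item_coverage``, otherwise
    missing; domain and total scores propagate missingness.
    """
    resp.validate_against(spec)
    facet_scores = {}
    for f in spec.facets:
        cols = list(spec.facet_items(f))
        block = resp.data[cols]
        frac = block.notna().mean(axis=1)
        score = block.mean(axis=1)
        score[frac < min_item_coverage] = np.nan
        facet_scores[f] = score
    facet_df = pd.DataFrame(facet_scores)
    domain_df = pd.DataFrame(
        {d: facet_df[list(spec.domain_facets(d))].mean(axis=1, skipna=False) for d in spec.domains}
    )
    total = facet_df.mean(axis=1, skipna=False)
    return ScaleScores(facet=facet_df, domain=domain_df, total=total, spec=spec)


def z_standardize(scores: ScaleScores, reference: Mapping[str, tuple[float, float]]) -> ScaleScores:
    """z-score every scale against reference (mean, SD) pairs.

    ``reference`` maps scale name (facet, domain or ``"total"``) to a
    ``(mean, sd)`` tuple, e.g. from a community norm sample.
    """

    def _z(series: pd.Series, name: str) -> pd.Series:
        mu, sd = reference[name]
        if sd <= 0:
            raise ValueError(f"reference SD for {name!r} must be > 0")
        return (series - mu) / sd

    facet = pd.DataFrame({f: _z(scores.facet[f], f) for f in scores.facet.columns})
    domain = pd.DataFrame({d: _z(scores.domain[d], d) for d in scores.domain.columns})
    total = _z(scores.total, "total")
    return ScaleScores(facet=facet, domain=domain, total=total, spec=scores.spec)


def reference_stats(scores: ScaleScores) -> dict[str, tuple[float, float]]:
    """(mean, SD) per scale, for use as a :func:`z_standardize` reference."""
    ref: dict[str, tuple[float, float]] = {}
    for f in scores.facet.columns:
        ref[f] = (float(scores.facet[f].mean()), float(scores.facet[f].std(ddof=1)))
    for d in scores.domain.columns:
        ref[d] = (float(scores.domain[d].mean()), float(scores.domain[d].std(ddof=1)))
    ref["total"] = (float(scores.total.mean()), float(scores.total.std(ddof=1)))
    return ref
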