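"""Trait-table statistics: summaries, correlations, subgroup t-tests and
top-accession mining with per-accession totals.

Display totals use half-up rounding to two decimals (matching printed
per-accession totals); all internal arithmetic is full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import DataError
from .types import TraitTable


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed trait tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    mean: float
    sd: float
    min: float
    max: float
    n: int


@dataclass
class CorrelationMatrix:
    trait_names: list[str]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray  # pairwise observation counts


@dataclass
class SubgroupTestResult:
    trait: str
    t: float
    p: float
    n1: int
    n2: int
    testable: bool = True


@dataclass
class TopAccessionReport:
    k: int
    top_per_trait: dict[str, list[str]]
    union: list[str]  # ordered by descending total
    totals: dict[str, float]  # accession -> rounded sum of trait values
    top_trait_counts: dict[str, int]  # accession -> number of traits where top-k
    raw_totals: dict[str, float] = field(default_factory=dict)


def summarize_traits(traits: TraitTable) -> list[TraitSummary]:
    """Mean/sd/min/max per trait, missing values excluded.

    Traits observed fewer than twice get ``sd = nan``; an all-missing trait
    yields an ``n = 0`` summary with NaN statistics.
    """
    if traits.n_accessions == 0:
        raise DataError("empty trait table")
    out = []
    for j, name in enumerate(traits.trait_names):
        col = traits.values[:, j]
        obs = col[~np.isnan(col)]
        n = len(obs)
        if n == 0:
            out.append(TraitSummary(name, np.nan, np.nan, np.nan, np.nan, 0))
        else:
            sd = float(np.std(obs, ddof=1)) if n > 1 else float("nan")
            out.append(
                TraitSummary(name, float(obs.mean()), sd, float(obs.min()), float(obs.max()), n)
            )
    return out


def correlation_matrix(traits: TraitTable) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided t-based p.

    Pairs with fewer than 3 complete observations, or with a constant
    trait, get ``r = nan``.
    """
    names = traits.trait_names
    m = len(names)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i, m):
            xi, xj = traits.values[:, i], traits.values[:, j]
            mask = ~np.isnan(xi) & ~np.isnan(xj)
            n[i, j] = n[j, i] = int(mask.sum())
            if n[i, j] < 3:
                continue
            a, b = xi[mask], xj[mask]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return CorrelationMatrix(trait_names=list(names), r=r, p=p, n=n)


def subgroup_ttest(
    traits: TraitTable, labels: dict[str, object]
) -> list[SubgroupTestResult]:
    """Two-sided pooled-variance Student's t-test per trait between the two
    subgroups defined by ``labels`` (accession -> subgroup key).

    Exactly two distinct subgroup values are required; a subgroup with
    fewer than two observations for a trait makes that trait untestable.
    """
    groups = sorted({labels[a] for a in traits.accession_ids if a in labels}, key=str)
    if len(groups) != 2:
        raise DataError(f"expected exactly 2 subgroups, found {len(groups)}: {groups}")
    g1 = [i for i, a in enumerate(traits.accession_ids) if labels.get(a) == groups[0]]
    g2 = [i for i, a in enumerate(traits.accession_ids) if labels.get(a) == groups[1]]
    out = []
    for j, name in enumerate(traits.trait_names):
        x1 = traits.values[g1, j]
        x2 = traits.values[g2, j]
        x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
        if len(x1) < 2 or len(x2) < 2:
            out.append(SubgroupTestResult(name, np.nan, np.nan, len(x1), len(x2), False))
            continue
        t, p = stats.ttest_ind(x1, x2, equal_var=True)
        out.append(SubgroupTestResult(name, float(t), float(p), len(x1), len(x2)))
    return out


def accession_total(traits: TraitTable, accession: str, ndigits: int = 2) -> float:
    """Half-up-rounded sum of an accession's trait values (display total)."""
    try:
        i = traits.accession_ids.index(accession)
    except ValueError:
        raise DataError(f"unknown accession {accession!r}") from None
    row = traits.values[i]
    return round_half_up(float(np.nansum(row)), ndigits)


def top_accessions(traits: TraitTable, k: int = 5) -> TopAccessionReport:
    """Top-k accessions per trait, their union, and per-accession totals.

    Ties at rank k keep every tied accession.  The union is ordered by
    descending rounded total (ties by accession id).
    """
    if k > traits.n_accessions:
        raise DataError(f"k={k} exceeds number of accessions {traits.n_accessions}")
    top_per_trait: dict[str, list[str]] = {}
    counts: dict[str, int] = {}
    for j, name in enumerate(traits.trait_names):
        col = traits.values[:, j]
        order = [
            i for i in np.argsort(-np.where(np.isnan(col), -np.inf, col), kind="stable")
            if not np.isnan(col[i])
        ]
        if not order:
            top_per_trait[name] = []
            continue
        chosen = order[:k]
        if len(order) > k:
            cutoff = col[chosen[-1]]
            for i in order[k:]:
                if col[i] == cutoff:
                    chosen.append(i)
                else:
                    break
        members = [traits.accession_ids[i] for i in chosen]
        top_per_trait[name] = members
        for a in members:
            counts[a] = counts.get(a, 0) + 1
    union = set(counts)
    raw_totals = {
        a: float(np.nansum(traits.values[traits.accession_ids.index(a)])) for a in union
    }
    totals = {a: round_half_up(v) for a, v in raw_totals.items()}
    ordered = sorted(union, key=lambda a: (-totals[a], a))
    return TopAccessionReport(
        k=k,
        top_per_trait=top_per_trait,
        union=ordered,
        totals=totals,
        top_trait_counts=counts,
        raw_totals=raw_totals,
    )
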