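"""DEG filtering, gene-set intersection, and the resampling null.

The question this stage answers: among genes that are both down-regulated in
the knockdown and carry the promoter element (the candidate direct targets),
is the fraction carrying the chromatin mark higher than chance?  "Chance" is
estimated the way the field usually presents it: draw many same-sized sets of
down-regulated genes *without* the element and count how often a random set
reaches the observed number of marked genes (the empirical exceedance
percentage).  The analytic counterpart, the hypergeometric upper tail of
drawing at least the observed number of marked genes from the pool, is
reported alongside but never conflated with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import hypergeom

from .core_io import DEGRecord

__all__ = [
    "OverlapSummary",
    "ResamplingResult",
    "IntegrationReport",
    "filter_downregulated",
    "overlap_summary",
    "percent",
    "hypergeom_tail",
    "resample_null",
    "run_integration",
]


def percent(numerator: int, denominator: int) -> float:
    """100 * num / den rounded half-up to one decimal (100/132 -> 75.8)."""
    if denominator == 0:
        return 0.0
    d = Decimal(100 * numerator) / Decimal(denominator)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class OverlapSummary:
    """Region counts of a 2- or 3-set Venn diagram over named gene sets."""

    set_names: list[str]
    set_sizes: dict[str, int]
    regions: dict[str, int]  # keys like "A", "A&B", "A&B&C" (exclusive regions)

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def intersection(self, *names: str) -> int:
        """|non-exclusive| intersection of the named sets."""
        want = set(names)
        return sum(
            n for key, n in self.regions.items() if want.issubset(key.split("&"))
        )

    def percent_of(self, names: Iterable[str], denominator: str) -> float:
        """Percentage of the intersection of ``names`` relative to one set."""
        if denominator not in self.set_sizes:
            raise KeyError(f"unknown denominator set {denominator!r}")
        return percent(self.intersection(*names), self.set_sizes[denominator])


def filter_downregulated(
    records: Iterable[DEGRecord], fold: float = 1.5, q_max: float = 0.05
) -> set[str]:
    """Genes down-regulated by strictly more than ``fold`` with q strictly
    below ``q_max``."""
    cut = -float(np.log2(fold))
    return {r.gene_id for r in records if r.log2fc < cut and r.q_value < q_max}


def overlap_summary(sets: Mapping[str, set[str]]) -> OverlapSummary:
    """Exact exclusive region counts for 2 or 3 named sets."""
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("overlap_summary takes 2 or 3 sets")
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for gid in universe:
        member = [n for n in names if gid in sets[n]]
        key = "&".join(member)
        regions[key] = regions.get(key, 0) + 1
    # ensure all region keys exist (even empty ones) in a deterministic order
    from itertools import combinations

    all_keys = [
        "&".join(c) for r in range(1, len(names) + 1) for c in combinations(names, r)
    ]
    regions = {k: regions.get(k, 0) for k in all_keys}
    return OverlapSummary(
        set_names=names,
        set_sizes={n: len(sets[n]) for n in names},
        regions=regions,
    )


def hypergeom_tail(N: int, K: int, k: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeometric(N population, K marked, k drawn)."""
    if not (0 <= K <= N and 0 <= k <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N}, K={K}, k={k}")
    if observed <= 0:
        return 1.0
    if observed > min(k, K):
        return 0.0
    return float(hypergeom.sf(observed - 1, N, K, k))


@dataclass
class ResamplingResult:
    """Monte-Carlo null for the marked-gene count of a drawn set."""

    pool_size: int
    pool_enriched: int
    set_size: int
    n_sets: int
    observed: int
    null_counts: np.ndarray
    exceed_count: int
    empirical_percent: float
    empirical_p_plus1: float
    hypergeom_tail: float
    tail: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "pool_size": self.pool_size,
            "pool_enriched": self.pool_enriched,
            "set_size": self.set_size,
            "n_sets": self.n_sets,
            "observed": self.observed,
            "exceed_count": self.exceed_count,
            "empirical_percent": self.empirical_percent,
            "empirical_p_plus1": self.empirical_p_plus1,
            "hypergeom_tail": self.hypergeom_tail,
            "tail": self.tail,
            "seed": self.seed,
            "null_counts": [int(x) for x in self.null_counts],
        }


def resample_null(
    pool_ids: Iterable[str],
    enriched_ids: Iterable[str],
    set_size: int,
    n_sets: int,
    observed: int,
    seed: int,
    tail: str = "ge",
) -> ResamplingResult:
    """Draw ``n_sets`` same-sized gene sets from the pool and count marked genes.

    Sets are drawn uniformly without replacement within a set and
    independently across sets.  ``exceed_count`` counts null sets whose marked
    count is >= observed ("ge") or > observed ("gt"); the raw empirical
    percentage 100*exceed/n_sets is reported next to the (b+1)/(B+1)
    estimator, and the analytic hypergeometric upper tail of the same event.
    """
    pool = np.array(sorted(set(pool_ids)))
    enr = set(enriched_ids)
    extra = enr - set(pool)
    if extra:
        import logging

        logging.getLogger(__name__).warning(
            "%d enriched ids outside the pool ignored", len(extra)
        )
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds pool size {len(pool)}")
    if tail not in ("ge", "gt"):
        raise ValueError("tail must be 'ge' or 'gt'")
    mask = np.array([gid in enr for gid in pool])
    K = int(mask.sum())
    rng = np.random.default_rng(seed)
    counts = np.empty(n_sets, dtype=np.int64)
    n = len(pool)
    for b in range(n_sets):
        idx = rng.choice(n, size=set_size, replace=False)
        counts[b] = int(mask[idx].sum())
    exceed = int(np.sum(counts >= observed) if tail == "ge" else np.sum(counts > observed))
    hg = hypergeom_tail(n, K, set_size, observed if tail == "ge" else observed + 1)
    return ResamplingResult(
        pool_size=n,
        pool_enriched=K,
        set_size=set_size,
        n_sets=n_sets,
        observed=observed,
        null_counts=counts,
        exceed_count=exceed,
        empirical_percent=float(100.0 * exceed / n_sets),
        empirical_p_plus1=float((exceed + 1) / (n_sets + 1)),
        hypergeom_tail=hg,
        tail=tail,
        seed=seed,
    )


@dataclass
class IntegrationReport:
    overlap: OverlapSummary
    candidates: list[str]
    observed_enriched: int
    percent_enriched: float
    resampling: Optional[ResamplingResult]
    warning: Optional[str] = None


def run_integration(
    element_set: set[str],
    down_set: set[str],
    enriched_set: set[str],
    n_sets: int = 1000,
    seed: int = 0,
    tail: str = "ge",
) -> IntegrationReport:
    """Full integration: candidates = element ∩ down, observed = candidates
    carrying the mark, null = same-sized sets resampled from the element-free
    down-regulated pool."""
    candidates = sorted(element_set & down_set)
    observed = len(set(candidates) & enriched_set)
    overlap = overlap_summary(
        {"element": element_set, "down": down_set, "enriched": enriched_set}
    )
    pct = percent(observed, len(candidates)) if candidates else 0.0
    if not candidates:
        return IntegrationReport(
            overlap=overlap,
            candidates=[],
            observed_enriched=0,
            percent_enriched=0.0,
            resampling=None,
            warning="no candidate genes (element ∩ down is empty); resampling skipped",
        )
    pool = down_set - element_set
    if len(candidates) > len(pool):
        return IntegrationReport(
            overlap=overlap,
            candidates=candidates,
            observed_enriched=observed,
            percent_enriched=pct,
            resampling=None,
            warning="element-free down-regulated pool smaller than the candidate set; "
            "resampling skipped",
        )
    res = resample_null(
        pool_ids=pool,
        enriched_ids=enriched_set & pool,
        set_size=len(candidates),
        n_sets=n_sets,
        observed=observed,
        seed=seed,
        tail=tail,
    )
    return IntegrationReport(
        overlap=overlap,
        candidates=candidates,
        observed_enriched=observed,
        percent_enriched=pct,
        resampling=res,
    )
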