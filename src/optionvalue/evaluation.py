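"""Inferential layer: benefit capture, SES comparisons, overrepresentation
permutation tests, top-set overlap, and distinctiveness statistics.

The central comparison works on replicate *capture counts*: how many species
flagged for a utilization category fall inside each selected set. An observed
strategy (e.g. greedy PD maximization) is compared against a null strategy
(e.g. uniform random sets of the same size) with a standardized effect size,
SES = (observed mean − null mean) / null SD, judged against the two-sided
normal thresholds 1.96 / 2.576 / 3.891 (5%, 1%, 0.01%). Confidence intervals
on capture counts are empirical 2.5/97.5 percentiles, since counts are
discrete and skewed at small set sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import SESReport
from .errors import DegenerateSetError, VocabularyError
from .selection import SelectionResult, rank_select, sample_size
from .treeio import SpeciesTable


# ---------------------------------------------------------------------------
# Capture counting
# ---------------------------------------------------------------------------


def count_captured(
    result: SelectionResult,
    table: SpeciesTable,
    category: str,
    include_other: bool = False,
) -> int:
    """Number of species flagged for ``category`` inside the selected set.
    ``category='all'`` pools the four main utilization categories."""
    return len(result.taxa & table.flagged(category, include_other=include_other))


@dataclass(frozen=True)
class CaptureSummary:
    """Replicate capture counts for one (strategy, fraction, category) cell."""

    strategy: str
    fraction: float
    category: str
    counts: tuple[int, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def ci95_low(self) -> float:
        return float(np.percentile(self.counts, 2.5))

    @property
    def ci95_high(self) -> float:
        return float(np.percentile(self.counts, 97.5))


def summarize_capture(
    results: Sequence[SelectionResult],
    table: SpeciesTable,
    category: str,
    include_other: bool = False,
) -> CaptureSummary:
    """Capture counts across replicate selections (all one strategy/fraction)."""
    if not results:
        raise ValueError("no selection results")
    strategies = {r.strategy for r in results}
    fractions = {r.fraction for r in results}
    if len(strategies) > 1 or len(fractions) > 1:
        raise ValueError("mixed strategies or fractions in one capture summary")
    counts = tuple(
        count_captured(r, table, category, include_other=include_other)
        for r in results
    )
    return CaptureSummary(
        strategy=strategies.pop(),
        fraction=fractions.pop(),
        category=category,
        counts=counts,
    )


def ses_between(observed: CaptureSummary, null: CaptureSummary) -> SESReport:
    """SES of an observed strategy's mean capture against a null strategy's
    capture distribution; positive SES = observed exceeds the null."""
    if observed.category != null.category or observed.fraction != null.fraction:
        raise ValueError("observed and null summaries must share category and fraction")
    if len(null.counts) < 2:
        raise ValueError("null needs at least 2 replicates")
    sd = float(np.std(null.counts, ddof=1))
    if sd == 0:
        raise DegenerateSetError("null capture distribution has zero SD")
    return SESReport.from_moments(
        m_obs=observed.mean,
        m_null=null.mean,
        sd_null=sd,
        n_obs=len(observed.counts),
        n_null=len(null.counts),
    )


# ---------------------------------------------------------------------------
# Order-level overrepresentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverrepReport:
    """Per-order observed counts vs a permutation null of random species sets
    of equal size; verdicts by the 2.5/97.5 percentile rule."""

    category: str
    n_perm: int
    observed: pd.Series  # per-order observed count
    null_counts: pd.DataFrame  # orders x permutations
    verdict: pd.Series  # 'over' | 'under' | 'ns'


def order_overrepresentation(
    table: SpeciesTable,
    category: str,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> OverrepReport:
    """Is any taxonomic order over/underrepresented in a utilization category?

    The null redraws species sets of the observed size uniformly from all
    species; an order is 'over' when its observed count is at or above the
    97.5th percentile of its null counts, 'under' at or below the 2.5th.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flagged = table.flagged(category)
    if not flagged:
        raise VocabularyError(f"category {category!r} has no flagged species")
    orders = table.orders
    order_names = sorted(orders.unique())
    code = {o: i for i, o in enumerate(order_names)}
    codes = orders.map(code).to_numpy()
    m = len(flagged)
    observed = (
        orders.loc[sorted(flagged)].value_counts().reindex(order_names).fillna(0)
    ).astype(int)
    n = len(table)
    null = np.zeros((len(order_names), n_perm), dtype=np.int64)
    for p in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        null[:, p] = np.bincount(codes[idx], minlength=len(order_names))
    hi = np.percentile(null, 97.5, axis=1)
    lo = np.percentile(null, 2.5, axis=1)
    obs = observed.to_numpy()
    verdict = np.where(obs >= hi, "over", np.where(obs <= lo, "under", "ns"))
    # an order whose null is constant (e.g. it contains every species) is ns
    verdict = np.where(null.std(axis=1) == 0, "ns", verdict)
    return OverrepReport(
        category=category,
        n_perm=n_perm,
        observed=observed,
        null_counts=pd.DataFrame(null, index=order_names),
        verdict=pd.Series(verdict, index=order_names, name="verdict"),
    )


# ---------------------------------------------------------------------------
# Top-set overlap (ED vs FDist)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of the top-k sets under two score maps over one universe."""

    fraction: float
    k: int
    a_only: frozenset
    b_only: frozenset
    both: frozenset

    @property
    def n_both(self) -> int:
        return len(self.both)


def top_set_overlap(
    scores_a: Mapping[str, float] | pd.Series,
    scores_b: Mapping[str, float] | pd.Series,
    universe: Iterable[str],
    fraction: float,
) -> OverlapReport:
    """Overlap between the top-``fraction`` sets of two rankings (e.g. ED vs
    FDist among threatened species)."""
    universe = sorted(set(universe))
    k = sample_size(fraction, len(universe))
    top_a = rank_select(scores_a, universe, k).taxa
    top_b = rank_select(scores_b, universe, k).taxa
    return OverlapReport(
        fraction=fraction,
        k=k,
        a_only=frozenset(top_a - top_b),
        b_only=frozenset(top_b - top_a),
        both=frozenset(top_a & top_b),
    )


# ---------------------------------------------------------------------------
# Distinctiveness statistics
# ---------------------------------------------------------------------------


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's t test (unequal variances); returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson correlation; returns (r, df, p) with df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r, p = stats.pearsonr(x, y)
    return float(r), len(x) - 2, float(p)


def dunn_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's z test for all pairwise group comparisons after Kruskal-Wallis.

    Uses joint ranks with the tie correction and adjusts two-sided p-values
    (Holm by default). Returns a frame with columns group_a, group_b, z,
    p_raw, p_adj.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: float(ranks[groups == g].mean()) for g in names}
    sizes = {g: int((groups == g).sum()) for g in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    frame = pd.DataFrame(rows)
    frame["p_adj"] = multipletests(frame["p_raw"], method=adjust)[1]
    return frame


@dataclass(frozen=True)
class DistinctivenessReport:
    """Kruskal-Wallis across groups with Dunn pairwise comparisons, plus any
    two-group Welch tests and the ED-FDist Pearson correlation."""

    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame
    welch: pd.DataFrame | None = None
    pearson: tuple[float, int, float] | None = None


def compare_distinctiveness(
    metric: pd.Series,
    groups: pd.Series,
    two_group_pairs: Sequence[tuple[str, str]] = (),
    correlate_with: pd.Series | None = None,
) -> DistinctivenessReport:
    """Compare a distinctiveness metric (ED or FDist) across labeled groups.

    ``metric`` and ``groups`` are aligned by index; each group needs >= 2
    members. ``two_group_pairs`` requests Welch t tests for specific group
    pairs; ``correlate_with`` adds a Pearson correlation between the two
    metrics over the shared index.
    """
    idx = metric.index.intersection(groups.index)
    metric = metric.loc[idx]
    groups = groups.loc[idx]
    counts = groups.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each group needs >= 2 members and >= 2 groups")
    samples = [metric[groups == g].to_numpy() for g in sorted(counts.index)]
    h, p = stats.kruskal(*samples)
    dunn = dunn_posthoc(metric.to_numpy(), groups.to_numpy())
    welch_rows = []
    for a, b in two_group_pairs:
        t, wp = welch_test(metric[groups == a], metric[groups == b])
        welch_rows.append({"group_a": a, "group_b": b, "t": t, "p": wp})
    pearson = None
    if correlate_with is not None:
        shared = metric.index.intersection(correlate_with.index)
        pearson = pearson_correlation(metric.loc[shared], correlate_with.loc[shared])
    return DistinctivenessReport(
        kruskal_h=float(h),
        kruskal_p=float(p),
        dunn=dunn,
        welch=pd.DataFrame(welch_rows) if welch_rows else None,
        pearson=pearson,
    )
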