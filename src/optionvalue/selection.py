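"""Species-set selection strategies.

The observed strategies are greedy PD maximization (optionally on top of a
"secured" set of low-risk species, so the objective is the *gain* in PD) and
rank-based prioritization by EDGE, median ED or FDist. The null strategies are
uniform random sampling, Red-List-weighted sampling (selection probability
proportional to the Red List Index weight of the category: VU=2, EN=3, CR=4,
EW=5), Red-List-controlled sampling (uniform within category, matching a
template set's category composition exactly), and FDist-weighted sampling.

Greedy PD maximization on a tree is exact: because PD gains are computed on a
tree metric, the greedy set of size k attains the maximum PD over all k-subsets
(tested exhaustively against brute force). Multiple optima exist whenever
branch lengths tie; greedy ties are broken uniformly at random with the seeded
generator, which is what makes repeated runs produce distinct maximizing sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CoverageError, FeasibilityError
from .treeio import Phylogeny, TreeEnsemble, normalize_label

STRATEGIES = (
    "greedy_pd",
    "greedy_pd_threatened",
    "edge_rank",
    "ed_rank",
    "fdist_rank",
    "random_uniform",
    "rl_weighted",
    "rl_controlled",
    "fdist_weighted",
)

#: Red List Index category weights used by the RL-weighted null strategy.
RL_INDEX_WEIGHTS = {"VU": 2, "EN": 3, "CR": 4, "EW": 5}

_TIE_RTOL = 1e-9


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf."""
    return int(math.floor(x + 0.5))


def sample_size(fraction: float, universe_size: int) -> int:
    """Number of species selected at a sample fraction (round-half-up)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return round_half_up(fraction * universe_size)


@dataclass(frozen=True)
class SelectionResult:
    """One selected species set with its provenance."""

    strategy: str
    fraction: float
    taxa: frozenset
    pd_value: float | None = None
    tree_index: int | None = None
    replicate: int | None = None

    @property
    def n_selected(self) -> int:
        return len(self.taxa)

    def to_record(self) -> dict:
        return {
            "strategy": self.strategy,
            "fraction": self.fraction,
            "tree_index": self.tree_index,
            "replicate": self.replicate,
            "pd_value": self.pd_value,
            "taxa": sorted(self.taxa),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "SelectionResult":
        return cls(
            strategy=rec["strategy"],
            fraction=rec["fraction"],
            taxa=frozenset(rec["taxa"]),
            pd_value=rec.get("pd_value"),
            tree_index=rec.get("tree_index"),
            replicate=rec.get("replicate"),
        )


# ---------------------------------------------------------------------------
# Greedy PD maximization
# ---------------------------------------------------------------------------


def greedy_max_pd(
    tree: Phylogeny,
    universe: Iterable[str],
    k: int,
    secured: Iterable[str] = (),
    seed: int | np.random.Generator = 0,
    strategy: str = "greedy_pd",
) -> SelectionResult:
    """Select k species from ``universe`` greedily maximizing rooted PD.

    At each step the candidate adding the largest PD increment to
    ``secured ∪ selected`` is taken; exact ties are broken uniformly at random.
    ``secured`` species (already-covered branches) contribute to the baseline
    but are never selected; any overlap with ``universe`` is dropped from the
    candidate pool. The returned ``pd_value`` is PD(secured ∪ selected).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = {normalize_label(s) for s in universe}
    secured = {normalize_label(s) for s in secured}
    unknown = (universe | secured) - tree.tips
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    candidates = sorted(universe - secured)
    if not 1 <= k <= len(candidates):
        raise ValueError(
            f"k={k} outside [1, {len(candidates)}] selectable candidates"
        )
    parent, lengths = tree.parent, tree.lengths
    covered = np.zeros(tree.n_nodes, dtype=bool)
    covered[0] = True  # rooted PD: the root is the baseline

    def cover(node: int) -> None:
        while not covered[node]:
            covered[node] = True
            node = parent[node]

    for s in secured:
        cover(tree.tip_node[tree.label_to_tip[s]])

    cand_cols = np.array([tree.label_to_tip[c] for c in candidates])
    cand_m = tree.node_tip_matrix[:, cand_cols].astype(float)  # nodes x cands
    alive = np.ones(len(candidates), dtype=bool)
    selected: list[str] = []
    for _ in range(k):
        gains = (lengths * ~covered) @ cand_m
        gains[~alive] = -np.inf
        best = gains.max()
        ties = np.flatnonzero(gains >= best - _TIE_RTOL * max(1.0, abs(best)))
        pick = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        alive[pick] = False
        selected.append(candidates[pick])
        cover(tree.tip_node[cand_cols[pick]])
    pd_value = float(lengths[covered].sum())
    return SelectionResult(
        strategy=strategy,
        fraction=k / len(universe),
        taxa=frozenset(selected),
        pd_value=pd_value,
    )


def greedy_over_ensemble(
    ensemble: TreeEnsemble,
    universe: Iterable[str],
    fraction: float,
    sets_per_tree: int = 10,
    secured: Iterable[str] = (),
    seed: int = 0,
    strategy: str = "greedy_pd",
) -> list[SelectionResult]:
    """Greedy PD-maximizing sets, ``sets_per_tree`` per tree, with distinct
    derived random streams, e.g. 10 sets x 100 trees = 1000 sets."""
    if sets_per_tree < 1:
        raise ValueError("sets_per_tree must be >= 1")
    universe = {normalize_label(s) for s in universe}
    secured = set(secured)
    k = sample_size(fraction, len(universe))
    out: list[SelectionResult] = []
    for ti, tree in enumerate(ensemble):
        for rep in range(sets_per_tree):
            rng = np.random.default_rng([seed, ti, rep])
            res = greedy_max_pd(tree, universe, k, secured, rng, strategy=strategy)
            out.append(
                SelectionResult(
                    strategy=strategy,
                    fraction=fraction,
                    taxa=res.taxa,
                    pd_value=res.pd_value,
                    tree_index=ti,
                    replicate=rep,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Rank-based selection
# ---------------------------------------------------------------------------


def rank_select(
    scores: Mapping[str, float] | pd.Series,
    universe: Iterable[str],
    k: int,
    strategy: str = "ed_rank",
    fraction: float | None = None,
) -> SelectionResult:
    """Top-k of ``universe`` by descending score; ties broken by species id
    (lexicographic), so a published ranking yields one deterministic set."""
    universe = sorted({normalize_label(s) for s in universe})
    scores = dict(scores) if not isinstance(scores, dict) else scores
    missing = [s for s in universe if s not in scores or pd.isna(scores[s])]
    if missing:
        raise CoverageError(f"no score for species: {missing[:5]}")
    if not 1 <= k <= len(universe):
        raise ValueError(f"k={k} outside [1, {len(universe)}]")
    ordered = sorted(universe, key=lambda s: (-float(scores[s]), s))
    return SelectionResult(
        strategy=strategy,
        fraction=fraction if fraction is not None else k / len(universe),
        taxa=frozenset(ordered[:k]),
    )


# ---------------------------------------------------------------------------
# Stochastic null strategies
# ---------------------------------------------------------------------------


def sample_weighted(
    universe: Iterable[str],
    weights: Mapping[str, float] | pd.Series,
    k: int,
    seed: int | np.random.Generator = 0,
    strategy: str = "rl_weighted",
    fraction: float | None = None,
) -> SelectionResult:
    """Weighted sampling without replacement: sequential draws, each with
    probability proportional to weight among the remaining species.

    Implemented with exponential sort keys (key_i = E_i / w_i, keep the k
    smallest), which draws from exactly the same distribution as the
    sequential procedure.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = sorted({normalize_label(s) for s in universe})
    w = np.array([float(weights[s]) for s in universe if s in weights])
    if len(w) != len(universe):
        missing = [s for s in universe if s not in weights]
        raise CoverageError(f"no weight for species: {missing[:5]}")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if not 1 <= k <= len(universe):
        raise ValueError(f"k={k} outside [1, {len(universe)}]")
    keys = rng.exponential(size=len(universe)) / w
    chosen = np.argsort(keys, kind="stable")[:k]
    return SelectionResult(
        strategy=strategy,
        fraction=fraction if fraction is not None else k / len(universe),
        taxa=frozenset(universe[i] for i in chosen),
    )


def random_uniform(
    universe: Iterable[str],
    k: int,
    seed: int | np.random.Generator = 0,
    fraction: float | None = None,
) -> SelectionResult:
    """Uniform sampling without replacement (the basic null strategy)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = sorted({normalize_label(s) for s in universe})
    if not 1 <= k <= len(universe):
        raise ValueError(f"k={k} outside [1, {len(universe)}]")
    chosen = rng.choice(len(universe), size=k, replace=False)
    return SelectionResult(
        strategy="random_uniform",
        fraction=fraction if fraction is not None else k / len(universe),
        taxa=frozenset(universe[i] for i in chosen),
    )


def sample_rl_controlled(
    universe: Iterable[str],
    rl_of: Mapping[str, str] | pd.Series,
    template: SelectionResult,
    seed: int | np.random.Generator = 0,
) -> SelectionResult:
    """Uniform sampling conditioned on the template's Red List composition:
    for each category, draw exactly as many species of that category as the
    template set contains."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = sorted({normalize_label(s) for s in universe})
    missing = [s for s in list(template.taxa) + universe if s not in rl_of]
    if missing:
        raise CoverageError(f"no Red List category for species: {missing[:5]}")
    need: dict[str, int] = {}
    for s in template.taxa:
        need[rl_of[s]] = need.get(rl_of[s], 0) + 1
    chosen: list[str] = []
    for cat in sorted(need):
        pool = [s for s in universe if rl_of[s] == cat]
        if len(pool) < need[cat]:
            raise FeasibilityError(
                f"category {cat}: template needs {need[cat]} species, "
                f"universe has {len(pool)}"
            )
        idx = rng.choice(len(pool), size=need[cat], replace=False)
        chosen.extend(pool[i] for i in idx)
    return SelectionResult(
        strategy="rl_controlled",
        fraction=template.fraction,
        taxa=frozenset(chosen),
        tree_index=template.tree_index,
        replicate=template.replicate,
    )
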