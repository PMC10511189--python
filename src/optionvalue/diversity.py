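"""Core diversity metrics.

Faith's phylogenetic diversity (PD) here is *rooted*: the PD of a species set
is the total length of all branches on the paths from the set's members to the
root, each branch counted once. With this convention the fair-proportion
evolutionary distinctiveness (ED) scores of all tips sum exactly to the tree's
total branch length, i.e. ED partitions total PD among species.

EDGE combines ED with a global endangerment (GE) weight derived from the IUCN
Red List category: EDGE = ln(1 + ED) + GE * ln 2, so each step up in threat
doubles the implied extinction probability weight. GE runs LC=0, NT=1, VU=2,
EN=3, CR=4, EW=5; Data Deficient species have no defined GE and are rejected
rather than guessed.

Phylogenetic clumping/dispersion of a labeled species set is measured by a
standardized effect size (SES) against a tip-label-shuffle null: the observed
PD of the set is compared with the PD of the same number of tips after
shuffling species names across the tree tips, SES = (obs − null mean)/null SD.
Negative SES indicates clumping (the set spans less PD than random sets of the
same size), positive SES indicates overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateSetError, VocabularyError
from .treeio import Phylogeny, TreeEnsemble

#: Global endangerment weight per Red List category (DD intentionally absent).
GE_BY_CATEGORY: Mapping[str, int] = {
    "LC": 0,
    "NT": 1,
    "VU": 2,
    "EN": 3,
    "CR": 4,
    "EW": 5,
}

#: |SES| thresholds for the significance tiers *, **, *** (two-sided normal
#: quantiles for alpha = 5%, 1% and 0.01%).
SES_TIERS = ((3.891, "***"), (2.576, "**"), (1.96, "*"))


def ses_tier(ses: float) -> str:
    """Significance tier for an SES value: 'ns', '*', '**' or '***'."""
    for threshold, tier in SES_TIERS:
        if abs(ses) >= threshold:
            return tier
    return "ns"


@dataclass(frozen=True)
class SESReport:
    """Standardized effect size of an observed quantity against a null.

    ``ses = (m_obs - m_null) / sd_null``; positive values mean the observed
    quantity exceeds the null expectation.
    """

    m_obs: float
    m_null: float
    sd_null: float
    ses: float
    n_obs: int
    n_null: int
    tier: str

    @classmethod
    def from_moments(
        cls, m_obs: float, m_null: float, sd_null: float, n_obs: int, n_null: int
    ) -> "SESReport":
        if sd_null <= 0:
            raise DegenerateSetError("null distribution has zero standard deviation")
        ses = (m_obs - m_null) / sd_null
        return cls(m_obs, m_null, sd_null, ses, n_obs, n_null, ses_tier(ses))


# ---------------------------------------------------------------------------
# PD
# ---------------------------------------------------------------------------


def faith_pd(tree: Phylogeny, taxa: Iterable[str]) -> float:
    """Rooted Faith PD of a species set (sum of branch lengths on all
    root-to-member paths, each branch once)."""
    taxa = set(taxa)
    if not taxa:
        raise ValueError("empty taxon set has no PD")
    cols = tree.tip_indices(taxa)  # raises KeyError for unknown taxa
    covered = tree.node_tip_matrix[:, cols].any(axis=1)
    return float(tree.lengths[covered].sum())


def pd_of_tip_sets(tree: Phylogeny, membership: np.ndarray) -> np.ndarray:
    """Vectorized rooted PD for many tip sets.

    ``membership`` is boolean (n_tips, n_sets); returns PD per column. Used by
    the shuffle null, where thousands of same-size sets are scored per tree.
    """
    counts = tree._node_tip_matrix_f @ membership.astype(np.float32)
    return (counts > 0).T.astype(float) @ tree.lengths


# ---------------------------------------------------------------------------
# ED / EDGE
# ---------------------------------------------------------------------------


def fair_proportion_ed(tree: Phylogeny) -> pd.Series:
    """Fair-proportion ED: each branch's length is split equally among its
    descendant tips; a tip's ED is the sum of its shares. Sums to the total
    branch length over all tips."""
    m = tree.node_tip_matrix
    share = np.divide(
        tree.lengths,
        tree.n_descendant_tips,
        out=np.zeros(tree.n_nodes),
        where=tree.n_descendant_tips > 0,
    )
    ed = m.T.astype(float) @ share
    return pd.Series(ed, index=list(tree.tip_labels), name="ed")


def edge_score(ed: float, rl_category: str) -> float:
    """EDGE = ln(1 + ED) + GE * ln 2 for one species."""
    if rl_category not in GE_BY_CATEGORY:
        raise VocabularyError(
            f"no GE weight defined for Red List category {rl_category!r}"
        )
    if ed < 0:
        raise ValueError("ED must be nonnegative")
    return math.log1p(ed) + GE_BY_CATEGORY[rl_category] * math.log(2.0)


class DistinctScores:
    """Per-species distinctiveness over a tree ensemble.

    Holds per-tree ED (and EDGE where GE is defined), their medians across
    trees, the FDist score, and dense ranks (1 = most distinct) within the
    stated species universe.
    """

    def __init__(
        self,
        ed_per_tree: pd.DataFrame,
        frame: pd.DataFrame,
    ):
        self.ed_per_tree = ed_per_tree  # species x trees
        self.frame = frame  # ed_median, ed_mean, edge_median?, fdist?, ranks

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def scores(self, kind: str) -> pd.Series:
        """Score vector for ranking: kind in {'ed', 'edge', 'fdist'}."""
        col = {"ed": "ed_median", "edge": "edge_median", "fdist": "fdist"}[kind]
        if col not in self.frame or self.frame[col].isna().any():
            raise ValueError(f"{kind} scores not available for every species")
        return self.frame[col]


def ed_table(ensemble: TreeEnsemble) -> pd.DataFrame:
    """Per-species ED for each tree in the ensemble (species x trees)."""
    cols = {i: fair_proportion_ed(t) for i, t in enumerate(ensemble)}
    return pd.DataFrame(cols).sort_index()


def distinct_scores(
    ensemble: TreeEnsemble,
    rl_category: Mapping[str, str] | pd.Series | None = None,
    fdist: Mapping[str, float] | pd.Series | None = None,
    universe: Iterable[str] | None = None,
) -> DistinctScores:
    """Compute ED (always), EDGE (where the Red List category has a GE) and
    attach FDist, with medians across trees and ranks within ``universe``
    (default: all tips). The median over an even number of trees is the mean
    of the two central values."""
    ed = ed_table(ensemble)
    if universe is not None:
        ed = ed.loc[sorted(universe)]
    frame = pd.DataFrame(
        {
            "ed_median": ed.median(axis=1),
            "ed_mean": ed.mean(axis=1),
        }
    )
    if rl_category is not None:
        rl = pd.Series(rl_category).reindex(frame.index)
        ge = rl.map(GE_BY_CATEGORY)
        edge_med = pd.Series(np.nan, index=frame.index)
        ok = ge.notna()
        if ok.any():
            # EDGE per tree, then median across trees
            edge_pt = np.log1p(ed.loc[ok]).add(
                ge[ok].astype(float) * math.log(2.0), axis=0
            )
            edge_med[ok] = edge_pt.median(axis=1)
        frame["edge_median"] = edge_med
    if fdist is not None:
        frame["fdist"] = pd.Series(fdist).reindex(frame.index)
    for col, rank_col in (
        ("ed_median", "ed_rank"),
        ("edge_median", "edge_rank"),
        ("fdist", "fdist_rank"),
    ):
        if col in frame:
            frame[rank_col] = frame[col].rank(ascending=False, method="min")
    return DistinctScores(ed, frame)


# ---------------------------------------------------------------------------
# Dispersion SES (tip-shuffle null)
# ---------------------------------------------------------------------------


def dispersion_ses(
    ensemble: TreeEnsemble | Phylogeny,
    taxa: Iterable[str],
    n_shuffles: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> SESReport:
    """Phylogenetic dispersion of a labeled set via the tip-shuffle null.

    For each tree, the observed PD of ``taxa`` is compared with the PD of the
    set after shuffling species names across tips ``n_shuffles`` times; the
    per-tree SES values are averaged across the ensemble. Negative SES means
    the set is phylogenetically clumped.
    """
    if isinstance(ensemble, Phylogeny):
        ensemble = TreeEnsemble([ensemble])
    taxa = frozenset(taxa)
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be at least 2")
    n = len(ensemble.shared_tipset)
    m = len(taxa)
    if m == 0 or m == n:
        raise DegenerateSetError(
            "dispersion SES undefined for empty or complete tip sets (null SD = 0)"
        )
    if not taxa <= ensemble.shared_tipset:
        raise KeyError(f"taxa not in trees: {sorted(taxa - ensemble.shared_tipset)}")
    rng = np.random.default_rng(seed)
    ses_values = []
    obs_values = []
    null_means = []
    null_sds = []
    for tree in ensemble:
        obs = faith_pd(tree, taxa)
        # A label shuffle maps the fixed set of m names onto a uniformly random
        # set of m tip positions, so the null is PD of uniform m-subsets.
        keys = rng.random((n, n_shuffles))
        idx = np.argpartition(keys, m - 1, axis=0)[:m, :]
        member = np.zeros((n, n_shuffles), dtype=bool)
        member[idx, np.arange(n_shuffles)[None, :]] = True
        null = pd_of_tip_sets(tree, member)
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd <= 0:
            raise DegenerateSetError("shuffle null has zero standard deviation")
        ses_values.append((obs - mu) / sd)
        obs_values.append(obs)
        null_means.append(mu)
        null_sds.append(sd)
    ses = float(np.mean(ses_values))
    return SESReport(
        m_obs=float(np.mean(obs_values)),
        m_null=float(np.mean(null_means)),
        sd_null=float(np.mean(null_sds)),
        ses=ses,
        n_obs=len(ensemble),
        n_null=n_shuffles,
        tier=ses_tier(ses),
    )
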