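"""Phylogeny and species-table I/O.

Trees are read and written with :mod:`dendropy` (Newick, one tree per line, or a
NEXUS TREES block) and wrapped in a lightweight :class:`Phylogeny` that exposes
flat arrays (parent pointers, branch lengths, clade/tip incidence) used by the
diversity and selection code. Species attributes travel in a delimited table
with one row per species (taxonomic order, IUCN Red List category, one boolean
flag per utilization category, and a functional-distinctiveness score).

Tip labels are matched to table rows by exact string equality after trimming
whitespace and replacing underscores with spaces.
"""

from __future__ import annotations

import io
import logging
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    EnsembleConsistencyError,
    ReconciliationError,
    SchemaError,
    TreeFormatError,
    VocabularyError,
)

logger = logging.getLogger("optionvalue")

#: Closed vocabulary of IUCN Red List categories handled by the package.
RL_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "DD")
#: Categories treated as threatened (candidates for conservation selection).
THREATENED_CATEGORIES = ("VU", "EN", "CR", "EW")
#: Categories treated as low-risk ("secured" in threatened-gain selection).
LOW_RISK_CATEGORIES = ("LC", "NT")

#: Utilization categories carried by the species table.
USE_CATEGORIES = ("food", "materials", "medicine", "pets", "other")
#: The four main categories pooled by the "all" pseudo-category.
MAIN_USE_CATEGORIES = ("food", "materials", "medicine", "pets")

REQUIRED_COLUMNS = (
    "species",
    "order",
    "rl_category",
    "use_food",
    "use_materials",
    "use_medicine",
    "use_pets",
    "use_other",
    "fdist",
)

_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False}


def normalize_label(label: str) -> str:
    """Canonical tip/species label: trimmed, underscores replaced by spaces."""
    return label.strip().replace("_", " ")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted phylogeny with branch lengths, backed by flat numpy arrays.

    Nodes are indexed in preorder (root = 0). ``parent[i]`` is the index of
    node *i*'s parent (−1 for the root) and ``lengths[i]`` the length of the
    edge above node *i* (0 for the root). Zero-length branches and polytomies
    are accepted; absent branch lengths are an error because phylogenetic
    diversity is undefined without them.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n, dtype=float)
        tip_node: list[int] = []
        tip_labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeFormatError(
                        "branch length missing on an internal or terminal edge; "
                        "lengths are required"
                    )
                if nd.edge.length < 0:
                    raise TreeFormatError("negative branch length")
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                raw = nd.taxon.label if nd.taxon is not None else nd.label
                if raw is None:
                    raise TreeFormatError("unlabeled tip")
                tip_node.append(i)
                tip_labels.append(normalize_label(str(raw)))
        if len(tip_labels) != len(set(tip_labels)):
            dupes = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
            raise TreeFormatError(f"duplicate tip labels: {dupes}")
        if not np.any(lengths > 0):
            raise TreeFormatError("all branch lengths are zero")
        self.parent = parent
        self.lengths = lengths
        self.tip_node = np.asarray(tip_node, dtype=np.int64)
        self.tip_labels: tuple[str, ...] = tuple(tip_labels)
        self.label_to_tip = {lab: j for j, lab in enumerate(tip_labels)}
        self.n_nodes = n
        self.n_tips = len(tip_labels)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        return cls(dtree)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeFormatError(f"newick parse failure: {exc}") from exc
        return cls(dtree)

    # -- basic structure ---------------------------------------------------

    @property
    def tips(self) -> frozenset:
        return frozenset(self.tip_labels)

    @cached_property
    def children(self) -> tuple[tuple[int, ...], ...]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            kids[self.parent[i]].append(i)
        return tuple(tuple(k) for k in kids)

    @cached_property
    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # preorder: parent precedes child
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    @cached_property
    def node_tip_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): entry (v, j) is True iff tip j descends
        from (or is) node v. Row 0 is all True."""
        m = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
        for j, v in enumerate(self.tip_node):
            while v != -1:
                m[v, j] = True
                v = self.parent[v]
        return m

    @cached_property
    def _node_tip_matrix_f(self) -> np.ndarray:
        return self.node_tip_matrix.astype(np.float32)

    @cached_property
    def n_descendant_tips(self) -> np.ndarray:
        return self.node_tip_matrix.sum(axis=1)

    @property
    def total_branch_length(self) -> float:
        return float(self.lengths.sum())

    def tip_indices(self, taxa: Iterable[str]) -> np.ndarray:
        """Column indices for a collection of tip labels (KeyError if absent)."""
        return np.asarray(
            sorted(self.label_to_tip[normalize_label(t)] for t in taxa),
            dtype=np.int64,
        )

    # -- interop -----------------------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        return self._dtree

    def to_newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Tree restricted to the given tips; path lengths among retained tips
        are preserved (collapsed unifurcations have their lengths summed)."""
        keep = {normalize_label(t) for t in labels}
        missing = keep - self.tips
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if keep == self.tips:
            return self
        taxa = [
            t.label
            for t in self._dtree.taxon_namespace
            if normalize_label(t.label) in keep
        ]
        sub = self._dtree.extract_tree_with_taxa_labels(taxa)
        return Phylogeny(sub)

    def patristic_distances(self) -> pd.DataFrame:
        """Tip-to-tip path-length matrix (small trees; used for validation)."""
        depths = self.depths
        m = self.node_tip_matrix
        n = self.n_tips
        out = np.zeros((n, n))
        # MRCA depth = depth of the deepest node containing both tips
        for v in range(self.n_nodes):
            row = m[v]
            d = depths[v]
            mask = np.outer(row, row)
            out = np.where(mask, np.maximum(out, d), out)
        tipd = depths[self.tip_node]
        dist = tipd[:, None] + tipd[None, :] - 2 * out
        np.fill_diagonal(dist, 0.0)
        return pd.DataFrame(dist, index=self.tip_labels, columns=self.tip_labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny n_tips={self.n_tips} total_length={self.total_branch_length:.4g}>"


# ---------------------------------------------------------------------------
# TreeEnsemble
# ---------------------------------------------------------------------------


class TreeEnsemble:
    """An ordered sequence of trees over one shared tip set (e.g. a posterior
    sample used to average over phylogenetic uncertainty)."""

    def __init__(self, trees: Sequence[Phylogeny]):
        trees = tuple(trees)
        if not trees:
            raise EnsembleConsistencyError("empty ensemble")
        ref = trees[0].tips
        for i, t in enumerate(trees[1:], start=1):
            if t.tips != ref:
                diff = sorted(t.tips ^ ref)
                raise EnsembleConsistencyError(
                    f"tree {i} tip set differs from tree 0; symmetric difference: {diff}"
                )
        self.trees = trees
        self.shared_tipset: frozenset = ref

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Phylogeny]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    def prune_to(self, labels: Iterable[str]) -> "TreeEnsemble":
        return TreeEnsemble([t.prune_to(labels) for t in self.trees])


def read_tree_ensemble(path, format: str = "newick") -> TreeEnsemble:
    """Read a tree ensemble from a Newick file (one tree per line) or a NEXUS
    TREES block. All trees must have identical tip sets."""
    if format == "newick":
        with open(path) as fh:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        if not lines:
            raise TreeFormatError(f"{path}: no trees found")
        trees = []
        for i, line in enumerate(lines):
            try:
                trees.append(Phylogeny.from_newick(line))
            except TreeFormatError as exc:
                raise TreeFormatError(f"{path}: tree {i}: {exc}") from exc
    elif format == "nexus":
        try:
            tl = dendropy.TreeList.get(path=str(path), schema="nexus")
        except Exception as exc:
            raise TreeFormatError(f"{path}: nexus parse failure: {exc}") from exc
        trees = []
        for i, dt in enumerate(tl):
            try:
                trees.append(Phylogeny(dt))
            except TreeFormatError as exc:
                raise TreeFormatError(f"{path}: tree {i}: {exc}") from exc
    else:
        raise ValueError(f"unknown tree format: {format!r}")
    return TreeEnsemble(trees)


def write_tree_ensemble(ensemble: TreeEnsemble, path) -> None:
    """Write an ensemble as Newick, one tree per line."""
    with open(path, "w") as fh:
        for t in ensemble:
            fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# SpeciesTable
# ---------------------------------------------------------------------------


class SpeciesTable:
    """Per-species attributes: taxonomic order, Red List category, one boolean
    flag per utilization category, and a functional-distinctiveness score."""

    def __init__(self, frame: pd.DataFrame):
        # frame indexed by species id with validated columns
        self._frame = frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpeciesTable":
        """Validate and coerce a raw DataFrame (columns as in REQUIRED_COLUMNS)."""
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["species"] = df["species"].astype(str).map(normalize_label)
        dup = df["species"][df["species"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate species ids: {sorted(set(dup))}")
        df["rl_category"] = df["rl_category"].astype(str).str.strip().str.upper()
        bad = df.loc[~df["rl_category"].isin(RL_CATEGORIES)]
        if len(bad):
            first = bad.iloc[0]
            raise VocabularyError(
                f"unknown Red List category {first['rl_category']!r} "
                f"for species {first['species']!r}"
            )
        for cat in USE_CATEGORIES:
            col = f"use_{cat}"
            vals = df[col].astype(str).str.strip().str.lower()
            unknown = vals[~vals.isin(_BOOL_MAP)]
            if len(unknown):
                raise SchemaError(
                    f"column {col}: non-boolean value {unknown.iloc[0]!r}"
                )
            df[col] = vals.map(_BOOL_MAP).astype(bool)
        try:
            df["fdist"] = df["fdist"].astype(float)
        except ValueError as exc:
            raise SchemaError(f"column fdist: {exc}") from exc
        if (df["fdist"] < 0).any():
            raise SchemaError("column fdist: negative values")
        df["order"] = df["order"].astype(str).str.strip()
        return cls(df.set_index("species", drop=True))

    # -- access ------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, sp: str) -> bool:
        return normalize_label(sp) in self._frame.index

    @property
    def rl_category(self) -> pd.Series:
        return self._frame["rl_category"]

    @property
    def orders(self) -> pd.Series:
        return self._frame["order"]

    @property
    def fdist(self) -> pd.Series:
        return self._frame["fdist"]

    def flagged(self, category: str, include_other: bool = False) -> frozenset:
        """Species flagged for a utilization category.

        ``"all"`` pools the four main categories (food, materials, medicine,
        pets); ``include_other=True`` additionally pools the unreconciled
        "other" uses into ``"all"`` (a sensitivity variant).
        """
        if category == "all":
            cats = list(MAIN_USE_CATEGORIES) + (["other"] if include_other else [])
            mask = np.zeros(len(self._frame), dtype=bool)
            for c in cats:
                mask |= self._frame[f"use_{c}"].to_numpy()
            return frozenset(self._frame.index[mask])
        if category not in USE_CATEGORIES:
            raise VocabularyError(f"unknown utilization category {category!r}")
        return frozenset(self._frame.index[self._frame[f"use_{category}"]])

    def threatened(self) -> frozenset:
        """Species in a threatened Red List category (VU, EN, CR, EW)."""
        return frozenset(
            self._frame.index[self._frame["rl_category"].isin(THREATENED_CATEGORIES)]
        )

    def low_risk(self) -> frozenset:
        """Species treated as secured from extinction (LC, NT)."""
        return frozenset(
            self._frame.index[self._frame["rl_category"].isin(LOW_RISK_CATEGORIES)]
        )

    def subset(self, ids: Iterable[str]) -> "SpeciesTable":
        keep = [normalize_label(i) for i in ids]
        missing = [i for i in keep if i not in self._frame.index]
        if missing:
            raise KeyError(f"species not in table: {sorted(missing)}")
        return SpeciesTable(self._frame.loc[sorted(keep)])

    def to_csv(self, path) -> None:
        out = self._frame.copy()
        for cat in USE_CATEGORIES:
            out[f"use_{cat}"] = out[f"use_{cat}"].astype(int)
        out.reset_index().to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SpeciesTable n={len(self)}>"


def read_species_table(path) -> SpeciesTable:
    """Read a comma- or tab-delimited species table with the standard header."""
    with open(path) as fh:
        text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    return SpeciesTable.from_frame(frame)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


def reconcile(
    ensemble: TreeEnsemble, table: SpeciesTable, policy: str = "intersect"
) -> tuple[TreeEnsemble, SpeciesTable]:
    """Align a tree ensemble with a species table.

    ``intersect`` prunes trees and filters the table to the common id set
    (counts of dropped ids are logged); ``strict`` raises on any mismatch.
    """
    tips = set(ensemble.shared_tipset)
    ids = set(table.species)
    if policy == "strict":
        if tips != ids:
            raise ReconciliationError(
                f"unmatched ids: {sorted(tips ^ ids)}"
            )
        return ensemble, table
    if policy != "intersect":
        raise ValueError(f"unknown reconcile policy {policy!r}")
    common = tips & ids
    if len(common) < 2:
        raise ReconciliationError(
            f"fewer than two species shared between trees and table ({len(common)})"
        )
    dropped_tips = len(tips - common)
    dropped_rows = len(ids - common)
    if dropped_tips or dropped_rows:
        logger.info(
            "reconcile: dropped %d tree tips and %d table rows; %d species retained",
            dropped_tips,
            dropped_rows,
            len(common),
        )
    ens = ensemble if not dropped_tips else ensemble.prune_to(common)
    tab = table if not dropped_rows else table.subset(common)
    return ens, tab
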