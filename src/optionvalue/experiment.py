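"""End-to-end experiment orchestration.

One configuration file drives generate → score → select → evaluate → report:
inputs are either a tree file plus species table or a synthetic-data
configuration; selections for every requested strategy × sample fraction are
persisted as line-delimited JSON (so one set of null selections can be reused
across utilization categories); capture reports carry the mean, empirical 95%
CI, SES against the configured null strategy and significance tier per
(strategy, fraction, category) cell; and a manifest records the configuration
hash, seed and package version so a rerun reproduces every output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import DistinctScores, distinct_scores
from .errors import OptionValueError
from .evaluation import ses_between, summarize_capture
from .selection import (
    RL_INDEX_WEIGHTS,
    STRATEGIES,
    SelectionResult,
    greedy_over_ensemble,
    random_uniform,
    rank_select,
    sample_rl_controlled,
    sample_size,
    sample_weighted,
)
from .synthdata import SynthConfig, generate
from .treeio import (
    SpeciesTable,
    TreeEnsemble,
    read_species_table,
    read_tree_ensemble,
    reconcile,
)

logger = logging.getLogger("optionvalue")

_RANK_STRATEGIES = ("edge_rank", "ed_rank", "fdist_rank")
_GREEDY_STRATEGIES = ("greedy_pd", "greedy_pd_threatened")

# stream offsets for per-strategy randomness
_STREAM_OF = {name: i for i, name in enumerate(STRATEGIES)}


@dataclass
class ExperimentConfig:
    """Configuration of one full experiment."""

    out_dir: str = "experiment_out"
    trees: str | None = None
    species: str | None = None
    synth: dict | None = None
    fractions: Sequence[float] = (0.025, 0.05, 0.10, 0.25, 0.50)
    strategies: Sequence[str] = ("greedy_pd",)
    null_strategy: str = "random_uniform"
    categories: Sequence[str] = ("food", "materials", "medicine", "pets", "all")
    universe: str = "all"  # 'all' or 'threatened'
    replicates: int = 1000
    sets_per_tree: int = 10
    seed: int = 0
    include_other_in_all: bool = False

    def __post_init__(self) -> None:
        fr = list(self.fractions)
        if any(not 0 < f <= 1 for f in fr) or fr != sorted(set(fr)):
            raise ValueError("fractions must be strictly increasing and in (0, 1]")
        for s in list(self.strategies) + [self.null_strategy]:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        if self.universe not in ("all", "threatened"):
            raise ValueError("universe must be 'all' or 'threatened'")
        if (self.trees is None) != (self.species is None):
            raise ValueError("trees and species must be given together")
        if self.trees is None and self.synth is None:
            raise ValueError("either trees+species or a synth block is required")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Selection generation (shared by run_experiment and the CLI)
# ---------------------------------------------------------------------------


def resolve_universe(
    ensemble: TreeEnsemble, table: SpeciesTable, universe: str
) -> tuple[frozenset, frozenset]:
    """(candidate universe, secured set) for a universe kind.

    'all': every tip is a candidate and nothing is secured. 'threatened':
    candidates are the VU/EN/CR/EW species, LC/NT species are secured, and DD
    species belong to neither (their risk is unknown).
    """
    tips = ensemble.shared_tipset
    if universe == "all":
        return frozenset(tips), frozenset()
    return frozenset(table.threatened() & tips), frozenset(table.low_risk() & tips)


def generate_selections(
    strategy: str,
    ensemble: TreeEnsemble,
    table: SpeciesTable,
    fraction: float,
    *,
    universe: str = "all",
    scores: DistinctScores | None = None,
    templates: Sequence[SelectionResult] | None = None,
    replicates: int = 1000,
    sets_per_tree: int = 10,
    seed: int = 0,
) -> list[SelectionResult]:
    """Replicate selections for one strategy at one sample fraction.

    Greedy strategies produce ``sets_per_tree`` sets per tree; rank strategies
    produce a single deterministic set; stochastic strategies produce
    ``replicates`` sets. ``rl_controlled`` requires template selections whose
    Red List composition is to be matched.
    """
    cand, secured = resolve_universe(ensemble, table, universe)
    if not cand:
        raise OptionValueError(f"empty candidate universe ({universe!r})")
    k = sample_size(fraction, len(cand))
    base = [seed, _STREAM_OF[strategy]]
    if strategy == "greedy_pd":
        return greedy_over_ensemble(
            ensemble, cand, fraction, sets_per_tree, secured=(), seed=seed
        )
    if strategy == "greedy_pd_threatened":
        return greedy_over_ensemble(
            ensemble,
            cand,
            fraction,
            sets_per_tree,
            secured=secured,
            seed=seed + 1,
            strategy="greedy_pd_threatened",
        )
    if strategy in _RANK_STRATEGIES:
        if scores is None:
            raise OptionValueError(f"{strategy} needs distinctiveness scores")
        kind = strategy.split("_")[0]
        return [
            rank_select(
                scores.scores(kind), cand, k, strategy=strategy, fraction=fraction
            )
        ]
    if strategy == "random_uniform":
        return [
            random_uniform(cand, k, np.random.default_rng(base + [r]), fraction)
            for r in range(replicates)
        ]
    if strategy == "rl_weighted":
        rl = table.rl_category
        missing = [s for s in cand if rl.get(s) not in RL_INDEX_WEIGHTS]
        if missing:
            raise OptionValueError(
                "rl_weighted needs a threatened universe; species without an "
                f"RL Index weight: {sorted(missing)[:5]}"
            )
        weights = {s: float(RL_INDEX_WEIGHTS[rl[s]]) for s in cand}
        return [
            sample_weighted(
                cand, weights, k, np.random.default_rng(base + [r]),
                strategy="rl_weighted", fraction=fraction,
            )
            for r in range(replicates)
        ]
    if strategy == "fdist_weighted":
        fd = table.fdist.loc[sorted(cand)]
        positive = fd[fd > 0]
        floor = float(positive.min()) / 2 if len(positive) else 1.0
        weights = fd.clip(lower=floor).to_dict()
        return [
            sample_weighted(
                cand, weights, k, np.random.default_rng(base + [r]),
                strategy="fdist_weighted", fraction=fraction,
            )
            for r in range(replicates)
        ]
    if strategy == "rl_controlled":
        if not templates:
            raise OptionValueError(
                "rl_controlled needs template selections (greedy PD sets)"
            )
        rl = table.rl_category
        return [
            sample_rl_controlled(cand, rl, tpl, np.random.default_rng(base + [r]))
            for r, tpl in enumerate(templates)
        ]
    raise ValueError(f"unknown strategy {strategy!r}")


def write_selections(results: Sequence[SelectionResult], path) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(r.to_record(), sort_keys=True) + "\n")


def read_selections(path) -> list[SelectionResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(SelectionResult.from_record(json.loads(line)))
    return out


def capture_advantage_ses(
    *,
    n_tips: int,
    n_trees: int,
    prevalence: float,
    clumping: float,
    fraction: float,
    sets_per_tree: int = 3,
    n_null: int = 300,
    seed: int = 0,
    category: str = "food",
):
    """SES of greedy-PD capture against uniform random sets for one synthetic
    benefit regime (one experiment replicate).

    Generates an ensemble and attribute table in which ``category`` has the
    given prevalence and clumping, selects greedy PD-maximizing sets and
    uniform random sets at ``fraction``, and returns the capture SES.
    """
    synth = SynthConfig(
        n_tips=n_tips,
        n_trees=n_trees,
        prevalence={category: prevalence},
        clumping={category: clumping},
        seed=seed,
    )
    ensemble, table = generate(synth)
    greedy = generate_selections(
        "greedy_pd", ensemble, table, fraction,
        sets_per_tree=sets_per_tree, seed=seed,
    )
    null = generate_selections(
        "random_uniform", ensemble, table, fraction,
        replicates=n_null, seed=seed,
    )
    obs = summarize_capture(greedy, table, category)
    nul = summarize_capture(null, table, category)
    return ses_between(obs, nul)


# ---------------------------------------------------------------------------
# run_experiment
# ---------------------------------------------------------------------------


def _load_inputs(config: ExperimentConfig) -> tuple[TreeEnsemble, SpeciesTable]:
    if config.synth is not None:
        synth = SynthConfig(**{**config.synth, "seed": config.synth.get("seed", config.seed)})
        return generate(synth)
    for path in (config.trees, config.species):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    ensemble = read_tree_ensemble(config.trees)
    table = read_species_table(config.species)
    return reconcile(ensemble, table, policy="intersect")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run every requested strategy × fraction × category cell and write the
    capture report, persisted selections and a manifest to ``out_dir``.

    Outputs are a pure function of the configuration (and thus of its hash):
    deleting them and rerunning reproduces them byte for byte.
    """
    ensemble, table = _load_inputs(config)
    out = Path(config.out_dir)
    (out / "selections").mkdir(parents=True, exist_ok=True)
    needs_scores = any(s in _RANK_STRATEGIES for s in config.strategies)
    scores = None
    if needs_scores:
        cand, _ = resolve_universe(ensemble, table, config.universe)
        scores = distinct_scores(
            ensemble,
            rl_category=table.rl_category,
            fdist=table.fdist,
            universe=cand,
        )

    all_selections: dict[tuple[str, float], list[SelectionResult]] = {}

    def selections_for(strategy: str, fraction: float) -> list[SelectionResult]:
        key = (strategy, fraction)
        if key not in all_selections:
            templates = None
            if strategy == "rl_controlled":
                greedy = next(
                    (s for s in config.strategies if s in _GREEDY_STRATEGIES), None
                )
                if greedy is None:
                    raise OptionValueError(
                        "rl_controlled requires a greedy strategy to template"
                    )
                templates = selections_for(greedy, fraction)
            all_selections[key] = generate_selections(
                strategy,
                ensemble,
                table,
                fraction,
                universe=config.universe,
                scores=scores,
                templates=templates,
                replicates=config.replicates,
                sets_per_tree=config.sets_per_tree,
                seed=config.seed,
            )
            fname = f"{strategy}_f{fraction:g}.jsonl"
            write_selections(all_selections[key], out / "selections" / fname)
        return all_selections[key]

    rows = []
    for fraction in config.fractions:
        null_sets = selections_for(config.null_strategy, fraction)
        for strategy in config.strategies:
            sel = selections_for(strategy, fraction)
            for category in config.categories:
                obs = summarize_capture(
                    sel, table, category, include_other=config.include_other_in_all
                )
                nul = summarize_capture(
                    null_sets, table, category,
                    include_other=config.include_other_in_all,
                )
                report = ses_between(obs, nul)
                rows.append(
                    {
                        "strategy": strategy,
                        "fraction": fraction,
                        "category": category,
                        "mean": obs.mean,
                        "ci_low": obs.ci95_low,
                        "ci_high": obs.ci95_high,
                        "null_mean": report.m_null,
                        "null_sd": report.sd_null,
                        "ses": report.ses,
                        "tier": report.tier,
                    }
                )
                logger.info(
                    "cell %s x %.3g x %s: mean=%.2f ses=%.2f %s",
                    strategy, fraction, category, obs.mean, report.ses, report.tier,
                )
    report_frame = pd.DataFrame(rows)
    report_frame.to_csv(out / "capture_report.csv", index=False)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_trees": len(ensemble),
        "n_species": len(table),
        "cells": [
            {"strategy": r["strategy"], "fraction": r["fraction"], "category": r["category"]}
            for r in rows
        ],
        "outputs": sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
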