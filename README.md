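# optionvalue

**Phylogenetic diversity and the option value of biodiversity.**

Many benefits that species provide to people — food, materials, medicine —
were, at some point in history, unknown future options. Conserving
*phylogenetic diversity* (PD) has been proposed as a way to keep those options
open: a species set spanning more of the Tree of Life should span more
distinct features, and hence more potential future benefits. `optionvalue` is
a library and command-line tool for testing that claim empirically: it asks
whether selecting species to maximize PD — with no knowledge of their uses —
captures species with *known* human uses better than selecting at random or by
extinction risk alone. It is aimed at researchers in conservation
prioritization and macroevolution who want a tested, reproducible
implementation of the full pipeline, including a synthetic study-system
generator so that every stage can be exercised without restricted data.

## What it computes

* **Faith's PD** of a species set `S` on a rooted tree: the summed length of
  all branches on the paths from members of `S` to the root, each branch
  counted once (rooted convention).
* **Fair-proportion evolutionary distinctiveness (ED)**: each branch's length
  is split equally among its descendant tips, so ED partitions total PD among
  species; medians are taken across a tree ensemble.
* **EDGE scores**: `EDGE = ln(1 + ED) + GE · ln 2`, with global endangerment
  GE mapped from the IUCN Red List category (LC=0, NT=1, VU=2, EN=3, CR=4,
  EW=5).
* **Greedy PD maximization**: the set of size *k* maximizing PD (exact on
  trees; verified against exhaustive search), optionally maximizing the *gain*
  over a secured set of low-risk (LC/NT) species.
* **Null selection strategies**: uniform random; Red-List-weighted sampling
  (weights VU=2 … EW=5); Red-List-controlled sampling (matching a template's
  category composition exactly); FDist-weighted sampling.
* **Evaluation**: capture counts of utilized species per strategy, compared by
  a standardized effect size `SES = (M_obs − M_null) / SD_null` with
  significance tiers at |SES| ≥ 1.96 / 2.576 / 3.891; tip-shuffle dispersion
  SES (negative = phylogenetically clumped); order-level overrepresentation
  permutation tests; top-*k* overlap between ED and FDist rankings;
  Kruskal–Wallis + Dunn, Welch's *t*, and Pearson correlations for
  distinctiveness comparisons.
* **Synthetic study systems**: ensembles of rooted ultrametric pure-birth
  trees with shared topology and resampled divergence times, plus species
  tables with controllable use-category prevalence, phylogenetic clumping,
  Red List composition, and ED–FDist correlation.

## Worked example

Generate a synthetic study system in which a rare "medicine" benefit sits on
phylogenetically distinct lineages while a prevalent "pets" benefit is
strongly clumped, then compare greedy-PD selection against uniform random
sets:

```python
from optionvalue import SynthConfig, generate, dispersion_ses
from optionvalue.experiment import ExperimentConfig, run_experiment

synth = {
    "n_tips": 500, "n_trees": 5, "seed": 42,
    "prevalence": {"medicine": 0.02, "pets": 0.35},
    "clumping": {"medicine": -1.0, "pets": 0.8},
}
ensemble, table = generate(SynthConfig(**synth))
for cat in ("medicine", "pets"):
    rep = dispersion_ses(ensemble, table.flagged(cat), n_shuffles=500, seed=1)
    print(f"{cat}: dispersion SES = {rep.ses:+.2f} ({rep.tier})")

run_experiment(ExperimentConfig(
    out_dir="demo_out", synth=synth,
    fractions=[0.05, 0.25], strategies=["greedy_pd"],
    categories=["medicine", "pets"], replicates=300, sets_per_tree=4, seed=42,
))
```

Output:

```
medicine: dispersion SES = +1.88 (ns)
pets: dispersion SES = -6.33 (***)
```

and `demo_out/capture_report.csv`:

```
 strategy  fraction category  mean  ci_low  ci_high  null_mean  null_sd  ses tier
greedy_pd      0.05 medicine  2.25     2.0     3.52       0.47     0.67 2.65   **
greedy_pd      0.05     pets 10.55     8.0    12.00       8.70     2.56 0.72   ns
greedy_pd      0.25 medicine 10.00    10.0    10.00       2.62     1.35 5.46  ***
greedy_pd      0.25     pets 44.70    41.0    48.00      43.84     4.55 0.19   ns
```

Reading: of the 10 species flagged for medicine, greedy-PD sets of 25 species
(5% of 500) capture 2.25 on average where random sets capture 0.47 — a
significant advantage (SES 2.65) that grows at the 25% sample size, where
greedy sets capture all 10. For the clumped, prevalent pets category the
advantage is never significant. This is the qualitative pattern the method is
designed to expose: PD selection pays off for rare benefits dispersed across
distinct lineages, not for prevalent clumped ones.

The same pipeline runs from the shell:

```bash
optionvalue synthdata generate --config synth.yaml --out-dir data/
optionvalue diversity ed --trees data/trees.nwk --out ed.csv
optionvalue select --strategy greedy_pd --trees data/trees.nwk \
    --species data/species.csv --fraction 0.05 --seed 1 --out sets.jsonl
optionvalue run --config experiment.yaml
```

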