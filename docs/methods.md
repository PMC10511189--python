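# Methods

This note documents the models and procedures implemented in `optionvalue`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic study system does and does not emulate.

## Diversity metrics

**Rooted PD.** Faith's PD of a set *S* is the total length of branches on the
union of root-to-member paths. The rooted convention (the path to the global
root is included) was chosen because it makes the fair-proportion identity
exact: summing ED over all tips returns the tree's total branch length, so ED
is literally a partition of total PD. Unrooted PD would differ by the stem
path but yields the same maximizing sets. PD is undefined without branch
lengths, so trees with missing lengths are rejected rather than imputed;
zero-length branches and polytomies are accepted, since both occur in
posterior tree samples.

**ED and EDGE.** Fair-proportion ED divides each branch equally among its
descendant tips. Over an ensemble, per-species ED is summarized by the median
(the median over an even number of trees is the mean of the two central
values — fixed for reproducibility). EDGE = ln(1 + ED) + GE·ln 2 with GE:
LC=0, NT=1, VU=2, EN=3, CR=4, EW=5. Extinct-in-the-wild sits one step above
CR, consistent with the Red List Index weightings used by the RL-weighted
sampler (VU=2 … EW=5). Data Deficient species have no defensible GE; the
package raises an error rather than guessing, and DD species are excluded
from both the threatened universe and the secured set in threatened-gain
selection.

**Dispersion SES.** The phylogenetic structure of a labeled species set is
measured against a tip-label-shuffle null: shuffling names across tips maps
the label set onto a uniformly random tip set of the same size, so the null
is the PD distribution of uniform same-size sets, computed vectorized (branch
× set incidence). SES = (observed − null mean)/null SD per tree, averaged
across the ensemble. Negative SES means clumping. Empty and complete sets are
rejected (the null SD is zero).

## Greedy PD maximization

Selection starts from the empty set (or from the "secured" low-risk species)
and repeatedly adds the candidate with the largest PD increment. On tree
metrics this greedy procedure is *exactly* optimal for every k; the test
suite verifies this against exhaustive subset enumeration on hundreds of
random trees. Exact ties — which are common, e.g. the first pick on an
ultrametric tree, where every tip has the same root path — are broken
uniformly at random with a seeded generator. This is deliberate: tie-breaking
randomness is what makes repeated runs produce *different maximizing sets*,
which is the point of generating many PD-maximizing sets per tree. Ties are
detected with a relative tolerance of 1e-9 to absorb floating-point summation
order. Rank-based selection (EDGE/ED/FDist) breaks ties lexicographically by
species id instead, because a published ranking is a single deterministic
list.

Sample sizes are `round_half_up(fraction × universe)`. Half-up rounding is a
genuine choice (5% of 1491 threatened species is 74.55, so floor gives 74 and
round gives 75); the rule is exposed through `sample_size` so either
convention can be obtained by adjusting the fraction.

**Secured sets.** For threatened-gain selection, LC and NT species are
treated as secured (their branches count toward the baseline but they are
never selected); the candidate universe is VU/EN/CR/EW. A candidate that also
appears in the secured set would always have zero gain, so the implementation
drops the overlap from the candidate pool.

## Stochastic null strategies

Weighted sampling without replacement is defined sequentially — each draw
proportional to weight among remaining species — and implemented with
exponential sort keys (`E_i / w_i`, keep the k smallest), which samples from
exactly that distribution in one vectorized pass. The RL-controlled sampler
draws, for each Red List category, exactly the number of species of that
category present in a template (e.g. a greedy set), uniformly within
category; it errors if any category is infeasible. FDist-weighted sampling
uses FDist scores as weights, with an exact zero (the minimum score after the
generator's shift) floored to half the smallest positive score so weights
stay positive.

## Evaluation

Capture counts are replicate-level intersections of selected sets with the
flagged species of a category ("all" pools food, materials, medicine and
pets; a flag adds the unreconciled "other" uses as a sensitivity variant).
Strategy comparisons use SES = (observed mean − null mean)/null SD with
significance tiers |SES| ≥ 1.96 (\*), 2.576 (\*\*), 3.891 (\*\*\*) — the
two-sided standard-normal quantiles for 5%, 1% and 0.01%. Confidence
intervals on counts are empirical 2.5/97.5 percentiles, because counts are
discrete and skewed at small set sizes.

The order-overrepresentation test redraws species sets of the observed size
uniformly (999 permutations by default) and calls an order over- or
under-represented when its observed count reaches the 97.5th or 2.5th
percentile of its null counts. On discrete counts the "≥ percentile" rule is
anti-conservative by up to the probability mass at the cutoff; its realized
type-I rate is close to 2.5% only when counts are fine-grained (large orders
and categories). Orders whose null counts are constant (e.g. an order
containing every species) are never flagged.

Kruskal–Wallis is taken from scipy; Dunn's post-hoc z tests are computed from
joint ranks with the standard tie correction, with Holm-adjusted two-sided
p-values (the adjustment method is a package choice; Holm is conservative and
order-preserving). Welch's t and Pearson's r also come from scipy.

## Synthetic study system

The generator emulates the statistical structure of a posterior sample of
ultrametric bird trees plus IUCN-style species attributes.

**Trees.** Pure birth (Yule): from two lineages at the root, a uniformly
chosen lineage bifurcates after Exp(birth_rate × lineages) waiting times;
after the n-th tip appears, one further Exp(n × birth_rate) epoch elapses, so
trees are ultrametric with expected depth Σ_{k=2..n} 1/(k·birth_rate). A
pure-birth prior was chosen over birth–death because it has closed-form
expectations for testing and extinction adds nothing the analysis needs. An
*ensemble* shares one topology and redraws epoch durations per tree:
posterior samples of a real phylogeny are topologically very similar, and
independently simulated topologies would destroy the cross-tree consistency
(of ED ranks, of greedy choices) that the ensemble-averaging step relies on.
This emulates divergence-time uncertainty only — topological uncertainty is
not represented, a known limitation.

**Use labels.** Each category flags `round(prevalence × n_tips)` tips, with a
clumping knob in [−1, 1]: 0 draws uniformly; +1 takes the smallest clade
holding the quota, trimmed to size by descending child-subtree size (the
"trim by proximity" of a clade is ambiguous on ultrametric trees, where all
of a clade's tips are equidistant from its root; taking whole child subtrees
keeps the trimmed set maximally clumped); −1 takes the tips with the highest
fair-proportion ED. Intermediate magnitudes fill a fraction |clumping| of the
quota from the structured scheme and the rest uniformly. Negative clumping
encodes the empirically relevant "dispersed benefit" regime: benefits carried
by phylogenetically distinct lineages. Such label sets have moderately
positive dispersion SES — distinct lineages are spread out but not maximally
so — which mirrors real utilization categories, whose PD-capture advantage
comes from distinctiveness rather than from literal overdispersion.

**Attributes.** Red List categories are multinomial with configurable
proportions (default ≈75% LC, 14.5% threatened, 1% DD — a realistic avian
composition). Pseudo-taxonomic orders are the clades founded by the earliest
lineages (about one order per 15 tips by default). FDist is a rank-blend:
Blom normal scores of median-ED ranks mixed with independent Gaussian noise,
with the blend weight solved numerically (Brent) so the *realized* Pearson
correlation with median ED matches the configured target (default 0.11, a
weak positive coupling); the blend is shifted to be nonnegative, which leaves
the correlation unchanged. At a target of ±1 the blend degenerates to the
(anti)monotone transform of ED rank.

**Default prevalences** (pets 0.35, food 0.13, materials 0.010, medicine
0.005, other 0.036) follow the relative frequencies of recorded bird uses;
default clumping is ordered pets ≫ food > other > materials ≈ medicine,
matching the qualitative dispersion ordering of those categories.

**Determinism.** One master seed; topology, per-tree times, Red List draws,
per-category labels and FDist noise each use a stream derived from the master
seed by fixed integer offsets, so any sub-experiment is replicable in
isolation and identical configurations produce byte-identical outputs.

**What passing tests do not show.** The generator reproduces the pipeline's
*statistical* structure, not avian biology: no trait evolution, no geography,
no correlation between threat status and phylogeny, no taxonomic error, and
topological certainty within an ensemble. Results on synthetic data validate
the machinery and the qualitative mechanism, not real-world effect sizes.

## Problem sizes used in validation

The test suite and acceptance script run scaled-down designs chosen so each
check has adequate statistical power: greedy exactness on 6–12-tip trees
(where exhaustive enumeration is feasible); SES calibrations on 100-tip
trees with hundreds of label replicates; and the central-result contrast on
500-tip, 4-tree ensembles with 3 greedy sets per tree and 300 null sets. The
500-tip size for the central result is a mechanistic requirement, not a
convenience: greedy PD selects one random representative per deep lineage, so
with only ~5 selection slots (5% of 100 tips) a specific flagged tip is
rarely captured on pure-birth trees, which — unlike real bird phylogenies —
seldom contain ancient depauperate lineages. At 500 tips (25 slots, 10
flagged species) the capture advantage for distinct-lineage benefits is
strong and reproducible while the prevalent-clumped regime stays
non-significant.

## Known limitations

* Topological uncertainty across an ensemble is not modeled.
* The clumping knob is a direct quota mixture, not a trait-evolution model;
  its dispersion SES response is monotone but not linear.
* The order-overrepresentation percentile rule is anti-conservative on
  coarse-grained counts (small orders or categories).
* EDGE requires a defined GE; Data Deficient species must be resolved or
  excluded by the caller.
* `reconcile` matches names only by normalized string equality — no synonym
  resolution or fuzzy matching.
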