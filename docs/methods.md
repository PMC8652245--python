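# Methods

`discordia` quantifies topological conflict between per-locus gene trees
and a species tree and asks whether that conflict is explicable by
incomplete lineage sorting (ILS) alone. This note documents the models,
the filters, the statistics, the synthetic-data generator, and the
numerical choices the package makes where the design was genuinely open.

## Tree distances

All comparisons use branching order only; branch lengths are ignored.
Both trees are first pruned to their shared tips, and a comparison is
attempted only when at least four tips are shared. Splits (nontrivial
bipartitions of the shared tip set) are the unit of comparison; rooted
trees are compared on their unrooted topology, so the two edges meeting
at a root contribute one split.

Three normalized distances in [0, 1] are computed, 0 meaning identical
split sets:

* **RF** — Robinson–Foulds, `(|S1\S2| + |S2\S1|) / (|S1| + |S2|)`. The
  `|S1|+|S2|` denominator handles polytomous trees naturally, since a
  collapsed tree simply contributes fewer splits.
* **Nye** — generalized RF. Each cross-tree split pair is scored by the
  better of the two side alignments, each alignment scored by the worse
  of its two Jaccard overlaps; a maximum-weight one-to-one matching `S`
  over split pairs is found by an exact linear assignment (not greedily),
  and `d = 1 − 2S/(|S1|+|S2|)`.
* **CI** — clustering-information distance. Split pairs are scored by
  their mutual clustering information in bits,
  `I = Σ (|X∩Y|/n) log2(n|X∩Y|/(|X||Y|))` over the four side
  intersections; with `M` the optimal matching value and `Hi` the summed
  split entropies, `d = (H1 + H2 − 2M)/(H1 + H2)`.

Logarithms are base 2 throughout; the base cancels after normalization.
The normalizations reduce to 0 at identity and 1 at total conflict and
are applied identically to observed and simulated trees, so the
observed-vs-expected contrast downstream does not depend on the choice.
A distance is reported as undefined (and the locus skipped with a
warning) only when both trees are stars on the shared tips. Pairwise
split scores are evaluated as vectorized matrix operations; the
assignment is solved on the score matrix (implicitly zero-padded to
square by the solver), and ties between optimal matchings are broken
arbitrarily since any optimum has equal value. The exact-matching
implementations are verified in the test suite against a brute-force
matcher that enumerates every injective split pairing on all 6-tip tree
pairs and sampled 7-tip pairs.

## Filters

Two filters reproduce standard practice for anchored-enrichment data:

* **Support collapsing.** Gene-tree edges whose support is strictly below
  a threshold (default 0.33, i.e. 33% bootstrap) are contracted into
  polytomies before profiling; edges without support values and pendant
  edges are never collapsed. Plastome trees in the cytonuclear comparison
  are collapsed at 0.75.
* **Occupancy.** A locus enters a clade's profile only when it contains
  strictly more than a minimum fraction (default 0.75) of that clade's
  taxa.

Newick internal-node labels are read as supports; if any value exceeds 1
anywhere in a tree, all values are interpreted as percentages and divided
by 100 (both bootstrap percentages and posterior probabilities occur in
practice). When pruning suppresses a path of edges, the merged edge
takes the minimum of the merged supports — confidence is never inflated.
Gene trees are rooted on the first outgroup set (ordered priority list)
with at least one member present, on the edge subtending the smallest
clade containing all present members; trees in which no such proper
clade exists are excluded from the concordance tally, and the run log
counts them.

## The ILS null and the adequacy test

Expected gene trees are simulated under the multispecies coalescent
contained in the species tree, whose branch lengths are read as
coalescent units (one unit = 2N generations; no separate population-size
surface). Within a branch, k lineages coalesce at rate k(k−1)/2;
surviving lineages merge at speciation nodes and coalesce to a single
lineage above the root. One haploid copy is sampled per species tip.
Simulated trees are complete and binary and carry no supports, so only
the pruning filter applies to them; a configuration flag can instead
subject the null to the observed-style missingness model. The simulator
is validated against closed-form coalescent theory: the three-taxon
concordance probability `1 − (2/3)e^(−t)`, the unit-exponential law for
the excess of the pairwise coalescence time over the species divergence,
topology symmetries, and the containment bound itself.

The per-clade adequacy test compares the observed per-locus distances
with the simulated ones (default 1,000 gene trees) using a two-tailed
Welch's t-test: `t = (x̄−ȳ)/√(vx/nx + vy/ny)` with Welch–Satterthwaite
degrees of freedom. A positive excess flag marks observed discordance
above the ILS expectation. Among-clade differences use a one-way ANOVA
followed by all-pairs Tukey HSD on the studentized-range distribution
(Tukey–Kramer standard errors for unbalanced groups), summarized as a
compact letter display built by insert-and-absorb so two clades share a
letter exactly when their adjusted p ≥ α (default 0.05). p-values come
from the scipy t, F, and studentized-range distributions. Raw p-values
are reported per test; no multiplicity adjustment is applied across
clades or metrics, and readers should interpret borderline p-values
accordingly.

## Reticulations

Introgression is modeled as level-1 reticulation events: each event sits
at a fixed time on a recipient edge and, independently for each gene,
reroutes all lineages present there to a donor edge with inheritance
probability γ ∈ (0, 0.5]. The whole locus follows one parental path (no
within-locus recombination), matching the reading of γ as the fraction
of the genome involved. Event times must lie strictly inside both edges'
time spans. The plastome is simulated as a single locus with branch
lengths multiplied by 2 (smaller effective size of a haploid,
uniparentally inherited genome; the factor is configurable); with the
chloroplast-capture flag, the plastome takes the donor path
deterministically rather than with probability γ.

## Concordance tallies and quartet score

For every internal species-tree clade C, each rooted gene tree g with at
least one tip inside and one outside C is classified: *concordant* if
the ≥2 present clade tips form a clade in g; *conflicting* if some clade
of g positively conflicts (intersects C∩tips(g) but neither contains nor
is contained in it) and C∩tips(g) is non-monophyletic; otherwise
*uninformative* — which deliberately includes non-monophyly expressed
only through polytomies, and cases with fewer than two clade tips. The
four counts therefore always sum to the number of gene trees analyzed at
the node. The most frequent positively conflicting clade across gene
trees is reported as the main conflict, with ties broken by
lexicographically smallest tip set so output is deterministic.

The normalized quartet score is the fraction of resolved gene-tree
quartets whose topology the species tree shares, pooled over gene trees.
Exact enumeration is permitted up to 25 shared tips (quartet count grows
as n⁴); above that, quartets are sampled with a seed, allocated across
gene trees in proportion to their quartet counts so the sampled score is
an unbiased estimate of the exact one.

## The synthetic-data generator

The generator emulates the derived tree-level structure of a ~190-tip,
~114-locus target-capture study of a large plant radiation:

* **Species tree.** A pure-birth backbone joins six clade blocks (93,
  10, 10, 37, 20 tips plus a 20-tip outgroup block by default), each
  grafted as its own pure-birth subtree, so clades are monophyletic by
  construction. Root depth defaults to 8 coalescent units with clade
  crowns at 2 — a deep, well-resolved backbone over young, ILS-rich
  radiations. These depths are a modeling choice for a realistic mix of
  strong backbone signal and substantial within-clade discordance, not a
  fit to any particular dataset.
* **Gene trees** are contained-coalescent draws, optionally through
  reticulations.
* **Estimation error.** Each gene tree receives Poisson-many random
  nearest-neighbor interchanges (rate 1 by default). Supports are drawn
  from Beta distributions: edges adjacent to a perturbation from
  Beta(2, 12) (93% of its mass below 0.33), others from Beta(14, 2). A
  second support mode draws low supports on edges whose split conflicts
  with a reference topology, mimicking the empirical tendency of
  bootstrap values to be weak exactly where a gene tree departs from the
  dominant signal; this mode is what makes support-collapsing remove
  conflicting splits preferentially, as it does in real data.
* **Missingness.** Each (tip, locus) pair is retained independently with
  probability 96.25/114 ≈ 0.844 (mean loci recovered per sample in the
  emulated study); outgroup tips retain at half that rate, reflecting
  probe-set divergence. Loci left with fewer than four tips are dropped
  and logged.

Equal seeds give byte-identical serialized studies; per-locus seeds are
spawned from the master seed so results do not depend on evaluation
order.

What the generator does *not* emulate: sequence-level error,
among-locus rate or length variation, non-independent (clustered)
missingness, rogue taxa, alignment or orthology failures, and any
particular empirical topology. Passing tests therefore demonstrate the
pipeline's statistical behaviour under a clean, known generative model,
not the idiosyncrasies of any real dataset.

## Validation experiments

`discordia.experiments` fixes four studies, shared by the test suite and
`scripts/acceptance.py`:

* **Coalescent calibration** — empirical three-taxon concordance at
  t ∈ {0.5, 1, 2} versus the closed form, n = 10,000.
* **Type-I error** — 200 replicates of the CI-metric adequacy test with
  observed trees drawn from the null itself (20-tip tree, 100 loci, 200
  simulated expected trees per replicate; the smaller-than-default null
  sample keeps the experiment fast and is handled exactly by the Welch
  test's unequal-n form).
* **Power** — a fixed 26-tip species tree with three 8-tip clades;
  gene flow at γ = 0.3 between two non-sister cherries inside clade A.
  Within-clade gene flow is used because an event into a clade's stem
  does not alter the clade's pruned topology and is undetectable by
  within-clade profiling. Clade C serves as an untouched control.
* **RF sign anomaly** — observed trees with conflict-aware supports,
  collapsed at 0.75, against a binary ILS expectation. Removing
  conflicting splits shrinks the RF numerator faster than its
  denominator, so observed RF drops below the expectation while the
  information-weighted CI does not: collapsing poorly supported edges
  downplays discordance under RF. This reproduces the empirically
  familiar pattern of negative RF contrasts alongside positive Nye/CI
  contrasts for the same clades.

## Numerical choices and degenerate inputs

* Mutual information and entropies use exact popcount arithmetic on
  bitmask splits; matrix variants use integer-count matmuls and are
  tested to 1e-12 against the scalar definitions.
* Newick round-trips preserve lengths and supports to 1e-9 (10
  significant digits are written).
* Rooting places the new root at the midpoint of the chosen edge when a
  length exists; distances ignore lengths, so only the split structure
  matters.
* Thresholds are strict inequalities: support exactly at the collapse
  threshold is kept; occupancy exactly at the minimum is dropped.
* Degenerate inputs raise typed errors: fewer than four shared tips,
  empty profiles (with the responsible filter named), unrootable trees,
  zero-variance Welch samples, single-clade comparisons.
* Reported distances are clipped to [0, 1] against floating-point noise.

## Limitations

The pipeline consumes trees; it never infers them from sequence, and it
does not estimate networks, concordance factors, or divergence times.
The adequacy test conditions on the species tree and its coalescent-unit
branch lengths being correct; misestimated lengths shift the null. The
missingness model is independent per (tip, locus), which is optimistic
relative to real capture data. Absolute distance means depend on the
normalization conventions above, so they are comparable within this
package but not necessarily to other implementations' absolute values;
observed-vs-expected contrasts are the supported inference.
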