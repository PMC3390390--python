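# Methods

## The model

`slapnet` scores the association between two nodes of a typed
heterogeneous network — canonically a chemical compound and a protein
target — from the bounded-length simple paths connecting them. The
procedure has four stages.

**Traversal probabilities and raw path scores.** The network is
undirected; each node carries one class label and each edge one type
label. A traversal step from node *v* along an edge of type *t* is
assigned probability `1 / type_degree(v, t)` — equal probability over the
node's same-type neighbors — so a path's probability is the product of
its step probabilities and its log-probability the sum of step logs.
Because the graph is undirected, the *raw score* of a path is the average
of the two directional log-probabilities. Raw scores are nonpositive;
zero occurs only when every traversed step in both directions has type
degree 1. Natural logarithms are used throughout; the base is immaterial
because a change of base rescales all raw scores within a pattern by one
constant, which the z-normalization removes (verified to 1e-9 in the
tests).

**Pattern z-normalization.** Paths sharing the same alternation of node
classes and edge types form a *pattern* (a meta-path); signatures are read
from the query end and not symmetrized. Raw scores are only comparable
within a pattern, so each pattern is normalized against a random-pair
sample: `fit_pattern_stats` samples pairs uniformly without replacement
from the declared source × target pools (minus known positives, when
supplied), enumerates all paths up to the length bound, and fits each
pattern's raw-score mean and standard deviation. A pattern is *usable*
when it has at least 30 sampled paths and a standard deviation above
1e-9; unusable patterns contribute nothing. Each observed path then gets
`z = (raw − mu) / sigma` for its pattern.

**Association score and pattern selection.** Only paths with z > 0 in
patterns that survived informativeness selection are *valid*; the
association score of a pair is the sum of its valid-path z scores (zero
if none). Informativeness is judged per pattern on labeled benchmarks:
for every benchmark pair the raw scores of its paths matching the pattern
are summed, pairs are ranked by evidence strength (the negated sum — raw
sums are nonpositive, so more and stronger paths mean a more negative
sum, and a pair with no matching path sits at zero, the weakest
evidence), and the pattern's AUROC is computed with the midrank tie
convention. A pattern is removed only when its AUROC is at or below the
threshold (default 0.55, configurable) on *every* supplied benchmark;
removal requires agreement between benchmarks.

**Null model and p-values.** The logarithms of strictly positive
association scores of random pairs are fitted to a normal distribution;
zero-score pairs are excluded (their count is recorded) and a score's
p-value is the null's upper-tail probability, with p = 1 by convention
for a zero score. `significance_threshold(null, alpha)` inverts the
p-value exactly. Polypharmacology profiles are rows of a drugs × targets
score matrix; profile similarity is the Pearson correlation between rows
(zero-variance profiles propagate as missing values, not zeros), and the
drug-similarity network links pairs at or above a correlation cut-off
(default 0.75), keeping isolated drugs as visible isolates.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `max_path_length` | 3 edges | path-length bound for every enumeration |
| `min_pattern_paths` | 30 | sampled paths needed for a usable pattern |
| `pattern_threshold` | 0.55 | benchmark AUROC at or below which a pattern is uninformative |
| `alpha` | 0.05 | significance level for matrix filtering |
| `similarity_threshold` | 0.75 | Pearson cut-off for the drug network |
| `n_sample_pairs` / `n_null_pairs` | 2000 / 1000 | random pairs for pattern and null fits |

The informativeness threshold is a knob because the separation between
useful and useless patterns is data-dependent; 0.55 sits between
near-chance patterns (≈0.5) and clearly informative ones (≥0.6 and
usually well above) on the synthetic benchmarks.

## Direct-link exclusion

Evaluation removes the known direct edge(s) between a pair before
enumeration, as an *edge* exclusion: longer paths re-using the direct
edge are removed along with the length-1 path, so the score measures
neighborhood evidence only (the "missing link" setting). Profile building
keeps direct links by default — a drug's signature should include its
known targets.

## Path enumeration

All simple paths up to the length bound are enumerated (not only
minimum-length ones): the association score is defined over the full
bounded path set, and shortest-path-only enumeration is kept as the
`n_shortest_paths` baseline. The enumerator is a depth-first search
pruned by a breadth-first distance map from the target; exclusion-free
distances are a lower bound on constrained distances, so pruning is
exact. Output order is deterministic (sorted by length, signature, node
sequence) so downstream floating-point sums are bit-reproducible, and the
whole fit is a pure function of the seed.

## The synthetic-data generator

`synth.generate` emulates an integrated chemical-biology network at desk
scale: 10 node classes (compounds, targets, genes, GO terms, pathways,
substructures, chemical ontology terms, side effects, tissues, diseases)
joined by 12 edge types. Defaults: 300 compounds, 150 targets, smaller
annotation vocabularies; background mean degrees per edge type are chosen
so a random compound–target pair averages roughly one path via the
binding/annotation mechanisms and a handful via expression-style noise
routes. Background edges are drawn per type with lognormal node
propensities (sigma 0.8, Chung–Lu style; `degree_skew=0` gives
Erdős–Rényi). The heavy-tailed default matters: with a homogeneous
background, simple path counting is itself an excellent link detector and
the raw-score baselines become strongly anti-correlated with the truth,
inverting the method ordering that motivates z-normalization; real
chemical-biology networks are strongly degree-skewed.

Planted positives are missing links: each planted (drug, target) pair
receives `planting_strength` (default 3) indirect evidence routes drawn
among three mechanisms — shared ligand (D–bind–T′–bind–C′–bind–T), shared
GO annotation (D–bind–T′–hasGO–G–hasGO–T) and shared substructure
(D–hasSubstructure–S–hasSubstructure–D′–bind–T) — without the direct bind
edge (a flag adds it). Planted routes pick intermediates uniformly, so
they are less hub-biased than background paths and tend to carry positive
z, which is exactly the evidence the method is designed to read.

Two special-purpose configurations:

- `calibration_config` is the regime in which the statistical model is
  actually fitted on real data — dense (random pairs average tens of
  paths) and homogeneous. There the within-pair spread of z scores makes
  random-pair association scores genuinely log-normal; in sparse or
  skewed regimes the left tail of low-path-count pairs visibly breaks the
  normal fit of log scores. Null calibration (p-value uniformity) is
  therefore studied on this configuration, planted-link recovery on the
  sparse default.
- `generate_drug_groups` builds the profile-clustering fixture as
  *identically wired modules*: each group has its own target panel, GO
  pool and substructure pool, with every group wired by the same rules
  and connected globally only by expression/tissue noise. The symmetry is
  essential: per-path scores are degree-normalized against pattern-wide
  fits, so a group wired more densely than an amorphous background is
  discounted as hub structure (z < 0) and its planted signal vanishes;
  identical modules instead put every within-group path squarely inside
  its pattern's distribution while cross-group pairs have almost no
  informative paths.

What the generator does *not* emulate: real degree distributions and
correlations between annotation layers, incomplete/biased curation,
binding-affinity weights, multiple node classes per entity, and any
chemistry (substructures are opaque tokens). Passing tests therefore
demonstrate that the statistical machinery behaves as designed under a
known ground truth, not that the method attains any particular accuracy
on real drug–target data.

## Problem sizes and numerical choices

The test and acceptance runs use networks of ~700–1000 nodes, pattern
fits on 400–4000 sampled pairs, null fits on 70–2000 pairs and 10-seed
replicates; these sizes give stable medians for every property under
study while keeping the full suite a few minutes of one CPU.
Ties in every ranking use the midrank (Mann–Whitney) convention through
one shared implementation. Degenerate inputs fail loudly: zero-variance
patterns are unusable rather than infinite-z, an all-zero score list
cannot fit a null, filtering that would empty a matrix raises with a
diagnostic, and unmapped nodes yield a `not_mapped` status distinguishable
from "no paths".

## Known limitations

- Enumeration cost grows with the cube of typical degree at the default
  length bound; very dense networks need sampling or a smaller bound.
- The log-normal null is an approximation; it is accurate in the dense
  regime it is fitted for and degrades for sparsely connected pairs
  (their scores cluster at zero and are assigned p = 1).
- Pattern selection with small benchmarks is noisy; benchmarks of a few
  hundred pairs per class are needed before the 0.55 threshold separates
  reliably.
- Edge weights (e.g. binding affinities) only enter as an optional load
  filter, not as traversal probabilities.
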