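# Methods

## Scoring model

The substrate is an undirected simple graph G over gene symbols (uppercased,
whitespace-trimmed; no alias resolution — symbols are matched verbatim across
input files, since no mapping procedure is better than a wrong one).
Parallel edges and self-interactions in the input are dropped at graph build
with a logged count; edge direction and interaction-evidence annotations are
ignored.

Against a seed set S (known disease genes), gene g receives two counts:

* direct score d(g) = |N(g) ∩ S \ {g}|,
* indirect score i(g) = Σ_{s ∈ S\{g}} |N(g) ∩ N(s) \ {g, s}|,

i.e. the number of length-2 paths g–x–s with x distinct from both endpoints.
Two deliberate choices in i(g):

1. **Intermediates may be any node, including other seeds.** Nothing in the
   underlying association argument restricts who the shared partner is, and
   excluding seeds would silently couple the score to the seed list's
   composition.
2. **Per-(seed, intermediate) counting.** When several seeds share one hub
   with g, each (seed, hub) pair contributes one path. The per-pair sum is
   the natural "interaction number per positive gene, summed over positives";
   the alternative — counting distinct intermediates once — is exposed as
   `intermediates="distinct"` on the scoring functions and `--intermediates`
   on the CLI, because the two readings cannot be distinguished from a
   single-seed example.

A seed never contributes to its own score (s is removed when scoring g = s),
so seed scores measure connectivity to *other* seeds — this is what the
summary's "positive gene interaction" counts rely on. Genes absent from the
network score 0 with a logged warning rather than an error, because curated
disease lists routinely contain genes with no catalogued interactions.

`score_all` computes all scores in one accumulation pass over the seeds'
two-hop neighborhoods (complexity ~ Σ_{s∈S} Σ_{x∈N(s)} deg(x)), and is
property-tested against an independent brute-force path enumeration.

## Classification, thresholds, ranking

Non-seed genes with d ≥ 1 are level-1 candidates; with i ≥ 1, level-2
candidates; level-2-only means i ≥ 1 and d = 0. Prior candidates use
**strict** thresholds — i > 50 and d > 4 by default ("more than 50",
"greater than 4") — both configurable. Seeds are excluded from candidate
output even when their scores would qualify. Ranking is total and
deterministic: indirect score descending, direct score descending, then
lexicographic symbol. Summary percentages (fraction of seeds with a
direct/indirect link to another seed) are rounded half-up to two decimals,
with raw fractions carried alongside; fold changes between the positive and
candidate score distributions are reported unrounded.

The summary's "indirect interactions" figure is the sum of candidate
indirect scores, i.e. a path count under the per-pair convention; a
pair-of-genes count would be smaller whenever hubs are shared. The figure is
therefore labeled by what it is, not treated as comparable across counting
conventions.

## Cross-validation

`holdout_cv(net, seeds, k=5, n_reps=100, rng_seed)`:

* **Eligible pool**: seeds with at least one direct AND one indirect
  interaction with another seed — the seeds both networks can "see". The
  pool must exceed k.
* Per replicate, k pool seeds are deleted, the whole network is rescored
  against the reduced seed set, and for each scoring level the statistic is
  mean(score of the k held-out genes) / mean(score of all non-seed genes).
  The held-out genes are scored *as if unknown*; this reading makes the
  ratio a measure of predictive power. (The alternative numerator — the
  remaining seeds — is available as `comparison_group="remaining"`.)
* Both levels use the SAME deletion set in each replicate, so the 100
  (level-2, level-1) ratio pairs are matched; the final comparison is a
  two-sided paired-samples t-test (α = 0.05). Zero-variance differences are
  special-cased: all-zero → t = 0, p = 1; constant non-zero shift →
  t = ±inf, p = 0.
* A replicate whose candidate mean is zero has an undefined ratio and is
  redrawn (logged, bounded retries) rather than skipped, preserving the
  paired design with exactly n_reps pairs.
* One integer seed drives a single sequential RNG stream
  (`numpy.random.default_rng`), so results are bit-reproducible.
* Each replicate also records where the held-out genes would rank among the
  candidates by indirect score (median rank as a fraction of the ranked
  universe) — the recovery statistic used by the planted-module test.

Note one structural subtlety the null test exposed: because the pool
conditions on having seed links, held-out genes are a *selected* subsample,
and on sparse random graphs this selection alone pushes the level-1 ratio
above 1. The null check therefore uses a dense uniform graph (300 genes,
edge probability 0.1, 30 random seeds) where nearly every seed is eligible
and the selection effect is negligible; both mean ratios then fall in
[0.8, 1.2] at 200 replicates.

## Coincidence profiles and set overlap

`coincidence_profile` bins ranked candidates by inclusive rank cutoffs
(default 14, 76, 965 plus an open tail — the bin layout used for comparing
top-ranked candidates against expression data) and reports per bin the
fraction present in a reference gene list. Bin edges are fully configurable
since different analyses bin differently. Empty bins report an undefined
ratio (`None`), never 0/0. `set_overlap` is the degenerate one-bin case.

## Enrichment

One-sided hypergeometric upper tail (Fisher's exact, "greater"): for a
query of n genes in a background universe of N genes, K of which belong to
the set, p = P[X ≥ k] for the observed overlap k. All counts are taken
within the deduplicated background; query genes outside it are dropped with
a warning. Default background is caller-supplied — the natural choice is
the network's node set, since candidates are sampled from it. The
significance cutoff defaults to 0.01 on raw p-values; Benjamini–Hochberg
adjustment is available by flag and, when active, the cutoff applies to
adjusted values (both are reported). Functional coherence = intersection of
set names enriched in the candidate and seed analyses, ordered by the worse
of the two p-values. Gene-ontology term propagation is out of scope: GO
collections must be supplied pre-propagated in GMT form.

## Synthetic generator

`simulate(SimConfig)` plants the exact motif the method exploits: seeds and
"true candidate" genes that never interact directly but attach to shared
hubs. Edge probability by role pair:

| pair | probability | default |
| --- | --- | --- |
| seed–seed | `seed_edge_prob` | 0.05 |
| hub–seed, hub–true-candidate | `attach_prob` | 0.6 |
| seed–true-candidate | 0 (never) | — |
| all other pairs | `edge_prob` | 0.01 |

Defaults: 500 background genes, 20 seeds, 15 hubs, 30 true candidates.
`seed_edge_prob = 0.05` makes roughly 60–70% of seeds carry a direct link
to another seed, matching the connectivity real curated disease-gene sets
show (a majority of positives directly interacting with another positive)
and guaranteeing the cross-validation's eligible pool is well-populated.
The background is Erdős–Rényi — deliberately free of degree heterogeneity
beyond the planted hubs, so any recovery signal is attributable to the
planted structure; it does not emulate the heavy-tailed degree
distributions, study bias, or false-positive edges of real interactome
data, so passing tests demonstrate correctness of the machinery and
recoverability of planted signal, not performance on real networks.
Symbols are G000001… to avoid colliding with real gene names. With an
empty background and `attach_prob = 1`, every true candidate's indirect
score is exactly `n_hubs × n_seeds` (closed form used as a test oracle).

`emit_fixture_files` writes the generated data in every dialect the readers
accept (generic and HPRD-style edge lists, seed list, reference list with a
configurable fraction of true candidates plus decoys, GMT whose first set
is the planted module, JSON manifest of the generating configuration), and
the round trip read→build→rescore is tested for bit-identity.

## Problem sizes and numerical notes

The test suite and examples run the planted configuration above (~565
genes, ~2000 edges, 100 CV replicates) and a 330-gene dense null at 200
replicates; oracle-equivalence checks cover 200 random graphs of up to 100
nodes, and the hypergeometric tail is verified against exhaustive
combinatorial summation for every universe size N ≤ 30. These sizes
exercise every code path while keeping the full suite to a few seconds.
Scores are exact integers; the only floating-point outputs are ratios,
percentages (half-up rounding via `decimal`), and p-values (scipy's
hypergeometric survival function and paired t-test).

## Known limitations

* Symbol-string identity: no handling of gene aliases or ID drift between
  interaction and annotation sources.
* No edge weights or evidence-quality filtering; a single low-confidence
  edge counts as much as a replicated one.
* Hub genes inflate indirect scores by construction; the score deliberately
  does not correct for degree (no topology-weighted variant).
* No level-3+ neighborhoods.
* The HPRD reader consumes only columns 1 and 4 of the binary-interaction
  flat file; all evidence columns are ignored.
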