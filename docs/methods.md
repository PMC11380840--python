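# Methods

## Model and procedure

`netprio` treats disease-gene discovery as link prediction on an
undirected simple graph G = (V, E) of gene symbols. The working
assumption is the disease-module hypothesis: genes causing one disease
occupy a densely interconnected neighborhood of the interactome, so a
gene sharing many interaction partners with known disease genes is a
plausible disease gene itself.

Four local similarity indices score a pair (x, y) from Γ(x), Γ(y) and
node degrees alone: preferential attachment (k_x·k_y), Adamic-Adar
(Σ 1/log k_z over common neighbors z), Jaccard
(|Γ(x)∩Γ(y)|/|Γ(x)∪Γ(y)|) and resource allocation (Σ 1/k_z). Every
common neighbor has degree ≥ 2, so the Adamic-Adar logarithm never
vanishes. With the natural log, 1/log k ≥ 1/k termwise, hence
AA ≥ RAI with equality exactly when the common-neighbor set is empty —
a property-tested invariant.

For one disease, every non-seed network gene receives, per index, the
**maximum** score over all in-network seeds; candidates are sorted
(score descending, symbol ascending) and cut at k ∈ {10, 50, 100}. The
simple-majority-voting ensemble keeps genes present in at least
⌈n_indices/2⌉ per-index lists (2 of 4 by default); its length is set by
the votes, not by k.

Evaluation is overlap analysis: precision TP/(TP+FP), recall
TP/(TP+FN), F-measure 2PR/(P+R), with 0 substituted for any 0/0. ROC
curves use the three cutoffs as operating points, append (0,0) and
(1,1), and integrate by trapezoid. The term-level assessment repeats
the same overlap logic on significant annotation terms: an exact
one-sided hypergeometric tail P(X ≥ overlap), Bonferroni-corrected
over the tested terms, with significance at adjusted p strictly below
alpha = 0.05. The enrichment engine is implemented in-package over
user-supplied GMT files, so no annotation web service is required;
results on any given annotation release will depend on that release's
term universe.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ks` | 10, 50, 100 | rank cutoffs per index |
| `indices` | PAC, AA, JC, RAI | active indices; SMV threshold is ⌈n/2⌉ |
| `log_base` | natural | Adamic-Adar log; rankings are base-invariant |
| `zero_policy` | exclude | drop zero-score candidates before cutting at k |
| `alpha` | 0.05 | ORA significance level (strict inequality) |
| `universe_policy` | network_minus_seeds | negative class for TN/ROC |
| `strict_fn` | off | count out-of-network validation genes as FN |

## Design choices where the design was open

* **Seed aggregation.** A candidate's score is its best link to *any*
  seed (max over seeds), the natural reading of qualifying "through any
  disease-related gene". With distinct candidates this coincides with
  ranking all seed–candidate pairs and keeping the first k distinct
  candidates.
* **Seed-adjacent candidates are not excluded.** The goal is
  disease-association, not new-edge prediction; an existing interaction
  with a seed is evidence, not leakage.
* **Tie-breaking** is score descending then symbol ascending. This
  makes runs deterministic and guarantees the nesting property: the
  k=10 list is a prefix of the k=50 list, which is a prefix of k=100 —
  which in turn makes TP/FP counts monotone in k and vote counts
  monotone, so ensemble membership can only grow with k.
* **Zero-score candidates are excluded by default**: a zero
  common-neighbor score carries no evidence, and padding to k would be
  tie-break noise. PAC is zero only for isolated nodes, so PAC lists
  are effectively always full.
* **Universe for TN.** A ranked list over network genes can only ever
  contain network genes, so the negative class defaults to all network
  nodes minus the disease's in-network seeds, plus in-network
  validation genes. Validation genes absent from the network are
  reported as `unreachable` and excluded from FN by default (no ranking
  can recover them); `strict_fn` restores the harsher convention. In
  strict mode TP+FP+FN+TN exceeds the universe size by the unreachable
  count.
* **Ensemble bounds, not guarantees.** The SMV member set always lies
  between the intersection and union of its input lists, and
  |members| ≤ Σ|lists|/threshold. Its F-measure, however, is *not*
  guaranteed to dominate the single-worst index at every (disease, k) —
  the ensemble list length is vote-determined — and simulations show
  marginal dips; on average per disease it tracks the
  single-worst..single-best band, which is what the tests assert.
* **Significance limit.** As alpha → 1, "significant" degenerates to
  p_adjusted < 1; terms with zero overlap have a capped adjusted p of
  exactly 1 and stay non-significant under the strict inequality.

## Synthetic data: what it emulates and what it does not

`SyntheticScenario` defaults describe a five-disease study at desk
scale: a 1,000-node Barabási–Albert graph with m = 3 edges per new
node (the networkx convention — m isolated seed nodes, hence
m·(n−m) base edges), five disjoint planted modules of 30–50 genes
whose absent within-module edges are added with probability 0.5–0.7,
30% of each module used as seeds, validation lists of the held-out
members plus 30% decoys, and 200 GMT terms of which three per module
are drawn with sampling weight 25 toward module members. The collection
is resampled (bounded retries) until every disease's *seed list* shows
at least one Bonferroni-significant term, so the term-level workflow is
well-posed by construction. All generators are bit-reproducible from
`rng_seed`; derived child seeds stay below 2^31.

The generator reproduces the features the method exploits — heavy-tailed
degrees and dense disease modules — but not others found in real
interactomes: no study bias (hub degree correlating with how well a
gene is studied), no false-positive/false-negative interaction noise,
no overlapping modules, and annotation terms are conditionally
independent given module membership, unlike the GO hierarchy. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of clean planted signal, not expected performance on a
real PPI network, where validation overlap is far sparser.

## Numerical notes

* Candidate scoring walks seed → common neighbor → candidate, linear in
  the seeds' two-hop neighborhoods; a seed's degree-1 neighbors are
  skipped (they lead only back to the seed). Agreement with a per-pair
  brute-force oracle is property-tested.
* The hypergeometric tail uses `scipy.stats.hypergeom.sf(k−1, …)`,
  exact at these sizes, and is verified against exhaustive enumeration
  of all C(background, query) draws for backgrounds ≤ 12.
* AUC is `numpy.trapezoid` over FPR-sorted points; a degenerate
  validation/universe (an empty positive or negative class) is an
  error, and such curves are skipped in batch tables.
* Problem sizes in the default test and acceptance runs (1,000-node
  graphs, 200 terms, 20 recovery trials) were chosen as the smallest
  scale at which the planted-module signal is comfortably detectable;
  the full suite runs in seconds.

## Known limitations

* Gene symbols are compared case-sensitively with no alias mapping;
  whatever identifiers appear in the edge list are atomic.
* Only the four local indices are implemented; global and quasi-local
  indices (Katz, random walks, local path) are out of scope, as are
  weighted or score-fusion ensembles.
* The ORA is over-representation on an unordered gene list, not
  ranked/weighted enrichment, and treats the GMT as flat — GO's
  ontology structure and namespaces are not modeled.
* ROC curves from three operating points are coarse by construction;
  AUC comparisons between methods should be read accordingly.
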