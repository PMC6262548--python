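# Methods

## Propagation model

The network is a directed graph over three node kinds (TF, miRNA, lncRNA)
with exactly five permitted relation classes (TF→miRNA, TF→lncRNA,
miRNA→lncRNA, miRNA→TF, lncRNA→TF). Every relation joins two different
kinds, so the graph is tripartite and self-loops are impossible; this is
enforced at parse time. Node ordering is lexicographic by id everywhere, so
the adjacency matrix, every probability vector and every ranking are
byte-reproducible.

Random walk with restart uses the row-normalized transition matrix
`w(i,j) = A(i,j)/Σ_j A(i,j)` (zero rows for out-degree-0 nodes) and the
update `P_{t+1} = (1−α)·Wᵀ·P_t + α·P₀`. Probability therefore flows along
edge direction. Choices and defaults:

- **α = 0.5.** The conventional restart probability for regulator
  prioritization; higher α localizes mass nearer the seeds.
- **P₀ = 1/n on each of the n seeds**, zero elsewhere.
- **Convergence**: L1 distance between successive vectors `< 1e-10`. The
  L1 norm is the natural metric for probability vectors. With α = 0.5 the
  residual contracts by ≈ ×2 per iteration, so convergence takes a few
  dozen iterations; `max_iter = 10,000` is an unreachable guard.
- **Dangling nodes**: with the transition rule above, mass reaching an
  out-degree-0 node is lost on the next step, so `sum(P∞) < 1` on networks
  with sinks (the worked example converges to ≈ 0.79). This is the literal
  model; `dangling="restart"` optionally reinjects the leaked mass into
  P₀, which restores `sum(P∞) = 1` without materially changing ranks.
- **Direction**: the network stays directed by default (in- and out-degree
  are analyzed separately, and the transition rule is stated on the
  directed adjacency); `undirected=True` symmetrizes A first, as a
  sensitivity analysis.
- **Ranking**: non-seed nodes sorted by P∞ descending, ties broken by node
  id ascending — determinism is worth more than pretending tied scores
  carry order information.

An independent oracle — the closed-form solve
`p = α (I − (1−α) Wᵀ)⁻¹ P₀` — is used in the tests to verify the iterative
engine to 1e-8 per entry on dozens of random networks.

## Evaluation

LOOCV withholds each seed in turn, restarts the walk from the remaining
seeds, and labels the held-out node 1 against all non-seed nodes (other
seeds are excluded from the candidate pool). The (score, label) pairs are
pooled across folds into a single ROC curve; the AUC is its trapezoidal
area, which with average-rank tie handling equals the Mann–Whitney
probability that a positive outscores a negative (asserted to 1e-9 against
a brute-force pair count). Pooling across folds (rather than averaging
per-fold AUCs) is the standard construction when each fold contributes a
single positive.

Null models:

- **Random seeds**: seed sets of the same size drawn uniformly from all
  network nodes, without kind stratification.
- **Rewired networks**: degree-preserving double-edge swaps performed
  within each relation class (a swap across classes would create a
  type-inconsistent edge). `n_swaps` counts attempted swaps, 10·|E| by
  default, each attempt drawing a class with probability proportional to
  its edge count; attempts that would duplicate an edge are skipped.
  Per-node, per-class in/out-degree conservation is exact and tested over
  100 replicates.
- **Partial networks**: induced subnetworks on kind subsets, keeping
  isolated nodes so candidate sets stay comparable; a subset with fewer
  than two mapped seeds is reported as "not analyzed" rather than scored.

Replicate counts for the nulls default to 20 in the analysis scripts and
acceptance run; the estimator is a mean of AUCs, whose spread at 20
replicates (≈ ±0.01) is far smaller than the effects of interest.

## Functional semantics

Over-representation uses a one-sided hypergeometric test per term after
propagating annotations to ancestors (true-path rule), with significance
at raw p < 0.05 by default; a Benjamini–Hochberg option exists but is off
by default to match the common single-cutoff reporting convention in this
setting. Term–term similarity is the Wang graph-based measure with the
standard decay weights (is_a 0.8, part_of 0.6): each term's S-values are
propagated to its ancestors along the best-decaying path, and two terms
are compared through their shared ancestors. Term sets are combined with
rcmax — the larger of the two directional best-match averages — so equal
sets (and supersets on the saturated side) score exactly 1. Wang/rcmax
needs no information-content corpus, which keeps the stage self-contained;
information-content measures (Resnik, Lin) are out of scope.

Significance of a set-similarity score is an empirical permutation test:
each replicate draws the same number of terms uniformly from the
namespace's annotated terms (never-annotated terms would deflate the null)
and rescores. The p-value is the fraction of null scores *strictly
greater* than the real score; ties do not count against the real score,
so p = 0 is attainable and is reported as such, not smoothed.

## Synthetic study conditions

The generator produces the regime the analysis assumes, at the scale of a
curated regulatory network: 155 TF + 681 miRNA + 1,332 lncRNA nodes and
4,500 edges (≈ 2 edges per node), relation classes filled approximately
uniformly, endpoints drawn with probability ∝ (degree + 1)^γ (γ = 1). At
this scale the degree histogram follows an approximate power law (log–log
OLS slope ≈ −1.6, R² ≈ 0.9) and TFs — members of four of the five relation
classes despite being 7% of nodes — emerge as hubs, matching the empirical
pattern in curated TF/ncRNA networks.

The planted signal is a **degree-corrected planted-partition overlay**:

- A 60-node module (25% TF, 50% miRNA, 25% lncRNA — regulator
  neighborhoods are TF/miRNA-centric, and lncRNA–lncRNA pairs admit no
  relation type) receives an internal-edge quota equal to the boosted
  within-module share `boost·q/(1−q+boost·q)` of all edges, where `q` is
  the within-module edge probability of the un-boosted graph and
  boost = 8 (≈ 79 internal edges at the defaults).
- Internal edges are placed to *cover* the module: each edge targets a
  currently least-covered member, with a compatible relation and a uniform
  module source. The testable assumption behind proximity-based
  prioritization is that true regulators are mutually proximal, so the
  module is built mutually interlinked rather than hub-dominated — a
  degree-biased placement would concentrate the plant on a few module
  hubs and leave the rest unreachable.
- Background proposals touching module nodes are thinned by the
  degree-matching factor `1 − (internal degree per member)/(expected
  background degree)`, so module nodes end with population-typical total
  degree. The planted signal is then purely positional: degree-preserving
  rewiring destroys it, which is exactly what makes the rewired network a
  sound null model. Without this correction the module doubles as a hub
  set and the rewired null inherits most of the signal from degree alone.

Seeds: 40, drawn 90% from the module and 10% from outside it (seed lists
in practice contain regulators the network does not corroborate). The toy
ontology is a rooted is_a DAG (150 terms, depth 5) with one designated
clade; module genes draw their Poisson(3) annotations with weight 20 on
clade terms, planting the enrichment and similarity signal.

Under these defaults the study behaves like its full-scale counterpart:
LOOCV AUC ≈ 0.91–0.94 across generator seeds, random-seed null ≈ 0.50,
rewired-network null ≈ 0.62–0.65, and partial networks recover less than
the integrated one.

**What the generator does not emulate**: database-specific evidence biases,
identifier messiness, correlated false positives, kind-stratified seed
ascertainment, and the extreme hubbiness of real curated networks (where
half the nodes have degree one against ≈ 20% here). Passing the synthetic
suite therefore demonstrates correctness and calibration of the machinery
under the stated statistical regime, not performance on any particular
curated network.

## Edge-table filters

Two filter semantics reflect how curated sources are thresholded:
`support_count > k` (strict; evidence counted in datasets, e.g. "more than
20") and `support_score ≥ s` (inclusive; prediction scores, e.g. "at least
0.95"). Merging is by union (deduplicating source/target/relation triples)
or intersection (evidence must appear in every set). An id appearing with
two different kinds across tables is a validation error listing the
offending ids — silent coercion would corrupt the type system the five
relation classes rely on.

## Known limitations

- Scores of nodes unreachable from the seed set are exactly 0 and tie; on
  sparse directed networks this can be a large group, and their pooled-ROC
  contribution is handled by tie-averaging rather than arbitrary order.
- The power-law fit is an OLS line on the log–log raw frequency histogram
  (zero-frequency degrees excluded). This is a descriptive
  characterization, deliberately simple; it is not a maximum-likelihood
  tail estimate and should not be read as a rigorous test of
  scale-freeness.
- The permutation p-value resolution is 1/n_reps; at 200 replicates a
  reported 0.0 means "below 0.005", not literally zero.
- `read_bundle`/pipeline networks are built from edge tables, so nodes
  with no edges exist only if a labels file supplies them; candidate
  counts can differ accordingly.
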