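# trireg

Network-based prioritization of candidate regulators on a tripartite
transcription-factor / miRNA / lncRNA regulatory network, with random walk
with restart (RWR), leave-one-out cross-validation, randomization null
models, and ontology-based functional validation.

## The problem

Autophagy — and many other cellular programs — is controlled not only by
post-translational machinery but by transcriptional and post-transcriptional
regulators: transcription factors (TFs), miRNAs and lncRNAs. Known
regulators of this kind are scarce, and candidates are expensive to test.
If known regulators sit close together in the regulatory wiring, network
proximity to them is evidence of shared function. `trireg` implements that
inference end to end for directed, typed regulatory networks restricted to
five relation classes:

    TF→miRNA, TF→lncRNA, miRNA→lncRNA, miRNA→TF, lncRNA→TF

which are the experimentally supported regulation layers curated by
resources such as TransmiR, ChIPBase, miRTarBase/miRecords, LncBase and
LncReg/LncRNA2Target. The package is aimed at systems-biology analysts who
have per-relation edge tables and a seed list of known regulators and want
a ranked candidate list with honest validation.

## The method

Let `A` be the binary adjacency of the directed network in a fixed
(lexicographic) node ordering. The transition matrix row-normalizes `A`:

    w(i,j) = A(i,j) / Σ_j A(i,j)   if the row sum is non-zero, else 0

Rows of out-degree-0 ("dangling") nodes are zero, so walk mass can leak;
an optional mode redirects that mass to the restart distribution. With
restart probability `α` (default 0.5) and the uniform seed distribution
`P₀(i) = 1/n` over the `n` seed regulators, the walk iterates

    P_{t+1} = (1 − α) · Wᵀ · P_t + α · P₀

until the L1 difference between successive vectors is below 1e-10. The
stationary vector `P∞` measures proximity to the seed set; non-seed nodes
are ranked by it (ties broken by node id for reproducibility).

Validation: leave-one-out cross-validation (each seed withheld and scored
as a candidate; pooled scores → ROC/AUC), a random-seed null, a
degree-preserving rewired-network null (double-edge swaps within each
relation class), and partial-network comparisons. Functional validation:
hypergeometric term over-representation (true-path annotation propagation)
and rcmax-combined Wang semantic similarity between the term sets enriched
in the top candidates and in the seeds, with an empirical permutation p.

Because the curated networks behind published analyses are not
redistributable here, the package ships a synthetic-data generator that
reproduces the statistical regime such analyses assume: a sparse
(|E| ≈ 2·|V|), lncRNA-heavy, approximately scale-free tripartite network
with a planted, degree-corrected module of mutually proximal regulators,
plus a toy ontology with clade-biased annotations. See
[docs/methods.md](docs/methods.md) for the model and its limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic conditions (2,168 nodes — 155 TF, 681 miRNA, 1,332 lncRNA —
4,500 edges, a planted 60-node module, 40 seeds of which 90% lie in the
module):

```sh
python analysis/01_simulate_data.py        # writes results/bundle/
python analysis/02_network_topology.py
python analysis/03_rank_candidates.py
python analysis/04_cross_validation.py
python analysis/05_functional_similarity.py
```

Output of the topology step:

```
19.7% of nodes have degree one
degree: y = 719.7 * x^-1.61 (R^2 = 0.893)
in_degree: y = 656.5 * x^-1.79 (R^2 = 0.917)
out_degree: y = 685.7 * x^-1.81 (R^2 = 0.909)
```

so the generated network is approximately scale-free, and TFs act as hubs
(median in/out-degree 7/8 versus 1/0 for lncRNAs). Ranking and validation:

```
propagation converged in 25 iterations (residual 7.50e-11); sum(P_inf) = 0.7897
top-100 composition: {'TF': 45, 'lncRNA': 39, 'miRNA': 16}
20 of the top 100 candidates lie in the planted module

LOOCV AUC on the full network: 0.915 (median held-out rank 49 of 2129)
  partial network lncRNA+miRNA: AUC 0.530 (31 mapped seeds)
  partial network TF+miRNA: AUC 0.803 (32 mapped seeds)
  partial network TF+lncRNA: AUC 0.670 (17 mapped seeds)
random-seed null mean AUC: 0.478 (20 replicates)
rewired-network null mean AUC: 0.636 (20 replicates)
real seeds beat the rewired null by 0.279 AUC
```

The held-out known regulators are recovered far better than chance
(AUC 0.915), the signal disappears when seeds are randomized (0.478) and
is largely destroyed by degree-preserving rewiring (0.636), and the
partial networks recover less than the integrated one — the qualitative
behavior expected when known regulators form a mutually proximal module.
Of the 24 module members not used as seeds, 20 appear in the top 100.
The functional stage finds 10 ontology terms enriched in the top-100
candidates whose rcmax similarity to the seed-enriched terms is 1.000 with
permutation p = 0.0 (200 random term sets).

The same machinery is exposed as a CLI (`trireg synth|rwr|evaluate|semsim|run`)
for use on real edge tables; `trireg run --config config.json` executes the
full pipeline from one validated JSON config.

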