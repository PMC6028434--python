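# Methods

This note records the models, estimators, numerical choices and known
limitations behind `hiccnet`, in the order the pipeline runs them.

## Control centrality

**Definition.** For a simple directed network, attach one input to node
*i*; C_c(i) is the generic dimension of the controllable subspace of the
structured system ẋ = Ax + e_i·u — equivalently the maximum number of
edges over stem-cycle disjoint subgraphs (one directed path from the
input plus vertex-disjoint cycles) inside the set reachable from *i*,
counting the input edge. C_c ∈ [1, N]; duplicate edges are collapsed
because the generic-rank theory assumes simple structure.

**Algorithm.** Generic rank is evaluated as the rank of the Krylov
sequence b, Ab, A²b, … with edge weights drawn uniformly from
GF(p), p = 2³¹ − 1, using incremental Gaussian elimination in exact
field arithmetic. Two facts keep this cheap and exact: the computation
restricts to the reachable set of *i* (unreached states contribute no
rank), and iteration stops the first time a Krylov vector reduces to
zero against the running basis (the Krylov space is then A-invariant),
so the cost is about C_c(i) sparse matrix–vector products plus a rank-
sized elimination. A random evaluation under-estimates the generic rank
only on the zero set of a fixed minor polynomial; by Schwartz–Zippel the
per-trial failure probability is at most ≈ N²/(2p), and the default of
3 independent weight draws (maximum taken) drives it below 10⁻⁶ for the
network sizes used here. Int64 overflow in A·v mod p is avoided by
splitting A into high/low 16-bit parts.

**Oracles.** Two independent routes guard the implementation: (1) a
deliberately naive full controllability matrix [b, Ab, …, A^{N−1}b] on
the whole node set, row-reduced over GF(p); (2) exact stem-cycle
enumeration for small graphs — bitmask dynamic programs over all simple
paths from *i* and over disjoint-cycle covers of each subset of the
reachable set (cycles grouped by their minimum member; g(S) = best cover
of subset S via g(S∖c) recursions). The acceptance suite holds all three
routes to 100% agreement on 200 random digraphs (n ≤ 12, edge
probability 0.2–0.5, every node).

## GRN inference

**Feature selection** is the three-step union: top 2000 genes by
variance, GWAS genes present on the array, then differential-expression-
ranked genes filling to 2500 total. DE ranking uses a moderated t with
empirical-Bayes variance shrinkage (pooled prior variance = mean gene-
wise pooled variance, prior df = 4, p from t with d0 + d df). Only the
ranking feeds the pipeline, so any monotone-in-evidence statistic
serves; the shrinkage protects genes measured with few samples from
variance noise. Eligibility requires nominal p < 0.05 in at least one of
the two contrasts (case/control; HbA1c dichotomized at 6%), ranked by
the average absolute statistic. All ties break by gene id.

**Mutual information** uses equal-frequency discretization into 3
categories (rank-based, so tied values share a bin and a constant vector
is a single category) and the plug-in estimate in nats. **MRMR** picks,
per target, the candidate maximizing MI with the target, then repeatedly
the candidate maximizing MI(candidate, target) − mean MI(candidate,
chosen), up to 3 parents. Selection stops early if the best adjusted
score falls below the estimator's first-order bias (bins−1)²/(2n) — a
candidate carrying less information than estimation bias is not a
parent. When a prior network is supplied the candidate pool is its
source genes (regulators), else all selected genes.

**Causality score.** The v-structure score for edge parent→target with
co-parent q is the induced-dependence contrast

  d = r(parent, q | target)² − r(parent, q)²,

the squared partial correlation given the target minus the squared
marginal correlation, averaged over co-parents and clipped to [−1, 1].
Conditioning on a common effect (collider) *induces* dependence between
otherwise independent causes (d > 0, evidence for parent→target);
conditioning on a mediator *removes* dependence (d < 0); co-parent-free
edges score 0. Differences below τ = 2/n are soft-thresholded to exactly
zero: under independence both squared correlations are ~χ²₁/n, so the
null difference has sd ≈ √2·(1+√2)/n-ish ≈ 2/n at the 2-sd level, and
thresholded null edges then fail the strict >0 retention rule. We chose
this Gaussian form over a discretized conditional-MI contrast after
measuring both on simulated colliders/chains/nulls: on SEM-like data the
partial-correlation form has ≥97% collider power at n = 60 with < 1%
null positives, whereas the 3-bin CMI version cannot reach 90% power at
any threshold that also controls nulls (its conditional estimate is
computed on thirds of the data and carries three times the bias and
variance).

**Prior combination.** combined = 0.75·causality + 0.25·prior-indicator;
edges with combined > 0 are retained. A prior-only edge scores 0.25 and
survives unless the data actively contradict it (causality ≤ −1/3); a
data-only edge needs positive collider evidence. The inferred GRN is
therefore prior-dominated with a sparse layer of data-oriented edges —
deliberately conservative, since false long-range edges are what corrupt
downstream control-centrality contrasts.

## Pathway statistics

HiCc: per pathway with ≥ 5 network genes, one-sided (greater)
Mann–Whitney U of member C_c values against all other network genes,
flagged at p < 0.05; pathways whose names match a configurable cancer
keyword list (cancer, carcinoma, leukemia, melanoma, glioma) are
excluded, mirroring the known literature bias toward cancer pathway
annotation. Enrichment of a pathway in a disease gene set is a one-sided
Fisher exact test on the 2×2 overlap table over the network-gene
universe; the HiCc vs non-HiCc enrichment-fraction contrast is a
two-tailed Fisher exact test. Construction-time GWAS genes are removed
from the disease set before enrichment to avoid circularity. The
published contrast tables (24/66 vs 26/120 → p = 0.038; 48/66 vs
59/120 → p = 0.0020) reproduce to the printed precision.

**Randomized ensembles.** Degree-preserving randomization performs
attempted directed double-edge swaps (default 10 per edge), rejecting
self-loops and multi-edges; in/out degrees are preserved exactly and the
swap chain is seeded. (The primitive is hand-rolled rather than taken
from networkx so that the swap sequence is stable across library
versions; degree preservation is asserted property-style in the tests.)
One caveat found during validation and worth stating: for the layered
synthetic networks generated here, stub-rematching *creates* cycles and
long mixed chains, so the randomized ensemble's mean C_c typically
*exceeds* the hierarchy's. The per-randomization rank-sum comparison
(`cc_vs_random_ensemble`) reliably detects the distributional
difference, but its direction is a property of the wiring being
randomized, not a universal; the cohort-scale network on which the
original direction was reported is not reproducible here.

## cis-eQTL

Pairs are SNPs within 250 kb (inclusive) of the gene body on the same
chromosome. Per pair, OLS expression ~ intercept + dosage + age + sex
via QR-based Frisch–Waugh partialling; the reported statistic is the
dosage-coefficient t (df = n − 4) with two-sided p. Monomorphic SNPs are
skipped. FDR is Benjamini–Hochberg across all tested pairs jointly
(threshold 1% by default, the Matrix-eQTL-style convention; a per-gene
alternative was considered and rejected because the pipeline's
downstream consumer — the Steiner stage — operates on the pooled pair
list). Permutation p-values permute the covariate-residualized
expression (preserving the genotype–covariate structure), re-project,
and recompute t; with the default legacy floor the value is
#exceedances/n_perm floored at 1/n_perm (1.00e-4 at 10k permutations),
and an add-one convention (1+k)/(n_perm+1) is available by flag. A
minimal VCF GT→dosage reader is provided for convenience. The generic
two-group Mann–Whitney utility uses exact enumeration when the smaller
sample has ≤ 8 untied values, else the tie-corrected normal
approximation.

## Steiner connection

Klein–Ravi greedy for node-weighted Steiner trees: maintain a forest of
terminal trees; repeatedly pick the node v (and node-cost shortest paths
from v to ≥ 2 trees) minimizing (cost of v + path costs) / trees merged;
merge until one tree, then reduce to a spanning tree and prune degree-1
non-terminals. Node costs default to 1 (no weighting scheme is imposed
on the interaction network; edge confidence scores are ignored by the
node-weighted objective). Ties break lexicographically by node id, so
runs are deterministic. Terminals missing from the network are dropped
with a warning; terminals spanning several components yield a forest
flagged partial. The guarantee is cost ≤ 2·ln(#terminals)·optimum,
verified against exhaustive subset search on 20 instances (n ≤ 15, 4
terminals).

## Synthetic data generator

The generator emulates the study design end to end so every stage has a
planted-truth recovery test.

- **Network**: n_genes (default 300) split into n_layers (default 5)
  equal layers; each non-bottom gene sends Poisson(2) edges to the next
  layer, every downstream gene receives ≥ 1 parent, and a
  cycle_fraction (default 0.1) of extra back-edges creates feedback.
  Layer-1 genes are the controller ground truth.
- **Expression**: linear-Gaussian SEM x = (I − Wᵀ)⁻¹ε with edge weight
  0.8 and noise sd 1 (weights rescaled if the spectral radius reaches
  1). Chosen over nonlinear kinetics because the covariance is closed
  form — corr(parent, child) = 0.8/√1.64 for an isolated edge, asserted
  in tests — while still giving MRMR a nontrivial redundancy structure.
- **Cohort**: 60 samples by default, ~15% disease (emulating a 9-vs-54
  case/control imbalance) shifting the deepest layer by the disease
  effect; HbA1c tracks disease status with noise; age and sex random.
- **Pathways**: one CONTROLLER set (15 controller genes), 20 random
  decoy sets, one cancer-named decoy to exercise the exclusion filter.
- **Prior**: a random half of the true edges (an incomplete but
  correctly oriented interaction database).
- **Kinase/signaling extensions**: predominantly downward (layer-
  respecting) random edges plus a few external substrate nodes —
  downstream signaling events, not uniform noise, since uniform random
  long-range edges destroy the very hierarchy the extensions are meant
  to enrich.
- **Genotypes**: genes on synthetic coordinates (1 Mb spacing, 10 kb
  bodies), dosages Binomial(2, MAF ∈ [0.1, 0.5]), 10 planted cis SNPs
  (β = 1) preferentially on controller-pathway genes so the eQTL stage
  has signal, remaining SNPs near random genes or in gene deserts.

What passing tests show — and what they do not: the generator is linear,
Gaussian, free of linkage disequilibrium, batch effects, array
saturation and mapping error, and its pathways are disjoint random sets
rather than overlapping curated ones. Recovery results here demonstrate
the pipeline's statistical machinery is correct and calibrated under the
model it assumes, not that the biological conclusions of any particular
cohort transfer.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline fans a single
global seed out to stages by CRC32 of the stage name, so adding a stage
never shifts earlier streams, and reruns are byte-identical. The
validation studies use 200 random digraphs for oracle agreement, 50
replicates for controller recovery, 20 for MRMR recovery (300 targets),
2000 null pairs and 100 power replicates for the eQTL suite, and 20
exhaustively solvable Steiner instances — sizes chosen so the whole
suite re-runs in minutes on one CPU while keeping every rate estimate's
binomial error well inside the asserted margins.

## Known limitations

- The stem-cycle brute force is exponential and guarded at 18 reachable
  nodes; it is an oracle, not a production path.
- The causality score assumes roughly monotone dependencies; strongly
  nonlinear regulation would favor the (weaker) discretized-MI variant.
- cc_vs_random_ensemble's direction caveat above.
- The Klein–Ravi implementation recomputes tree-to-node distances each
  merge round (fine for hundreds of terminals, not for tens of
  thousands).
- No LD, imputation, trans-eQTL or conditional eQTL analyses; the eQTL
  model is single-SNP OLS with two covariates.
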