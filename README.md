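# hiccnet

Control-centrality analysis of tissue-specific gene-regulatory networks.

Complex-disease genes rarely act alone: they perturb regulatory programs
whose influence propagates *down* a hierarchy of transcription factors,
kinases and their targets. `hiccnet` asks which pathways sit high in that
hierarchy. It builds an extended gene-regulatory network (EGRN) from
expression data plus prior interactions, scores every gene's **control
centrality** — how much of the network a single gene could steer — flags
**HiCc** (high-control-centrality) pathways, tests their disease-gene
enrichment, maps cis-eQTLs of HiCc pathway genes, and connects the eQTL
genes into one functional module with a node-weighted Steiner tree. It is
aimed at systems-biology researchers who have (or can simulate) an
expression cohort with genotypes and want pathway-level control analysis
with every statistical step testable against planted ground truth.

## The central quantity

For a directed network with adjacency structure *A*, attach a single
time-varying input *u(t)* to gene *i* (input matrix *b = e_i*). The
control centrality of *i* is the generic dimension of the controllable
subspace of ẋ = *Ax* + *bu*,

&nbsp;&nbsp;&nbsp;&nbsp;C_c(i) = generic-rank [b, Ab, A²b, …, A^{N−1}b],
&nbsp;&nbsp;&nbsp;&nbsp;c_c(i) = C_c(i)/N ∈ (0, 1],

an integer between 1 and N. Combinatorially (Hosoe's theorem) C_c(i) is
the largest edge count over *stem-cycle disjoint subgraphs*: one directed
path (stem) starting at the input plus vertex-disjoint cycles, all inside
the set reachable from *i*. `hiccnet` computes the rank exactly over the
prime field GF(2³¹−1) with random edge weights (Schwartz–Zippel), and
ships two independent oracles — a full-matrix finite-field rank and an
exhaustive stem-cycle enumeration — that the test suite holds to 100%
agreement on hundreds of random digraphs.

A pathway is **HiCc** when the C_c values of its member genes are
stochastically greater than those of all other network genes (one-sided
Mann–Whitney U, p < 0.05, pathways with < 5 network genes untested,
cancer-named pathways excluded).

Around that core the pipeline provides: MRMR + v-structure GRN inference
with a weighted prior (weight 0.75), moderated-t differential-expression
ranking, degree-preserving network randomization with topology z-scores,
one-sided Fisher enrichment and two-tailed enrichment-fraction contrasts,
OLS cis-eQTL models (expression ~ dosage + age + sex, 250 kb window,
joint BH-FDR, permutation p-values), and the Klein–Ravi greedy
approximation for node-weighted Steiner trees.

## Worked example

Everything runs from synthetic data with known ground truth — no
downloads. Simulate a study (300 genes in a 5-layer hierarchy, 60
samples, a planted controller pathway among 20 decoys, genotypes with
planted cis effects), then run all stages:

```bash
hiccnet simulate --outdir bundle --seed 0
# simulate: wrote bundle to bundle (N=300, M=613, samples=60)

cat > run.cfg <<EOF
expression = bundle/expression.tsv
covariates = bundle/covariates.tsv
prior = bundle/prior.tsv
kinase = bundle/kinase.tsv
signaling = bundle/signaling.tsv
pathways_gmt = bundle/pathways.gmt
disease_genes = bundle/disease_genes.txt
genotypes = bundle/genotypes.tsv
annotation = bundle/annotation.tsv
outdir = run
n_perm = 1000
seed = 0
EOF

hiccnet run-all --config run.cfg
# run-all: 9/9 stages completed -> run/manifest.json
```

The manifest records per-stage status and counts:

```
features               completed  rows=300
grn                    completed  rows=293  N=255
egrn_lcc               completed  rows=370  N=270 (pre-LCC N=275, M=373)
topology               completed  rows=1    aspl=5.928 C=0.0087
control_centrality     completed  rows=270  mean_cc=5.06
hicc_pathways          completed  rows=21   hicc=2
enrichment_contrast    completed  rows=22   contrast_p=1
eqtl                   completed  rows=21   fdr_pass=7 genes
steiner                completed  rows=18   linkers=13
```

Reading the numbers: the inferred GRN (255 genes, 293 edges) is extended
with kinase/signaling edges and reduced to its largest connected
component (270 genes, 370 edges). Among 21 tested pathways the planted
CONTROLLER pathway is flagged HiCc (`run/hicc_pathways.tsv`: p = 0.0079,
mean C_c 7.9 vs network mean 5.1) along with one decoy — the nominal
false-positive rate at p < 0.05. Seven planted eQTL genes pass FDR < 1%
(e.g. `rs00005_planted → G0004`, t = 3.3, q = 0.0063, permutation
p = 0.005), and the Steiner stage connects them through 13 linker genes
into a single module.

Each stage is also a subcommand (`build-grn`, `cc`, `hicc`, `enrich`,
`eqtl`, `steiner`) over the same TSV/GMT formats, and the whole pipeline
is importable (`hiccnet.run_pipeline`, `hiccnet.control_centrality_all`,
…).

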