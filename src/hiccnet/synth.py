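"""Synthetic ground-truth inputs for every pipeline stage.

The generator emulates the structure the HiCc hypothesis assumes: a layered
(hierarchical) directed regulatory network whose top layer regulates
everything downstream, expression produced by a linear-Gaussian structural
equation model over that network, a case/control cohort with HbA1c, age and
sex covariates, pathway collections with one planted controller pathway,
partially overlapping disease gene sets, and genotypes with planted cis
effects.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eqtl import GeneAnnotation, GenotypeMatrix
from .graph_core import DirectedNetwork
from .grn import ExpressionMatrix
from .pathways import GeneSetCollection

GENE_SPAN = 10_000          # synthetic gene length (bp)
GENE_SPACING = 1_000_000    # distance between consecutive gene starts (bp)


@dataclass
class SyntheticTruth:
    """Planted structure for recovery tests."""

    true_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    controller_genes: set[str] = field(default_factory=set)
    planted_eqtl: list[tuple[str, str, float]] = field(default_factory=list)
    disease_genes: set[str] = field(default_factory=set)
    params: dict = field(default_factory=dict)
    layers: dict[str, int] = field(default_factory=dict)


def generate_regulatory_network(n_genes: int = 300, n_layers: int = 5,
                                out_degree_mean: float = 2.0,
                                cycle_fraction: float = 0.1,
                                seed: int = 0,
                                ) -> tuple[DirectedNetwork, SyntheticTruth]:
    """Layered digraph: edges predominantly layer k → k+1, plus a fraction
    of back-edges creating feedback cycles.  Layer-1 nodes are the planted
    controller genes."""
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    per_layer = n_genes // n_layers
    if out_degree_mean >= per_layer:
        raise ValueError("out_degree_mean must be < genes per layer")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    layer_of: dict[str, int] = {}
    layers: list[list[str]] = []
    start = 0
    for k in range(n_layers):
        size = per_layer + (1 if k < n_genes % n_layers else 0)
        layers.append(genes[start:start + size])
        for g in layers[-1]:
            layer_of[g] = k + 1
        start += size

    net = DirectedNetwork(nodes=genes)
    truth = SyntheticTruth(layers=layer_of)
    for k in range(n_layers - 1):
        nxt = layers[k + 1]
        for g in layers[k]:
            n_out = max(1, rng.poisson(out_degree_mean))
            n_out = min(n_out, len(nxt))
            targets = rng.choice(nxt, size=n_out, replace=False)
            for t in targets:
                net.add_edge(g, t)
                truth.true_edges[(g, t)] = 1.0
    # every non-top node gets at least one parent so the hierarchy is wired
    for k in range(1, n_layers):
        prev = layers[k - 1]
        for g in layers[k]:
            if net.in_degree(g) == 0:
                p = str(rng.choice(prev))
                net.add_edge(p, g)
                truth.true_edges[(p, g)] = 1.0
    # feedback: back-edges from deeper layers to shallower ones
    n_back = int(round(cycle_fraction * len(truth.true_edges)))
    for _ in range(n_back):
        k_src = int(rng.integers(1, n_layers))       # layers 2..n (0-based 1..)
        k_dst = int(rng.integers(0, k_src))
        u = str(rng.choice(layers[k_src]))
        v = str(rng.choice(layers[k_dst]))
        if u != v and not net.has_edge(u, v):
            net.add_edge(u, v)
            truth.true_edges[(u, v)] = 1.0
    truth.controller_genes = set(layers[0])
    truth.params = dict(n_genes=n_genes, n_layers=n_layers,
                        out_degree_mean=out_degree_mean,
                        cycle_fraction=cycle_fraction, seed=seed)
    return net, truth


def simulate_expression(net: DirectedNetwork, truth: SyntheticTruth,
                        n_samples: int = 60, edge_weight: float = 0.8,
                        noise_sd: float = 1.0, disease_effect: float = 1.0,
                        disease_fraction: float = 0.15,
                        seed: int = 0) -> ExpressionMatrix:
    """Linear-Gaussian SEM expression: x = (I − Wᵀ)⁻¹ ε per sample.

    A disease indicator (default ~15% of samples, emulating a 9/63
    case/control imbalance) shifts the deepest-layer genes by
    ``disease_effect``; HbA1c tracks disease status with noise; age and sex
    are randomized.  For cyclic networks the weight matrix is rescaled so
    its spectral radius stays below 1 (equilibrium solution exists).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    w = np.zeros((n, n))
    for (u, v), rel in truth.true_edges.items():
        w[idx[u], idx[v]] = edge_weight * rel
    radius = np.max(np.abs(np.linalg.eigvals(w)))
    if radius >= 1.0:
        w *= 0.95 / radius
        if np.max(np.abs(np.linalg.eigvals(w))) >= 1.0:  # pragma: no cover
            raise ValueError("weight matrix could not be stabilized")

    eps = rng.normal(0.0, noise_sd, size=(n, n_samples))
    x = np.linalg.solve(np.eye(n) - w.T, eps)

    n_cases = max(1, int(round(disease_fraction * n_samples)))
    disease = np.zeros(n_samples, dtype=int)
    case_idx = rng.choice(n_samples, size=n_cases, replace=False)
    disease[case_idx] = 1
    max_layer = max(truth.layers.values()) if truth.layers else 1
    affected = sorted(g for g in genes
                      if truth.layers.get(g, max_layer) == max_layer)
    truth.disease_genes = set(affected)
    if disease_effect != 0.0:
        rows = [idx[g] for g in affected]
        x[np.ix_(rows, case_idx)] += disease_effect

    samples = [f"S{j:03d}" for j in range(n_samples)]
    hba1c = 5.5 + 1.5 * disease + rng.normal(0.0, 0.4, n_samples)
    covariates = pd.DataFrame({
        "disease": disease,
        "hba1c": hba1c,
        "age": rng.normal(58.0, 9.0, n_samples).round(1),
        "sex": rng.integers(0, 2, n_samples),
    }, index=samples)
    values = pd.DataFrame(x, index=genes, columns=samples)
    return ExpressionMatrix(values=values, covariates=covariates)


def generate_pathways(truth: SyntheticTruth, n_decoys: int = 20,
                      set_size: int = 15, seed: int = 0,
                      include_cancer_decoy: bool = True,
                      ) -> GeneSetCollection:
    """One planted ``CONTROLLER`` pathway sampled from the controller genes
    plus random decoy pathways (and optionally a cancer-named decoy for the
    exclusion filter)."""
    rng = np.random.default_rng(seed)
    all_genes = sorted({g for e in truth.true_edges for g in e}
                      | truth.controller_genes)
    controllers = sorted(truth.controller_genes)
    k = min(set_size, len(controllers))
    sets = {"CONTROLLER": sorted(rng.choice(controllers, k, replace=False))}
    for j in range(n_decoys):
        sets[f"DECOY_{j:02d}"] = sorted(
            rng.choice(all_genes, min(set_size, len(all_genes)),
                       replace=False))
    if include_cancer_decoy:
        sets["PANCREATIC_CANCER_DECOY"] = sorted(
            rng.choice(all_genes, min(set_size, len(all_genes)),
                       replace=False))
    return GeneSetCollection(sets=sets, origin="pathways")


def generate_disease_genes(truth: SyntheticTruth, n_genes: int = 30,
                           overlap_fraction: float = 0.5, seed: int = 0,
                           ) -> list[str]:
    """Disease gene set partially overlapping the planted disease-affected
    genes; the remainder drawn from the rest of the network."""
    rng = np.random.default_rng(seed)
    affected = sorted(truth.disease_genes)
    all_genes = sorted({g for e in truth.true_edges for g in e}
                      | truth.controller_genes)
    others = sorted(set(all_genes) - set(affected))
    n_hit = min(int(round(overlap_fraction * n_genes)), len(affected))
    chosen = list(rng.choice(affected, n_hit, replace=False))
    chosen += list(rng.choice(others, min(n_genes - n_hit, len(others)),
                              replace=False))
    return sorted(chosen)


def gene_annotation_for(genes: list[str], chrom: str = "1") -> GeneAnnotation:
    """Deterministic synthetic coordinates: gene *g* (by sorted index)
    starts at ``GENE_SPACING·(g+1)`` and spans ``GENE_SPAN`` bp."""
    genes = sorted(genes)
    table = pd.DataFrame({
        "chrom": chrom,
        "start": [GENE_SPACING * (i + 1) for i in range(len(genes))],
        "end": [GENE_SPACING * (i + 1) + GENE_SPAN for i in range(len(genes))],
    }, index=genes)
    return GeneAnnotation(table=table)


def generate_genotypes(truth: SyntheticTruth, expr: ExpressionMatrix,
                       n_snps: int = 200,
                       maf_range: tuple[float, float] = (0.1, 0.5),
                       beta: float = 1.0, n_planted: int = 10,
                       cis_window: int = 250_000, seed: int = 0,
                       planted_pool: list[str] | None = None,
                       ) -> tuple[GenotypeMatrix, GeneAnnotation,
                                  ExpressionMatrix]:
    """Genotypes with planted cis effects.

    Genes sit on synthetic coordinates (1 Mb apart, 10 kb long).  A set of
    planted SNPs lands inside the cis window of chosen genes and shifts
    that gene's expression by ``beta × dosage``; the remaining SNPs scatter
    near random genes and in gene deserts.  Dosages are Binomial(2, MAF).
    Returns the genotypes, the annotation, and the expression matrix with
    the planted effects added (the input is not modified).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(expr.genes)
    annot = gene_annotation_for(genes)
    samples = expr.samples
    n_samples = len(samples)

    # plant preferentially on controller genes (or a caller-supplied pool,
    # e.g. the planted controller pathway) so the downstream HiCc-pathway
    # eQTL stage has signal to find, as in the study design
    if planted_pool is not None:
        pool = sorted(set(planted_pool) & set(genes)) or genes
    else:
        pool = sorted(truth.controller_genes & set(genes)) or genes
    planted_genes = list(rng.choice(pool, min(n_planted, len(pool)),
                                    replace=False))
    snp_rows, chroms, poss, snp_ids = [], [], [], []
    values = expr.values.copy()

    def _new_snp(pos: int, dosage: np.ndarray, tag: str) -> str:
        sid = f"rs{len(snp_ids):05d}_{tag}"
        snp_ids.append(sid)
        chroms.append("1")
        poss.append(int(pos))
        snp_rows.append(dosage)
        return sid

    for g in planted_genes:
        row = annot.table.loc[g]
        pos = int(rng.integers(max(1, row["start"] - cis_window),
                               row["end"] + cis_window + 1))
        maf = rng.uniform(*maf_range)
        dosage = rng.binomial(2, maf, size=n_samples).astype(float)
        sid = _new_snp(pos, dosage, "planted")
        values.loc[g] = values.loc[g].to_numpy() + beta * dosage
        truth.planted_eqtl.append((sid, g, beta))

    n_rest = max(0, n_snps - len(planted_genes))
    desert_start = GENE_SPACING * (len(genes) + 5)
    for j in range(n_rest):
        maf = rng.uniform(*maf_range)
        dosage = rng.binomial(2, maf, size=n_samples).astype(float)
        if rng.random() < 0.7:
            g = str(rng.choice(genes))
            row = annot.table.loc[g]
            pos = int(rng.integers(max(1, row["start"] - cis_window),
                                   row["end"] + cis_window + 1))
        else:  # gene desert, beyond every cis window
            pos = desert_start + int(rng.integers(0, 10 * GENE_SPACING))
        _new_snp(pos, dosage, "null")

    geno = GenotypeMatrix(
        dosages=pd.DataFrame(snp_rows, index=snp_ids, columns=samples),
        chrom=pd.Series(chroms, index=snp_ids),
        pos=pd.Series(poss, index=snp_ids))
    out_expr = ExpressionMatrix(values=values,
                                covariates=expr.covariates.copy())
    return geno, annot, out_expr


def default_instance(seed: int = 0, n_genes: int = 300, n_layers: int = 5,
                     n_samples: int = 60, n_decoys: int = 20,
                     ) -> dict:
    """The default synthetic study: network + truth + expression +
    pathways, as one bundle."""
    net, truth = generate_regulatory_network(n_genes=n_genes,
                                             n_layers=n_layers, seed=seed)
    expr = simulate_expression(net, truth, n_samples=n_samples,
                               seed=seed + 1)
    pathways = generate_pathways(truth, n_decoys=n_decoys, seed=seed + 2)
    return {"net": net, "truth": truth, "expr": expr, "pathways": pathways}


def generate_prior(truth: SyntheticTruth, fraction: float = 0.5,
                   n_false: int = 0, seed: int = 0) -> DirectedNetwork:
    """Prior regulatory network: a random subset of the true edges
    (emulating an incomplete interaction database), optionally with a few
    false-positive edges."""
    rng = np.random.default_rng(seed)
    edges = sorted(truth.true_edges)
    keep_idx = rng.choice(len(edges), int(round(fraction * len(edges))),
                          replace=False)
    prior = DirectedNetwork((edges[i] for i in sorted(keep_idx)),
                            provenance="prior")
    genes = sorted({g for e in edges for g in e})
    added = 0
    while added < n_false:
        u, v = rng.choice(genes, 2, replace=False)
        if (u, v) not in truth.true_edges and not prior.has_edge(u, v):
            prior.add_edge(u, v, "prior")
            added += 1
    return prior


def generate_extension_edges(truth: SyntheticTruth, n_edges: int = 50,
                             provenance: str = "kinase",
                             seed: int = 0, p_downward: float = 0.9,
                             ) -> DirectedNetwork:
    """Kinase-substrate or signaling interactions to extend the GRN with.

    Real kinase and signaling catalogues add *downstream* events to a
    regulatory network, so the generated edges predominantly point from
    shallower to deeper layers of the planted hierarchy (a small fraction
    is lateral/upward noise).  A few extra substrate nodes outside the
    expression panel are appended as a deepest tier.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth.layers) or sorted(
        {g for e in truth.true_edges for g in e})
    max_layer = max(truth.layers.values()) if truth.layers else 1
    extra = [f"X{provenance[:3].upper()}{j:03d}"
             for j in range(max(2, n_edges // 10))]
    layer_of = dict(truth.layers)
    for x in extra:
        layer_of[x] = max_layer + 1
    pool = genes + extra
    net = DirectedNetwork()
    made = 0
    while made < n_edges:
        u, v = (str(a) for a in rng.choice(pool, 2, replace=False))
        downward = layer_of.get(u, 1) < layer_of.get(v, 1)
        if rng.random() < p_downward and not downward:
            continue
        if not net.has_edge(u, v):
            net.add_edge(u, v, provenance)
            made += 1
    return net
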