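"""Synthetic validation studies for the pipeline's core claims.

Each function runs one self-contained experiment — enrichment contrasts on
the published contingency tables, cross-validation of the three control-
centrality routes, planted-controller pathway recovery, MRMR parent
recovery, cis-eQTL calibration and power, and Steiner-tree quality — and
returns a dict of measured quantities.  The test suite asserts on these
numbers and the reproduction script reports them.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import synth
from .control import (control_centrality, control_centrality_all,
                      krylov_rank_oracle, stem_cycle_cc)
from .eqtl import GenotypeMatrix, fit_eqtl, permutation_p
from .graph_core import DirectedNetwork
from .grn import ExpressionMatrix, mrmr_parents
from .pathways import contrast_from_counts, hicc_pathways
from .steiner import brute_force_steiner, klein_ravi_steiner

# Published 2x2 contingency tables: enriched/not-enriched pathway counts
# for the HiCc (top row) and non-HiCc (bottom row) groups, against the
# curated disease-gene database (GOLD) and the GWAS meta-analysis gene set.
GOLD_TABLE = ((24, 42), (26, 94))
GWAS_TABLE = ((48, 18), (59, 61))


def enrichment_contrasts(seed: int = 0) -> dict:
    """Two-tailed Fisher exact p-values of the published contrast tables."""
    gold = contrast_from_counts(*GOLD_TABLE[0], *GOLD_TABLE[1])
    gwas = contrast_from_counts(*GWAS_TABLE[0], *GWAS_TABLE[1])
    return {
        "gold_fisher_p": gold.fisher_p_two_tailed,
        "gold_odds_ratio": gold.odds_ratio,
        "gwas_fisher_p": gwas.fisher_p_two_tailed,
        "gwas_odds_ratio": gwas.odds_ratio,
    }


def _random_digraph(rng: np.random.Generator, n: int,
                    p: float) -> DirectedNetwork:
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(n)
             if i != j and rng.random() < p]
    return DirectedNetwork(edges, nodes=nodes)


def cc_oracle_agreement(seed: int = 0, n_graphs: int = 200) -> dict:
    """Exhaustive three-way agreement of the production algorithm, the
    full-matrix finite-field oracle and the stem-cycle brute force on
    random digraphs (n <= 12, edge probability 0.2-0.5)."""
    rng = np.random.default_rng(seed)
    n_nodes = 0
    n_agree = 0
    for k in range(n_graphs):
        n = int(rng.integers(2, 13))
        net = _random_digraph(rng, n, float(rng.uniform(0.2, 0.5)))
        for node in sorted(net.nodes):
            main = control_centrality(net, node, seed=seed + k)
            kry = krylov_rank_oracle(net, node, seed=seed + 7919 + k)
            brute = stem_cycle_cc(net, node)
            n_nodes += 1
            n_agree += (main == kry == brute)
    return {
        "n_graphs": n_graphs,
        "n_nodes_tested": n_nodes,
        "agreement_rate": n_agree / n_nodes,
    }


def cc_closed_forms(seed: int = 0, n_monotonicity_pairs: int = 50) -> dict:
    """Closed-form values (chain, cycle, out-star) plus edge-addition
    monotonicity checks on random graph/edge pairs."""
    checks = 0
    passed = 0

    chain = DirectedNetwork([(f"x{i}", f"x{i+1}") for i in range(1, 7)])
    for node, expect in (("x1", 7), ("x7", 1)):
        checks += 1
        passed += control_centrality(chain, node) == expect
    cycle = DirectedNetwork([("a", "b"), ("b", "c"), ("c", "a")])
    for node in ("a", "b", "c"):
        checks += 1
        passed += control_centrality(cycle, node) == 3
    star = DirectedNetwork([("hub", f"l{k}") for k in range(1, 4)])
    checks += 1
    passed += control_centrality(star, "hub") == 2

    rng = np.random.default_rng(seed)
    mono_ok = 0
    done = 0
    while done < n_monotonicity_pairs:
        net = _random_digraph(rng, int(rng.integers(4, 10)),
                              float(rng.uniform(0.15, 0.4)))
        nodes = sorted(net.nodes)
        u, v = (str(x) for x in rng.choice(nodes, 2, replace=False))
        if net.has_edge(u, v):
            continue
        before = control_centrality_all(net, n_trials=2, seed=done)
        bigger = net.copy()
        bigger.add_edge(u, v)
        after = control_centrality_all(bigger, n_trials=2, seed=done + 101)
        mono_ok += all(after.cc[x] >= before.cc[x] for x in nodes)
        done += 1
    return {
        "closed_form_pass_rate": passed / checks,
        "monotonicity_pass_rate": mono_ok / n_monotonicity_pairs,
    }


def controller_recovery(seed: int = 0, n_replicates: int = 50,
                        n_genes: int = 300, n_layers: int = 5,
                        n_decoys: int = 20) -> dict:
    """Planted-controller HiCc recovery across synthetic replicates:
    the controller pathway must be flagged (one-sided rank-sum p < 0.05)
    and decoy pathways only at the nominal false-positive rate."""
    rng = np.random.default_rng(seed)
    n_flagged = 0
    decoy_flags = 0
    decoy_tests = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2**31))
        net, truth = synth.generate_regulatory_network(
            n_genes=n_genes, n_layers=n_layers, seed=s)
        pathways = synth.generate_pathways(truth, n_decoys=n_decoys,
                                           seed=s + 1)
        cc = control_centrality_all(net, n_trials=1, seed=s + 2)
        stats_ = hicc_pathways(cc, pathways)
        by_name = {st.name: st for st in stats_}
        n_flagged += by_name["CONTROLLER"].is_hicc
        for st in stats_:
            if st.name.startswith("DECOY") and st.tested:
                decoy_tests += 1
                decoy_flags += st.is_hicc
    return {
        "n_replicates": n_replicates,
        "controller_recovery_rate": n_flagged / n_replicates,
        "decoy_false_positive_rate": decoy_flags / decoy_tests,
        "n_decoy_tests": decoy_tests,
    }


def mrmr_recovery(seed: int = 0, n_replicates: int = 20,
                  n_samples: int = 200, targets_per_replicate: int = 15,
                  ) -> dict:
    """Planted single-parent recovery: for single-parent targets of the
    synthetic hierarchy (SEM weights 0.8, noise sd 1), the true parent
    must be the first MRMR pick from the regulator candidate pool."""
    from .grn import discretize

    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2**31))
        net, truth = synth.generate_regulatory_network(seed=s)
        expr = synth.simulate_expression(net, truth, n_samples=n_samples,
                                         edge_weight=0.8, noise_sd=1.0,
                                         seed=s + 1)
        regulators = sorted(g for g in net.nodes if net.out_degree(g) > 0)
        singles = [g for g in sorted(net.nodes) if net.in_degree(g) == 1]
        picks = list(rng.choice(singles,
                                min(targets_per_replicate, len(singles)),
                                replace=False))
        codes = pd.DataFrame(
            {g: discretize(expr.values.loc[g].to_numpy(), 3)
             for g in expr.genes}).T
        for target in picks:
            parent = net.predecessors(target)[0]
            candidates = [c for c in regulators if c != target]
            chosen = mrmr_parents(expr, target, candidates, _codes=codes)
            total += 1
            hits += bool(chosen) and chosen[0] == parent
    return {
        "n_targets": total,
        "first_pick_recovery_rate": hits / total,
    }


def _eqtl_pair(rng: np.random.Generator, n: int, beta: float,
               maf: float) -> tuple[ExpressionMatrix, GenotypeMatrix]:
    g = rng.binomial(2, maf, size=n).astype(float)
    age = rng.normal(55.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    y = beta * g + 0.02 * age + 0.1 * sex + rng.normal(size=n)
    samples = [f"S{j:03d}" for j in range(n)]
    values = pd.DataFrame([y], index=["gene"], columns=samples)
    cov = pd.DataFrame({"disease": 0, "hba1c": 5.5, "age": age, "sex": sex},
                       index=samples)
    expr = ExpressionMatrix(values=values, covariates=cov)
    dos = pd.DataFrame([g], index=["snp"], columns=samples)
    geno = GenotypeMatrix(dosages=dos, chrom=pd.Series("1", index=["snp"]),
                          pos=pd.Series(1_000_000, index=["snp"]))
    return expr, geno


def eqtl_calibration_and_power(seed: int = 0, n_null_pairs: int = 2000,
                               n_power_replicates: int = 100,
                               n_perm_floor: int = 10_000) -> dict:
    """Null-p uniformity (KS), detection power for a planted effect
    (beta 1, MAF 0.3, n 100, BH q < 0.01 against a null background), and
    the legacy permutation-p floor at 10k permutations."""
    rng = np.random.default_rng(seed)

    null_p = []
    for _ in range(n_null_pairs):
        expr, geno = _eqtl_pair(rng, n=100, beta=0.0, maf=0.3)
        rec = fit_eqtl(expr, geno, [("snp", "gene")])
        null_p.append(rec[0].p)
    ks = stats.kstest(null_p, "uniform")

    detected = 0
    for _ in range(n_power_replicates):
        # one planted pair FDR-corrected against 20 null pairs, all fitted
        # jointly so the q-values come from the package's own BH step
        n = 100
        age = rng.normal(55.0, 8.0, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        samples = [f"S{j:03d}" for j in range(n)]
        cov = pd.DataFrame({"disease": 0, "hba1c": 5.5, "age": age,
                            "sex": sex}, index=samples)
        dosage_rows, value_rows, pairs = {}, {}, []
        for k in range(21):
            beta = 1.0 if k == 0 else 0.0
            g = rng.binomial(2, 0.3, size=n).astype(float)
            y = beta * g + 0.02 * age + 0.1 * sex + rng.normal(size=n)
            dosage_rows[f"snp{k:02d}"] = g
            value_rows[f"gene{k:02d}"] = y
            pairs.append((f"snp{k:02d}", f"gene{k:02d}"))
        expr = ExpressionMatrix(
            values=pd.DataFrame(value_rows, index=samples).T,
            covariates=cov)
        geno = GenotypeMatrix(
            dosages=pd.DataFrame(dosage_rows, index=samples).T,
            chrom=pd.Series("1", index=list(dosage_rows)),
            pos=pd.Series(1_000_000, index=list(dosage_rows)))
        rec = fit_eqtl(expr, geno, pairs)
        planted = next(r for r in rec if r.snp == "snp00")
        detected += planted.fdr_q < 0.01

    expr, geno = _eqtl_pair(rng, n=100, beta=3.0, maf=0.3)
    floor = permutation_p(expr.values.loc["gene"].to_numpy(),
                          geno.dosages.loc["snp"].to_numpy(),
                          expr.covariates, n_perm=n_perm_floor,
                          seed=int(rng.integers(2**31)),
                          legacy_perm_floor=True)

    return {
        "null_ks_p": float(ks.pvalue),
        "power_q01": detected / n_power_replicates,
        "perm_floor": floor,
        "n_null_pairs": n_null_pairs,
    }


def steiner_quality(seed: int = 0, n_instances: int = 20) -> dict:
    """Feasibility and approximation quality on exhaustively solvable
    instances (n <= 15 nodes, 4 terminals, unit node costs)."""
    rng = np.random.default_rng(seed)
    bound = 2.0 * math.log(4)
    feasible = 0
    within_bound = 0
    done = 0
    while done < n_instances:
        g = nx.gnp_random_graph(15, float(rng.uniform(0.2, 0.3)),
                                seed=int(rng.integers(1 << 30)))
        if not nx.is_connected(g):
            continue
        g = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})
        terminals = set(str(t) for t in
                        rng.choice(sorted(g.nodes), 4, replace=False))
        sol = klein_ravi_steiner(g, terminals)
        gsol = nx.Graph()
        gsol.add_nodes_from(sol.nodes)
        gsol.add_edges_from(sol.edges)
        ok = (nx.is_connected(gsol) and terminals <= set(gsol.nodes)
              and gsol.number_of_edges() == gsol.number_of_nodes() - 1)
        feasible += ok
        _, opt_cost = brute_force_steiner(g, terminals)
        if opt_cost == 0:
            within_bound += sol.total_node_cost == 0
        else:
            within_bound += sol.total_node_cost <= bound * opt_cost + 1e-9
        done += 1
    return {
        "n_instances": n_instances,
        "feasible_rate": feasible / n_instances,
        "within_bound_rate": within_bound / n_instances,
    }
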