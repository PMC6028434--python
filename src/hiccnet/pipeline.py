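"""End-to-end orchestration: feature selection → GRN → EGRN/LCC →
topology → control centrality → HiCc pathways → enrichment contrasts →
cis-eQTL → Steiner connection.

A single global seed fans out to per-stage seeds by stable hashing of the
stage name, so adding a stage does not shift the random streams of earlier
ones.  Every stage writes its table under the output directory and the run
ends with a JSON manifest of parameters, seeds and row counts; a stage
failure is recorded in the manifest and earlier outputs are preserved.
"""

from __future__ import annotations

import json
import time
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .control import control_centrality_all
from .eqtl import (cis_pairs, fit_eqtl, permutation_p, read_dosage_tsv,
                   read_gene_annotation, records_to_frame)
from .graph_core import (DirectedNetwork, largest_connected_component,
                         merge_networks, read_network, topology_summary,
                         write_network)
from .grn import GrnConfig, build_grn, read_expression_tsv, select_features
from .pathways import (GeneSetCollection, hicc_pathways,
                       hicc_enrichment_contrast, pathway_enrichment,
                       read_gene_list, read_gmt)
from .steiner import klein_ravi_steiner


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    expression: str = ""
    covariates: str = ""
    prior: str = ""                 # TF→target edge list (optional)
    kinase: str = ""                # kinase-substrate edge list (optional)
    signaling: str = ""             # signaling edge list (optional)
    pathways_gmt: str = ""
    disease_genes: str = ""         # one gene per line (optional)
    gwas_genes: str = ""            # construction GWAS genes (optional)
    genotypes: str = ""             # dosage TSV (optional)
    annotation: str = ""            # gene coordinates TSV (optional)
    outdir: str = "hiccnet_run"
    grn: GrnConfig = field(default_factory=GrnConfig)
    p_cut: float = 0.05
    min_overlap: int = 5
    exclude_cancer: bool = True
    n_random: int = 100
    window_bp: int = 250_000
    fdr_cut: float = 0.01
    n_perm: int = 10_000
    legacy_perm_floor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_cut < 1.0:
            raise ValueError("fdr_cut must be in (0, 1)")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of the stage name mixed with the
    global seed, kept below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 0x9E3779B1)) % (2**31)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (asdict(v) if isinstance(v, GrnConfig) else v)
                   for k, v in asdict(cfg).items()},
        "stages": [],
    }

    def record(stage: str, status: str, rows: int | None = None,
               seed: int | None = None, note: str = "") -> None:
        manifest["stages"].append({
            "stage": stage, "status": status, "rows": rows,
            "seed": seed, "note": note, "time": round(time.time(), 1)})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    state: dict = {}
    for stage, fn in _STAGES:
        seed = stage_seed(cfg.seed, stage)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows, note = fn(cfg, state, out, seed)
        except _SkipStage as e:
            record(stage, "skipped", note=str(e))
            continue
        except KeyError as e:
            record(stage, "skipped", note=f"missing upstream output: {e}")
            continue
        except Exception as e:  # noqa: BLE001 - manifest must record failures
            record(stage, "failed", note=f"{type(e).__name__}: {e}")
            continue
        record(stage, "completed", rows=rows, seed=seed, note=note)
    return manifest


class _SkipStage(Exception):
    """Raised by a stage to mark itself as skipped (missing optional input)."""


# ---------------------------------------------------------------------------
# Stage implementations (cfg, state, outdir, seed) -> (rows, note)
# ---------------------------------------------------------------------------

def _st_features(cfg, state, out, seed):
    expr = read_expression_tsv(cfg.expression, cfg.covariates)
    gwas = read_gene_list(cfg.gwas_genes) if cfg.gwas_genes else []
    state["expr"] = expr
    state["gwas"] = gwas
    if len(expr.genes) > cfg.grn.n_total:
        features = select_features(expr, gwas, cfg.grn)
    else:
        features = list(expr.genes)
    state["features"] = features
    pd.Series(features, name="gene").to_csv(out / "features.tsv", sep="\t",
                                            index=False)
    return len(features), ""


def _st_grn(cfg, state, out, seed):
    prior = read_network(cfg.prior, "prior") if cfg.prior else None
    net, scored = build_grn(state["expr"], state["gwas"], prior, cfg.grn,
                            features=state["features"])
    state["grn"] = net
    scored.edges.to_csv(out / "grn_scored_edges.tsv", sep="\t", index=False)
    write_network(net, out / "grn.tsv")
    return net.M, f"N={net.N}"


def _st_egrn(cfg, state, out, seed):
    extensions = []
    if cfg.kinase:
        extensions.append(read_network(cfg.kinase, "kinase"))
    if cfg.signaling:
        extensions.append(read_network(cfg.signaling, "signaling"))
    egrn = merge_networks(state["grn"], extensions)
    lcc = largest_connected_component(egrn)
    state["egrn"] = lcc
    write_network(lcc, out / "egrn_lcc.tsv")
    return lcc.M, f"N={lcc.N} (pre-LCC N={egrn.N}, M={egrn.M})"


def _st_topology(cfg, state, out, seed):
    summ = topology_summary(state["egrn"], n_random=min(cfg.n_random, 20),
                            seed=seed)
    pd.DataFrame([vars(summ)]).to_csv(out / "topology.tsv", sep="\t",
                                      index=False)
    return 1, f"aspl={summ.avg_shortest_path:.3f} C={summ.clustering_coefficient:.4f}"


def _st_cc(cfg, state, out, seed):
    cc = control_centrality_all(state["egrn"], n_trials=3, seed=seed)
    state["cc"] = cc
    df = pd.DataFrame({"node": sorted(cc.cc),
                       "cc": [cc.cc[g] for g in sorted(cc.cc)],
                       "normalized_cc": [cc.normalized_cc[g]
                                         for g in sorted(cc.cc)]})
    df.to_csv(out / "control_centrality.tsv", sep="\t", index=False)
    return len(df), f"mean_cc={np.mean(list(cc.cc.values())):.2f}"


def _st_hicc(cfg, state, out, seed):
    if not cfg.pathways_gmt:
        raise _SkipStage("no pathway GMT configured")
    pws = read_gmt(cfg.pathways_gmt)
    state["pathways"] = pws
    stats_ = hicc_pathways(state["cc"], pws, p_cut=cfg.p_cut,
                           min_overlap=cfg.min_overlap,
                           exclude_cancer=cfg.exclude_cancer)
    state["hicc"] = stats_
    pd.DataFrame([vars(s) for s in stats_]).to_csv(
        out / "hicc_pathways.tsv", sep="\t", index=False)
    n_hicc = sum(s.is_hicc for s in stats_)
    return len(stats_), f"hicc={n_hicc}"


def _st_enrichment(cfg, state, out, seed):
    if not cfg.disease_genes:
        raise _SkipStage("no disease gene set configured")
    disease = read_gene_list(cfg.disease_genes)
    # circularity guard: construction GWAS genes leave the disease set
    disease = sorted(set(disease) - set(state.get("gwas", [])))
    universe = sorted(state["egrn"].nodes)
    enr = pathway_enrichment(state["pathways"], disease, universe,
                             p_cut=cfg.p_cut)
    tested = [s for s in state["hicc"] if s.tested]
    hicc_flags = {s.name: s.is_hicc for s in tested}
    enr_flags = {name: enr[name][1] for name in hicc_flags}
    contrast = hicc_enrichment_contrast(hicc_flags, enr_flags)
    state["contrast"] = contrast
    pd.DataFrame({
        "pathway": sorted(enr),
        "fisher_p": [enr[n][0] for n in sorted(enr)],
        "enriched": [enr[n][1] for n in sorted(enr)],
    }).to_csv(out / "pathway_enrichment.tsv", sep="\t", index=False)
    with open(out / "enrichment_contrast.json", "w") as fh:
        json.dump({"table": contrast.table.tolist(),
                   "odds_ratio": contrast.odds_ratio,
                   "fisher_p_two_tailed": contrast.fisher_p_two_tailed}, fh,
                  indent=2)
    return len(enr), f"contrast_p={contrast.fisher_p_two_tailed:.4g}"


def _st_eqtl(cfg, state, out, seed):
    if not cfg.genotypes or not cfg.annotation:
        raise _SkipStage("no genotypes/annotation configured")
    geno = read_dosage_tsv(cfg.genotypes)
    annot = read_gene_annotation(cfg.annotation)
    expr = state["expr"]
    hicc_genes = sorted({g for s in state.get("hicc", []) if s.is_hicc
                         for g in state["pathways"].sets[s.name]}
                        & set(expr.genes))
    if not hicc_genes:
        raise _SkipStage("no HiCc pathway genes to test")
    pairs = cis_pairs(hicc_genes, annot, geno, window_bp=cfg.window_bp)
    records = fit_eqtl(expr, geno, pairs)
    rng = np.random.default_rng(seed)
    for r in records:
        if r.fdr_q < cfg.fdr_cut:
            y = expr.values.loc[r.gene].to_numpy(float)
            g = geno.dosages.loc[r.snp, expr.samples].to_numpy(float)
            r.perm_p = permutation_p(
                y, g, expr.covariates, n_perm=cfg.n_perm,
                seed=int(rng.integers(2**31)),
                legacy_perm_floor=cfg.legacy_perm_floor)
    df = records_to_frame(records)
    df.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    state["eqtl_genes"] = sorted({r.gene for r in records
                                  if r.fdr_q < cfg.fdr_cut})
    return len(records), f"fdr_pass={len(state['eqtl_genes'])} genes"


def _st_steiner(cfg, state, out, seed):
    terminals = set(state.get("eqtl_genes", []))
    g = state["egrn"].undirected()
    if len(terminals & set(g.nodes)) < 2:
        raise _SkipStage("fewer than 2 eQTL genes present in the network")
    sol = klein_ravi_steiner(g, terminals)
    rows = [{"node": v, "role": "terminal" if v in sol.terminals else "linker"}
            for v in sorted(sol.nodes)]
    pd.DataFrame(rows).to_csv(out / "steiner_nodes.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(sol.edges), columns=["a", "b"]).to_csv(
        out / "steiner_edges.tsv", sep="\t", index=False)
    return len(sol.nodes), (f"linkers={len(sol.linkers)}"
                            + (" partial" if sol.partial else ""))


_STAGES: list[tuple[str, object]] = [
    ("features", _st_features),
    ("grn", _st_grn),
    ("egrn_lcc", _st_egrn),
    ("topology", _st_topology),
    ("control_centrality", _st_cc),
    ("hicc_pathways", _st_hicc),
    ("enrichment_contrast", _st_enrichment),
    ("eqtl", _st_eqtl),
    ("steiner", _st_steiner),
]
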