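"""Pathway-level control-centrality statistics and disease-gene enrichment.

A pathway is *HiCc* (high control centrality) when the control-centrality
values of its genes inside the network are stochastically greater than those
of all other network genes (one-sided Mann–Whitney U, p < 0.05).  Enrichment
of pathways in disease gene sets uses one-sided Fisher exact tests, and the
HiCc vs non-HiCc enrichment-fraction contrast uses a two-tailed Fisher exact
test on the resulting 2×2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .control import CcResult, control_centrality_all
from .graph_core import DirectedNetwork, degree_preserving_randomize

CANCER_KEYWORDS = ("cancer", "carcinoma", "leukemia", "melanoma", "glioma")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or disease-gene lists)."""

    sets: dict[str, list[str]]
    origin: str = "pathways"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class PathwayCcStat:
    """Rank-sum comparison of one pathway's Cc values vs the rest."""

    name: str
    n_in_network: int
    U: float
    p: float
    mean_cc_in: float
    is_hicc: bool
    tested: bool = True


@dataclass
class EnrichmentContrast:
    """2×2 enrichment-fraction contrast between HiCc and non-HiCc pathways."""

    table: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), int))
    odds_ratio: float = float("nan")
    fisher_p_two_tailed: float = float("nan")


# ---------------------------------------------------------------------------
# GMT and gene-list I/O
# ---------------------------------------------------------------------------

def read_gmt(path, origin: str = "pathways") -> GeneSetCollection:
    """Read tab-separated GMT: name, description, genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g.strip() for g in fields[2:] if g.strip()]
    return GeneSetCollection(sets=sets, origin=origin)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(collection.sets[name])
            fh.write(f"{name}\t{collection.origin}\t{genes}\n")


def read_gene_list(path) -> list[str]:
    """One gene per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                out.append(g)
    return out


# ---------------------------------------------------------------------------
# HiCc pathway identification
# ---------------------------------------------------------------------------

def hicc_pathways(cc: CcResult, pathways: GeneSetCollection,
                  p_cut: float = 0.05, min_overlap: int = 5,
                  exclude_cancer: bool = True,
                  cancer_keywords: tuple[str, ...] = CANCER_KEYWORDS,
                  ) -> list[PathwayCcStat]:
    """Rank-sum HiCc test per pathway against all other network genes.

    Pathways with fewer than ``min_overlap`` network genes are returned with
    ``tested=False``; cancer pathways (keyword match on the name) are
    removed entirely when ``exclude_cancer``.
    """
    network_genes = set(cc.cc)
    out: list[PathwayCcStat] = []
    for name in sorted(pathways.sets):
        if exclude_cancer and any(k in name.lower() for k in cancer_keywords):
            continue
        in_net = sorted(set(pathways.sets[name]) & network_genes)
        if len(in_net) < min_overlap:
            out.append(PathwayCcStat(name=name, n_in_network=len(in_net),
                                     U=float("nan"), p=float("nan"),
                                     mean_cc_in=float("nan"),
                                     is_hicc=False, tested=False))
            continue
        inside = np.array([cc.cc[g] for g in in_net], float)
        outside = np.array([cc.cc[g] for g in network_genes - set(in_net)],
                           float)
        res = stats.mannwhitneyu(inside, outside, alternative="greater")
        out.append(PathwayCcStat(
            name=name, n_in_network=len(in_net), U=float(res.statistic),
            p=float(res.pvalue), mean_cc_in=float(inside.mean()),
            is_hicc=bool(res.pvalue < p_cut)))
    return out


def cc_vs_random_ensemble(net: DirectedNetwork, n_random: int = 100,
                          seed: int = 0, n_trials: int = 1,
                          ) -> dict[str, object]:
    """Compare the network's Cc distribution against a degree-preserving
    randomized ensemble: one two-sided rank-sum p per randomization, plus
    the mean Cc of each network."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    real = control_centrality_all(net, n_trials=n_trials, seed=seed)
    real_vals = np.array(sorted(real.cc.values()), float)
    rng = np.random.default_rng(seed)
    pvals, means = [], []
    for _ in range(n_random):
        rnet = degree_preserving_randomize(net, seed=int(rng.integers(2**31)))
        rcc = control_centrality_all(rnet, n_trials=n_trials,
                                     seed=int(rng.integers(2**31)))
        rvals = np.array(sorted(rcc.cc.values()), float)
        res = stats.mannwhitneyu(real_vals, rvals, alternative="two-sided")
        pvals.append(float(res.pvalue))
        means.append(float(rvals.mean()))
    return {"p_values": pvals, "random_means": means,
            "real_mean": float(real_vals.mean())}


# ---------------------------------------------------------------------------
# Disease-gene enrichment
# ---------------------------------------------------------------------------

def pathway_enrichment(pathways: GeneSetCollection, disease_genes: list[str],
                       universe: list[str], p_cut: float = 0.05,
                       ) -> dict[str, tuple[float, bool]]:
    """One-sided (greater) Fisher exact enrichment of each pathway in the
    disease gene set, restricted to the gene universe.

    Returns ``{pathway: (p, enriched)}``.  Callers must have removed any
    construction-time GWAS genes from ``disease_genes`` beforehand when the
    circularity exclusion applies.
    """
    uni = set(universe)
    dis = set(disease_genes) & uni
    if not dis:
        raise ValueError("disease gene set does not intersect the universe")
    out = {}
    for name in sorted(pathways.sets):
        pw = set(pathways.sets[name]) & uni
        a = len(pw & dis)
        b = len(pw - dis)
        c = len(dis - pw)
        d = len(uni - pw - dis)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        out[name] = (float(p), bool(p < p_cut))
    return out


def hicc_enrichment_contrast(hicc_flags: dict[str, bool],
                             enriched_flags: dict[str, bool],
                             ) -> EnrichmentContrast:
    """Two-tailed Fisher exact test on the 2×2 table of pathway counts
    (HiCc enriched/not vs non-HiCc enriched/not)."""
    missing = set(hicc_flags) ^ set(enriched_flags)
    if missing:
        raise ValueError(f"pathways missing a flag: {sorted(missing)[:5]}")
    a = sum(1 for n, h in hicc_flags.items() if h and enriched_flags[n])
    b = sum(1 for n, h in hicc_flags.items() if h and not enriched_flags[n])
    c = sum(1 for n, h in hicc_flags.items() if not h and enriched_flags[n])
    d = sum(1 for n, h in hicc_flags.items() if not h and not enriched_flags[n])
    return contrast_from_counts(a, b, c, d)


def contrast_from_counts(n_hicc_enriched: int, n_hicc_not: int,
                         n_non_enriched: int, n_non_not: int,
                         ) -> EnrichmentContrast:
    """Contrast directly from the four cell counts of the 2×2 table."""
    if (n_hicc_enriched + n_hicc_not == 0) or (n_non_enriched + n_non_not == 0):
        raise ValueError("both pathway groups must be non-empty")
    table = np.array([[n_hicc_enriched, n_hicc_not],
                      [n_non_enriched, n_non_not]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentContrast(table=table, odds_ratio=float(odds),
                              fisher_p_two_tailed=float(p))
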