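"""cis-eQTL mapping: per SNP–gene linear models with covariate adjustment,
joint BH-FDR, and permutation p-values.

The association model is ordinary least squares
``expression ~ intercept + dosage + age + sex``; the reported statistic is
the t of the dosage coefficient.  FDR is Benjamini–Hochberg across all
tested cis pairs jointly.  Permutation p-values permute the
covariate-residualized expression, preserving the genotype–covariate
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GenotypeMatrix:
    """SNP dosages (SNPs × samples, values in [0, 2]) with coordinates."""

    dosages: pd.DataFrame          # index snp id, columns sample ids
    chrom: pd.Series               # per-SNP chromosome
    pos: pd.Series                 # per-SNP 1-based position

    def __post_init__(self) -> None:
        if (self.pos < 0).any():
            raise ValueError("SNP positions must be non-negative")

    @property
    def snps(self) -> list[str]:
        return list(self.dosages.index)


@dataclass
class GeneAnnotation:
    """Gene coordinates: 1-based inclusive start/end per gene."""

    table: pd.DataFrame            # index gene id; columns chrom, start, end

    def __post_init__(self) -> None:
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene start must be <= end")


@dataclass
class EqtlRecord:
    snp: str
    gene: str
    beta: float
    t_stat: float
    p: float
    fdr_q: float = float("nan")
    perm_p: float = float("nan")


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Dosage TSV: columns snp, chrom, pos, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.set_index("snp")
    return GenotypeMatrix(dosages=df.drop(columns=["chrom", "pos"]),
                          chrom=df["chrom"], pos=df["pos"].astype(int))


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Minimal VCF reader: GT field of each sample → allele-count dosage."""
    rows, chroms, poss, snps = [], [], [], []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid = fields[0], int(fields[1]), fields[2]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            dos = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = [a for a in gt.split("/") if a not in (".", "")]
                dos.append(sum(int(a) > 0 for a in alleles))
            rows.append(dos)
            chroms.append(chrom)
            poss.append(pos)
            snps.append(vid if vid != "." else f"{chrom}:{pos}")
    dosages = pd.DataFrame(rows, index=snps, columns=samples, dtype=float)
    return GenotypeMatrix(dosages=dosages,
                          chrom=pd.Series(chroms, index=snps),
                          pos=pd.Series(poss, index=snps))


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def cis_pairs(genes: list[str], annot: GeneAnnotation, geno: GenotypeMatrix,
              window_bp: int = 250_000) -> list[tuple[str, str]]:
    """SNP–gene pairs with the SNP within ``window_bp`` of the gene body
    (inclusive bounds, same chromosome)."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    pairs = []
    pos = geno.pos
    chrom = geno.chrom
    for gene in genes:
        if gene not in annot.table.index:
            warnings.warn(f"gene {gene!r} missing annotation; skipped")
            continue
        row = annot.table.loc[gene]
        lo, hi = row["start"] - window_bp, row["end"] + window_bp
        hit = (chrom == row["chrom"]) & (pos >= lo) & (pos <= hi)
        pairs.extend((snp, gene) for snp in hit.index[hit])
    return pairs


# ---------------------------------------------------------------------------
# Association fitting
# ---------------------------------------------------------------------------

def _covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        np.ones(len(covariates)),
        covariates["age"].to_numpy(float),
        covariates["sex"].to_numpy(float),
    ])


def _dosage_t(y: np.ndarray, g: np.ndarray, xc: np.ndarray,
              ) -> tuple[float, float, float]:
    """(beta, t, p) of the dosage coefficient via Frisch–Waugh partialling:
    both expression and dosage are residualized on the covariates."""
    n = len(y)
    q, _ = np.linalg.qr(xc)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)
    gg = float(g_r @ g_r)
    if gg <= 1e-12:
        return float("nan"), float("nan"), float("nan")
    beta = float(g_r @ y_r) / gg
    df = n - xc.shape[1] - 1
    rss = float(y_r @ y_r) - beta * beta * gg
    sigma2 = max(rss, 0.0) / df
    if sigma2 <= 0:
        return beta, float("inf"), 0.0
    t = beta / np.sqrt(sigma2 / gg)
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return beta, float(t), float(p)


def fit_eqtl(expr, geno: GenotypeMatrix, pairs: list[tuple[str, str]],
             covariates: pd.DataFrame | None = None) -> list[EqtlRecord]:
    """OLS ``expression ~ intercept + dosage + age + sex`` per cis pair,
    with joint BH-FDR q-values across all tested pairs.

    ``expr`` is an :class:`~hiccnet.grn.ExpressionMatrix`; monomorphic SNPs
    are skipped and recorded via a warning.
    """
    cov = covariates if covariates is not None else expr.covariates
    samples = list(expr.values.columns)
    cov = cov.loc[samples]
    xc = _covariate_matrix(cov)
    if len(samples) < xc.shape[1] + 1 + 5:
        raise ValueError("need at least 5 more samples than parameters")
    dosages = geno.dosages[samples]
    records: list[EqtlRecord] = []
    skipped = 0
    for snp, gene in pairs:
        g = dosages.loc[snp].to_numpy(float)
        if g.var() <= 0:
            skipped += 1
            continue
        y = expr.values.loc[gene].to_numpy(float)
        beta, t, p = _dosage_t(y, g, xc)
        if not np.isfinite(p):
            skipped += 1
            continue
        records.append(EqtlRecord(snp=snp, gene=gene, beta=beta,
                                  t_stat=t, p=p))
    if skipped:
        warnings.warn(f"skipped {skipped} monomorphic/degenerate pairs")
    if records:
        pvals = np.array([r.p for r in records])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(records, qvals):
            r.fdr_q = float(q)
    return records


def permutation_p(y: np.ndarray, g: np.ndarray, covariates: pd.DataFrame,
                  n_perm: int = 10_000, seed: int = 0,
                  legacy_perm_floor: bool = True) -> float:
    """Permutation p-value for one SNP–gene pair.

    The covariate-residualized expression is permuted across samples and
    the dosage t-statistic recomputed each time.  With
    ``legacy_perm_floor`` (default) the p-value is ``#exceedances/n_perm``
    floored at ``1/n_perm`` (so 1e-4 at 10k permutations); otherwise the
    add-one convention ``(1 + #exceedances)/(n_perm + 1)`` is used.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    xc = _covariate_matrix(covariates)
    n = len(y)
    q, _ = np.linalg.qr(xc)
    proj = np.eye(n) - q @ q.T
    y_r = proj @ y
    g_r = proj @ g
    gg = float(g_r @ g_r)
    df = n - xc.shape[1] - 1

    def t_of(yy: np.ndarray) -> np.ndarray:
        # yy: (n_perm, n) already in the residual space after re-projection
        gy = yy @ g_r
        beta = gy / gg
        rss = np.einsum("ij,ij->i", yy, yy) - beta * beta * gg
        sigma2 = np.maximum(rss, 1e-300) / df
        return beta / np.sqrt(sigma2 / gg)

    obs = abs(float(t_of(y_r[None, :])[0]))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y_r) for _ in range(n_perm)])
    perms = perms @ proj.T   # re-residualize the permuted outcome
    t_perm = np.abs(t_of(perms))
    exceed = int((t_perm >= obs).sum())
    if legacy_perm_floor:
        return max(exceed, 1) / n_perm
    return (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Generic two-group rank-sum utility
# ---------------------------------------------------------------------------

def group_rank_sum(values_a, values_b, alternative: str = "two-sided",
                   ) -> tuple[float, float]:
    """Mann–Whitney U between two samples: exact enumeration when the
    smaller sample has ≤ 8 untied values, otherwise the tie-corrected
    normal approximation.  Returns (U, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def records_to_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def read_gene_annotation(path) -> GeneAnnotation:
    """BED-like TSV with columns gene, chrom, start, end (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneAnnotation(table=df.set_index("gene"))


def write_gene_annotation(annot: GeneAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="gene")


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = geno.dosages.copy()
    df.insert(0, "pos", geno.pos)
    df.insert(0, "chrom", geno.chrom)
    df.to_csv(path, sep="\t", index_label="snp")
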