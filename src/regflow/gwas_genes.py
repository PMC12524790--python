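"""Stage 1: SNP filtering, SNP-to-gene mapping, and gene-level statistics.

Gene-level p-values combine the p-values of all SNPs mapped to a gene with
Fisher's method, or Brown's correlated-chi-square approximation when a
pairwise LD correlation matrix is supplied. Competitive gene-set and
gene-property enrichment operate on the resulting gene-level statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("regflow")


def filter_snps(snps: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Keep SNPs with p strictly below ``threshold``, preserving input order."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return snps.loc[snps["pvalue"] < threshold].reset_index(drop=True)


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 10_000
) -> pd.DataFrame:
    """Map SNPs to genes within the gene body extended by ``window_bp``.

    A pair (snp_id, gene_id) is emitted iff chromosomes match and
    ``start - window_bp <= pos <= end + window_bp`` (inclusive). A SNP may
    map to several genes; unmapped SNPs are absent from the output.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    pairs: list[tuple[str, str]] = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        ssub = snps.loc[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy()
        sid = ssub["snp_id"].to_numpy()
        for gene_id, start, end in zip(gsub["gene_id"], gsub["start"], gsub["end"]):
            hit = (pos >= start - window_bp) & (pos <= end + window_bp)
            pairs.extend((s, gene_id) for s in sid[hit])
    return pd.DataFrame(pairs, columns=["snp_id", "gene_id"])


def _brown_scale(ld: np.ndarray) -> tuple[float, float]:
    """Scale factor c and effective df for Brown's method.

    Uses the Kost-McDermott cubic to approximate cov(-2 ln p_i, -2 ln p_j)
    from the pairwise correlation.
    """
    k = ld.shape[0]
    r = ld[np.triu_indices(k, 1)]
    cov = 3.263 * r + 0.710 * r**2 + 0.027 * r**3
    var = 4.0 * k + 2.0 * cov.sum()
    mean = 2.0 * k
    c = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    return c, df


def gene_level_pvalue(
    pvalues, ld: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Combine SNP p-values into one gene-level statistic.

    Without ``ld``: Fisher's method, ``stat = -2 sum(ln p)`` on chi-square
    with ``2k`` df. With ``ld`` (square symmetric unit-diagonal correlation
    matrix): Brown's approximation with rescaled statistic and df.

    Returns (stat, df, pvalue).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    if ld is None:
        df = 2.0 * p.size
        return stat, df, float(stats.chi2.sf(stat, df))
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (p.size, p.size):
        raise ValueError(
            f"ld matrix shape {ld.shape} does not match {p.size} p-values"
        )
    if not np.allclose(ld, ld.T) or not np.allclose(np.diag(ld), 1.0):
        raise ValueError("ld must be symmetric with unit diagonal")
    c, df = _brown_scale(ld)
    return stat, df, float(stats.chi2.sf(stat / c, df))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def aggregate_gene_pvalues(
    snps: pd.DataFrame,
    mapping: pd.DataFrame,
    alpha: float = 0.05,
    ld: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-gene combined p-values over all mapped SNPs, Bonferroni-flagged.

    ``ld`` optionally maps gene_id -> correlation matrix ordered as the
    gene's SNPs appear in ``mapping``.
    """
    pmap = snps.set_index("snp_id")["pvalue"]
    rows = []
    gene_groups = mapping.groupby("gene_id", sort=True)
    for gene_id, sub in gene_groups:
        pvals = pmap.loc[sub["snp_id"]].to_numpy()
        gene_ld = ld.get(gene_id) if ld else None
        stat, df, pvalue = gene_level_pvalue(pvals, gene_ld)
        rows.append(
            {
                "gene_id": gene_id,
                "n_snps": len(pvals),
                "stat": stat,
                "df": df,
                "pvalue": pvalue,
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "n_snps", "stat", "df", "pvalue"])
    if len(out):
        thr = bonferroni_threshold(len(out), alpha)
        out["significant"] = out["pvalue"] < thr
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


@dataclass
class OlsEnrichment:
    beta: float
    se: float
    t: float
    pvalue: float
    df: int


def _ols_one_sided(y: np.ndarray, x: np.ndarray) -> OlsEnrichment:
    """OLS of y on [1, x]; one-sided (greater) test on the slope."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_hat = xtx_inv @ X.T @ y
    resid = y - X @ beta_hat
    df = n - 2
    if df <= 0:
        raise ValueError("need more observations than parameters")
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(beta_hat[1])
    if se == 0.0:
        # perfect fit: slope sign decides the one-sided p
        if abs(beta) < 1e-12:
            return OlsEnrichment(0.0, se, 0.0, 0.5, df)
        t = np.inf if beta > 0 else -np.inf
        p = 0.0 if beta > 0 else 1.0
        return OlsEnrichment(beta, se, t, p, df)
    t = beta / se
    p = float(stats.t.sf(t, df))
    return OlsEnrichment(beta, se, t, p, df)


def enrich_competitive(gene_stats, membership) -> OlsEnrichment:
    """Competitive gene-set test: regress gene statistics on set membership.

    One-sided (greater): do set members carry larger statistics than
    non-members?
    """
    y = np.asarray(gene_stats, dtype=float)
    m = np.asarray(membership, dtype=float)
    if y.shape != m.shape:
        raise ValueError("gene_stats and membership lengths differ")
    n_in = int(m.sum())
    if n_in < 2 or (m.size - n_in) < 2:
        raise ValueError("need >= 2 members and >= 2 non-members")
    if np.ptp(m) == 0:
        raise ValueError("membership has zero variance")
    return _ols_one_sided(y, m)


def enrich_property(gene_stats, property_values) -> OlsEnrichment:
    """Gene-property test: OLS slope of gene statistics on a continuous
    covariate (e.g. tissue expression), one-sided greater."""
    y = np.asarray(gene_stats, dtype=float)
    x = np.asarray(property_values, dtype=float)
    if y.shape != x.shape:
        raise ValueError("gene_stats and property_values lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("property has zero variance")
    return _ols_one_sided(y, x)


def run_gwas_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    *,
    snp_p: float = 5e-8,
    window_bp: int = 10_000,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP catalogue + gene-level statistics for one summary-stat table.

    The SNP catalogue lists genome-wide-significant SNPs (reporting path);
    gene aggregation uses ALL mapped SNPs regardless of significance.
    """
    catalogue = filter_snps(snps, snp_p)
    mapping = map_snps_to_genes(snps, genes, window_bp)
    gene_level = aggregate_gene_pvalues(snps, mapping, alpha)
    logger.info(
        "gwas_genes: %d significant SNPs, %d genes aggregated, %d significant",
        len(catalogue),
        len(gene_level),
        int(gene_level["significant"].sum()) if len(gene_level) else 0,
    )
    return catalogue, gene_level
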