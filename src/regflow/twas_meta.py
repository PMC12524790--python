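"""Stage 2: summary-statistic TWAS integration across brain regions.

Per-region gene z-scores (computed from eQTL weight models and SNP-level
z-scores, or supplied precomputed) are screened for direction-consistent
significance in at least ``min_regions`` regions, then meta-analysed with
Fisher's sum-of-logs method and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("regflow")

_P_FLOOR = 1e-300


@dataclass
class EqtlModel:
    """Per-(gene, region) expression-prediction weights.

    ``weights`` maps snp_id -> elastic-net weight; ``snp_sd`` maps
    snp_id -> reference-panel allele-dosage standard deviation; ``cv_r2``
    is the cross-validated prediction accuracy carried downstream as an
    enrichment weight.
    """

    gene_id: str
    region: str
    weights: dict[str, float]
    snp_sd: dict[str, float] = field(default_factory=dict)
    cv_r2: float = 1.0

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError(f"model {self.gene_id}/{self.region}: all weights zero")
        if not 0 < self.cv_r2 <= 1:
            raise ValueError(f"model {self.gene_id}/{self.region}: cv_r2 outside (0, 1]")


def spredixcan_z(
    model: EqtlModel,
    snp_z: dict[str, float],
    snp_cov: np.ndarray | None = None,
) -> float:
    """Gene association z-score from SNP z-scores and eQTL weights.

    z_gene = sum_l w_l * sigma_l * z_l / sigma_g with
    sigma_g^2 = w' Sigma w over the model's SNPs (Sigma defaults to the
    identity, i.e. independent SNPs).
    """
    snps = [s for s, w in model.weights.items() if w != 0]
    missing = [s for s in snps if s not in snp_z]
    if missing:
        raise ValueError(f"snp_z missing model SNP(s): {', '.join(missing)}")
    w = np.array([model.weights[s] for s in snps], dtype=float)
    sd = np.array([model.snp_sd.get(s, 1.0) for s in snps], dtype=float)
    z = np.array([snp_z[s] for s in snps], dtype=float)
    if snp_cov is None:
        cov = np.diag(sd**2)
    else:
        cov = np.asarray(snp_cov, dtype=float)
        if cov.shape != (len(snps), len(snps)):
            raise ValueError("snp_cov does not conform to the model's SNPs")
    var_g = float(w @ cov @ w)
    if var_g <= 0:
        raise ValueError(f"model {model.gene_id}/{model.region}: sigma_g is zero (degenerate)")
    return float((w * sd * z).sum() / np.sqrt(var_g))


def z_to_p(z: float) -> float:
    """Two-sided normal tail probability, clipped away from 0."""
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, _P_FLOOR), 1.0))


def gene_stats_from_models(
    models: list[EqtlModel],
    snp_z: dict[str, float],
    snp_cov: dict[tuple[str, str], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Build a GeneStat table (gene_id, region, zscore, pvalue, cv_r2)."""
    rows = []
    for m in models:
        cov = snp_cov.get((m.gene_id, m.region)) if snp_cov else None
        z = spredixcan_z(m, snp_z, cov)
        rows.append(
            {
                "gene_id": m.gene_id,
                "region": m.region,
                "zscore": z,
                "pvalue": z_to_p(z),
                "cv_r2": m.cv_r2,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "region", "zscore", "pvalue", "cv_r2"])


def select_consistent_genes(
    stats_table: pd.DataFrame, min_regions: int = 3, alpha: float = 0.05
) -> pd.DataFrame:
    """Count significant regions per sign and assign a direction per gene.

    direction = "up" if >= min_regions regions have p < alpha with z > 0 and
    the negative count stays below min_regions; "down" symmetric; "conflict"
    if both counts reach min_regions (logged, never selected); "none"
    otherwise. Rows with z exactly 0 count as neither sign.
    """
    if min_regions < 1:
        raise ValueError("min_regions must be >= 1")
    if stats_table.duplicated(subset=["gene_id", "region"]).any():
        dup = stats_table.loc[
            stats_table.duplicated(subset=["gene_id", "region"]), ["gene_id", "region"]
        ].iloc[0]
        raise ValueError(f"duplicate (gene, region) row: {dup.gene_id}/{dup.region}")
    sig = stats_table["pvalue"] < alpha
    pos = sig & (stats_table["zscore"] > 0)
    neg = sig & (stats_table["zscore"] < 0)
    agg = pd.DataFrame(
        {
            "n_sig_pos": pos.groupby(stats_table["gene_id"]).sum(),
            "n_sig_neg": neg.groupby(stats_table["gene_id"]).sum(),
        }
    ).reset_index()
    up = (agg["n_sig_pos"] >= min_regions) & (agg["n_sig_neg"] < min_regions)
    down = (agg["n_sig_neg"] >= min_regions) & (agg["n_sig_pos"] < min_regions)
    conflict = (agg["n_sig_pos"] >= min_regions) & (agg["n_sig_neg"] >= min_regions)
    agg["direction"] = "none"
    agg.loc[up, "direction"] = "up"
    agg.loc[down, "direction"] = "down"
    agg.loc[conflict, "direction"] = "conflict"
    agg["consistent_selected"] = up | down
    n_conf = int(conflict.sum())
    if n_conf:
        logger.warning(
            "select_consistent_genes: %d gene(s) significant in both directions, excluded",
            n_conf,
        )
    return agg


def fisher_meta(pvalues) -> tuple[float, int, float]:
    """Fisher's sum-of-logs combination: (stat, df, p_meta)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return stat, df, float(stats.chi2.sf(stat, df))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_twas_meta(
    stats_table: pd.DataFrame,
    min_regions: int = 3,
    alpha: float = 0.05,
    meta_alpha: float = 0.05,
    bh_family: str = "selected",
) -> pd.DataFrame:
    """Consistency selection followed by Fisher meta-analysis and BH.

    Fisher combines ALL regions with a statistic for the gene (df adapts).
    By default BH is applied within the consistency-selected family
    (``bh_family="selected"``); pass ``"all"`` to adjust over every gene.
    """
    if bh_family not in ("selected", "all"):
        raise ValueError("bh_family must be 'selected' or 'all'")
    sel = select_consistent_genes(stats_table, min_regions, alpha)
    meta_rows = []
    for gene_id, sub in stats_table.groupby("gene_id", sort=True):
        stat, df, p_meta = fisher_meta(sub["pvalue"].to_numpy())
        meta_rows.append(
            {"gene_id": gene_id, "fisher_stat": stat, "df": df, "p_meta": p_meta}
        )
    meta = pd.DataFrame(meta_rows)
    out = sel.merge(meta, on="gene_id", how="left")
    out["p_adj"] = np.nan
    family = out["consistent_selected"] if bh_family == "selected" else np.ones(len(out), bool)
    family = np.asarray(family, dtype=bool)
    if family.any():
        out.loc[family, "p_adj"] = bh_adjust(out.loc[family, "p_meta"].to_numpy())
    out["meta_selected"] = out["consistent_selected"] & (out["p_adj"] < meta_alpha)
    n_up = int((out["meta_selected"] & (out["direction"] == "up")).sum())
    n_down = int((out["meta_selected"] & (out["direction"] == "down")).sum())
    logger.info(
        "twas_meta: %d consistent genes, %d meta-selected (%d up / %d down)",
        int(out["consistent_selected"].sum()),
        int(out["meta_selected"].sum()),
        n_up,
        n_down,
    )
    return out
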