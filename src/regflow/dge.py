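"""Stage 4: sex-stratified differential expression on count matrices.

Counts are filtered on CPM, normalised with trimmed-mean-of-M-values
(TMM) factors, and tested gene-by-gene with a covariate-adjusted linear
model on log2-CPM. DEGs are classified at a soft (|logFC| > 0.5,
p < 0.05) and a strict (|logFC| > 1, adjusted p < 0.05) threshold, and
directions are cross-referenced against the TWAS meta-analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from regflow.twas_meta import bh_adjust

logger = logging.getLogger("regflow")


def _check_libsizes(counts: pd.DataFrame) -> np.ndarray:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"zero-total library for sample {counts.columns[zero[0]]!r}")
    return lib


def cpm(counts: pd.DataFrame, libsizes: np.ndarray | None = None) -> pd.DataFrame:
    if libsizes is None:
        libsizes = _check_libsizes(counts)
    return counts / libsizes * 1e6


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int | None = None
) -> pd.DataFrame:
    """Keep genes with CPM > min_cpm in at least min_samples samples.

    ``min_samples`` defaults to the full sample count floor-divided by
    two when unspecified is not desirable; callers should pass the
    smallest group size. Here the default is 2.
    """
    if min_samples is None:
        min_samples = 2
    c = cpm(counts)
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    logger.info("filter_low_expression: kept %d/%d genes", int(keep.sum()), len(counts))
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, geometric mean 1.

    Reference sample: the one whose upper-quartile CPM is closest to the
    mean upper-quartile. For each sample, M (log2 expression ratio vs the
    reference) and A (average log2 abundance) are computed over genes
    positive in both; both tails of M (30%) and A (5%) are trimmed and the
    factor is 2 to the precision-weighted mean of the remaining M values.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = _check_libsizes(counts)
    x = counts.to_numpy(dtype=float)
    c = x / lib * 1e6
    uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0 for col in c.T])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs = x[:, j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            logger.warning(
                "tmm_factors: sample %r shares no positive genes with reference; factor 1",
                counts.columns[j],
            )
            continue
        o = obs[both] / lib[j]
        r = ref[both] / ref_lib
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        # asymptotic binomial variance of M (delta method)
        v = (
            (lib[j] - obs[both]) / (lib[j] * obs[both])
            + (ref_lib - ref[both]) / (ref_lib * ref[both])
        )
        if np.allclose(m, m[0], atol=1e-10):
            factors[j] = 2.0 ** m[0]
            continue
        m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        factors[j] = 2.0 ** ((m[keep] / v[keep]).sum() / (1.0 / v[keep]).sum())

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log2_cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior_count: float = 0.5
) -> pd.DataFrame:
    """log2 CPM on TMM-adjusted library sizes with a prior count."""
    lib = _check_libsizes(counts)
    if factors is not None:
        lib = lib * factors.loc[counts.columns].to_numpy()
    return np.log2((counts + prior_count) / (lib + 2 * prior_count) * 1e6)


def dge_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    covariate_names: list[str] | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene covariate-adjusted test of diagnosis on log2-CPM.

    Fits, for every gene simultaneously, a linear model of log2-CPM on
    diagnosis (MDD vs control) plus the named covariates; logFC is the
    diagnosis coefficient (log2 scale) with a two-sided t-test on
    residual df, BH-adjusted across genes.
    """
    covariate_names = covariate_names or []
    meta = meta.set_index("sample_id").loc[counts.columns]
    diag = (meta["diagnosis"] == "MDD").to_numpy(dtype=float)
    if diag.sum() < 2 or (len(diag) - diag.sum()) < 2:
        raise ValueError("need >= 2 samples per diagnosis arm")
    cols = [np.ones(len(diag)), diag]
    for name in covariate_names:
        if name not in meta.columns:
            raise ValueError(f"covariate {name!r} absent from metadata")
        v = pd.to_numeric(meta[name], errors="raise").to_numpy(dtype=float)
        cols.append(v)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first covariate whose removal restores full rank
        for k, name in enumerate(covariate_names, start=2):
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank:
                raise ValueError(f"design is singular: covariate {name!r} is confounded")
        raise ValueError("design matrix is singular")

    factors = tmm_factors(counts)
    Y = log2_cpm(counts, factors, prior_count).to_numpy()
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - beta @ X.T
    sigma2 = (resid**2).sum(axis=1) / df_resid
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    logfc = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(t), df_resid)
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "logFC": logfc,
            "pvalue": pvalue,
            "p_adj": bh_adjust(pvalue),
        }
    ).reset_index(drop=True)
    return out


def classify_degs(
    results: pd.DataFrame,
    soft: tuple[float, float] = (0.5, 0.05),
    strict: tuple[float, float] = (1.0, 0.05),
) -> pd.DataFrame:
    """Attach soft/strict DEG flags (strict inequalities at the boundary)."""
    soft_lfc, soft_p = soft
    strict_lfc, strict_p = strict
    if min(soft_lfc, soft_p, strict_lfc, strict_p) <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    out["soft_deg"] = (out["logFC"].abs() > soft_lfc) & (out["pvalue"] < soft_p)
    out["strict_deg"] = (out["logFC"].abs() > strict_lfc) & (out["p_adj"] < strict_p)
    return out


def run_stratified(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    covariate_names: list[str] | None = None,
    min_cpm: float = 1.0,
    soft: tuple[float, float] = (0.5, 0.05),
    strict: tuple[float, float] = (1.0, 0.05),
    dataset: str = "dataset1",
) -> tuple[dict[tuple[str, str, str], pd.DataFrame], pd.DataFrame]:
    """Run the DE test per (sex, region) stratum; strata with fewer than
    two samples per arm are skipped with a warning.

    Returns ({(dataset, sex, region): DgeResult table}, summary table of
    soft/strict DEG counts per stratum).
    """
    results: dict[tuple[str, str, str], pd.DataFrame] = {}
    summary_rows = []
    strata = meta.groupby(["sex", "region"], sort=True)
    for (sex, region), sub in strata:
        n_case = int((sub["diagnosis"] == "MDD").sum())
        n_ctrl = int((sub["diagnosis"] == "control").sum())
        if n_case < 2 or n_ctrl < 2:
            logger.warning(
                "run_stratified: skipping %s/%s/%s (%d cases / %d controls)",
                dataset, sex, region, n_case, n_ctrl,
            )
            continue
        sub_counts = counts[sub["sample_id"]]
        sub_counts = filter_low_expression(sub_counts, min_cpm, min(n_case, n_ctrl))
        res = dge_test(sub_counts, sub, covariate_names)
        res = classify_degs(res, soft, strict)
        res.insert(1, "dataset", dataset)
        res.insert(2, "sex", sex)
        res.insert(3, "region", region)
        results[(dataset, sex, region)] = res
        summary_rows.append(
            {
                "dataset": dataset,
                "sex": sex,
                "region": region,
                "n_case": n_case,
                "n_control": n_ctrl,
                "n_genes_tested": len(res),
                "n_soft_deg": int(res["soft_deg"].sum()),
                "n_strict_deg": int(res["strict_deg"].sum()),
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "dataset", "sex", "region", "n_case", "n_control",
            "n_genes_tested", "n_soft_deg", "n_strict_deg",
        ],
    )
    return results, summary


def direction_concordance(
    twas: pd.DataFrame, dge_strata: dict[tuple[str, str, str], pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare TWAS-predicted direction with per-stratum DE direction.

    Rows are emitted only for genes that are TWAS meta-selected AND
    soft-DEG in the stratum; a row is concordant when sign(logFC) matches
    the TWAS direction. The summary gives the concordant fraction per sex.
    """
    sel = twas.loc[twas["meta_selected"], ["gene_id", "direction"]]
    twas_dir = dict(zip(sel["gene_id"], sel["direction"]))
    rows = []
    for (dataset, sex, region), res in sorted(dge_strata.items()):
        hits = res.loc[res["soft_deg"] & res["gene_id"].isin(twas_dir)]
        for gene_id, logfc in zip(hits["gene_id"], hits["logFC"]):
            tdir = twas_dir[gene_id]
            ddir = "up" if logfc > 0 else "down"
            rows.append(
                {
                    "gene_id": gene_id,
                    "dataset": dataset,
                    "sex": sex,
                    "region": region,
                    "twas_dir": tdir,
                    "dge_dir": ddir,
                    "concordant": tdir == ddir,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "dataset", "sex", "region", "twas_dir", "dge_dir", "concordant",
        ],
    )
    if len(table):
        summary = (
            table.groupby("sex")["concordant"].agg(["mean", "size"]).reset_index()
        ).rename(columns={"mean": "concordant_fraction", "size": "n_pairs"})
    else:
        summary = pd.DataFrame(columns=["sex", "concordant_fraction", "n_pairs"])
    return table, summary
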