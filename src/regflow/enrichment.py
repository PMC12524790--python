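"""Stage 3: gene-set enrichment with permutation nulls.

Two modes: uncertainty-weighted regression enrichment (weights such as
cross-validated prediction accuracy enter a weighted least-squares fit of
the signature on set membership) and weighted Kolmogorov-Smirnov rank
enrichment with a running-sum enrichment score. Both use gene-label
permutation nulls, a plus-one-corrected two-sided empirical p-value, and
a null-standardised score (NES).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from regflow.twas_meta import bh_adjust

logger = logging.getLogger("regflow")


@dataclass
class EnrichmentResult:
    set_name: str
    n_members_used: int
    effect: float
    nes: float
    pvalue: float
    direction: str  # "up" | "down"
    p_adj: float = float("nan")


def _wls_beta(y: np.ndarray, member: np.ndarray, w: np.ndarray) -> float:
    """Slope of weighted least squares of y on intercept + membership."""
    sw = w.sum()
    mw = (w * member).sum()
    # weighted covariance formulation avoids building design matrices
    ybar = (w * y).sum() / sw
    mbar = mw / sw
    sxx = (w * (member - mbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("membership is constant within the signature")
    sxy = (w * (member - mbar) * (y - ybar)).sum()
    return float(sxy / sxx)


def enrich_weighted_regression(
    signature: dict[str, float],
    gene_set,
    weights: dict[str, float] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    exact: bool = False,
    set_name: str = "",
) -> EnrichmentResult:
    """Weighted-regression enrichment of a gene set in a signed signature.

    ``effect`` is the membership slope of a WLS fit of the signature on
    intercept + membership with per-gene weights (missing weights default
    to 1). The null permutes gene labels of the membership vector, keeping
    weights attached to genes; with ``exact=True`` all distinct
    memberships of the same size are enumerated instead (small sets only).
    p = (#{|beta*| >= |beta|} + 1) / (n_null + 1); NES standardises beta
    by the null mean and sd.
    """
    genes = list(signature)
    y = np.array([signature[g] for g in genes], dtype=float)
    w = np.array([(weights or {}).get(g, 1.0) for g in genes], dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    member = np.array([g in set(gene_set) for g in genes], dtype=float)
    k = int(member.sum())
    if k < 2 or len(genes) - k < 2:
        raise ValueError("need >= 2 members and >= 2 non-members in the signature")
    if n_perm < 100 and not exact:
        logger.warning("enrich_weighted_regression: n_perm=%d is low", n_perm)
    beta = _wls_beta(y, member, w)

    if exact:
        null = np.array(
            [
                _wls_beta(y, _indicator(len(genes), idx), w)
                for idx in itertools.combinations(range(len(genes)), k)
            ]
        )
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _wls_beta(y, rng.permutation(member), w)
    n_null = null.size
    pvalue = (int((np.abs(null) >= abs(beta) - 1e-12).sum()) + 1) / (n_null + 1)
    sd = float(null.std(ddof=0))
    nes = float((beta - null.mean()) / sd) if sd > 0 else 0.0
    return EnrichmentResult(
        set_name=set_name,
        n_members_used=k,
        effect=beta,
        nes=nes,
        pvalue=float(pvalue),
        direction="up" if beta > 0 else "down",
    )


def _indicator(n: int, idx) -> np.ndarray:
    v = np.zeros(n)
    v[list(idx)] = 1.0
    return v


def _running_es(scores_sorted: np.ndarray, hit_sorted: np.ndarray, exponent: float) -> float:
    """Enrichment score: signed extremum of the weighted-KS running sum."""
    n = scores_sorted.size
    n_hit = int(hit_sorted.sum())
    n_miss = n - n_hit
    hit_w = np.abs(scores_sorted) ** exponent
    denom = hit_w[hit_sorted].sum()
    if denom == 0:
        # all member scores zero: fall back to equal hit weights
        hit_w = np.ones(n)
        denom = float(n_hit)
    steps = np.where(hit_sorted, hit_w / denom, -1.0 / n_miss if n_miss else 0.0)
    running = np.cumsum(steps)
    lo, hi = float(running.min()), float(running.max())
    return hi if hi >= -lo else lo


def enrich_gsea(
    ranking: dict[str, float],
    gene_set,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "",
) -> EnrichmentResult:
    """Weighted-KS rank enrichment with a gene-label permutation null.

    Genes are sorted by descending score; a member hit at position i adds
    |score_i|^exponent / sum_set |score|^exponent to the running sum, a
    miss subtracts 1/(N - N_set). ES is the extremum; NES divides ES by
    the mean |null ES| of matching sign.
    """
    genes = np.array(list(ranking))
    scores = np.array([ranking[g] for g in genes], dtype=float)
    if np.ptp(scores) == 0:
        raise ValueError("ranking scores are all equal")
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    order = np.lexsort((genes, -scores))  # descending score, id tiebreak
    genes_sorted = genes[order]
    scores_sorted = scores[order]
    hit = np.isin(genes_sorted, list(members))
    es = _running_es(scores_sorted, hit, exponent)

    rng = np.random.default_rng(seed)
    n_hit = int(hit.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_hit = np.zeros(genes.size, dtype=bool)
        perm_hit[rng.choice(genes.size, size=n_hit, replace=False)] = True
        null[i] = _running_es(scores_sorted, perm_hit, exponent)
    pvalue = (int((np.abs(null) >= abs(es) - 1e-12).sum()) + 1) / (n_perm + 1)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = float(np.abs(same_sign).mean()) if same_sign.size else float("nan")
    nes = float(es / denom) if denom and np.isfinite(denom) else 0.0
    return EnrichmentResult(
        set_name=set_name,
        n_members_used=n_hit,
        effect=float(es),
        nes=nes,
        pvalue=float(pvalue),
        direction="up" if es > 0 else "down",
    )


def enrich_catalogue(
    signature: dict[str, float],
    sets: list[tuple[str, str, list[str]]],
    weights: dict[str, float] | None = None,
    mode: str = "regression",
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Run one enrichment mode over a GMT catalogue with BH adjustment.

    Set size is counted on members present in the signature; sets outside
    [min_size, max_size] are skipped. One derived sub-seed per set keeps
    results independent of catalogue order.
    """
    if mode not in ("regression", "gsea"):
        raise ValueError("mode must be 'regression' or 'gsea'")
    sig_genes = set(signature)
    results: list[EnrichmentResult] = []
    for name, _desc, members in sets:
        used = [g for g in members if g in sig_genes]
        if not min_size <= len(used) <= max_size:
            continue
        sub_seed = (seed * 1_000_003 + _stable_hash(name)) % (2**32)
        try:
            if mode == "regression":
                res = enrich_weighted_regression(
                    signature, used, weights, n_perm, sub_seed, set_name=name
                )
            else:
                res = enrich_gsea(
                    signature, used, exponent, n_perm, sub_seed, set_name=name
                )
        except ValueError as exc:
            logger.warning("enrich_catalogue: skipping set %r: %s", name, exc)
            continue
        results.append(res)
    if not results:
        logger.warning("enrich_catalogue: no gene set survived the size filter")
        return pd.DataFrame(
            columns=[
                "set_name", "n_members_used", "effect", "nes", "pvalue",
                "p_adj", "direction",
            ]
        )
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "n_members_used": [r.n_members_used for r in results],
            "effect": [r.effect for r in results],
            "nes": [r.nes for r in results],
            "pvalue": [r.pvalue for r in results],
            "direction": [r.direction for r in results],
        }
    )
    df["p_adj"] = bh_adjust(df["pvalue"].to_numpy())
    return df[
        ["set_name", "n_members_used", "effect", "nes", "pvalue", "p_adj", "direction"]
    ]


def enrich_by_region(
    stats_table: pd.DataFrame,
    sets: list[tuple[str, str, list[str]]],
    mode: str = "regression",
    n_perm: int = 1000,
    seed: int = 0,
    min_regions_display: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Enrich each region's signature separately; long region x set table.

    ``min_regions_display`` optionally keeps only sets significant
    (p_adj < 0.05) in at least that many regions.
    """
    frames = []
    for region, sub in stats_table.groupby("region", sort=True):
        signature = dict(zip(sub["gene_id"], sub["zscore"]))
        weights = dict(zip(sub["gene_id"], sub["cv_r2"]))
        df = enrich_catalogue(
            signature, sets, weights if mode == "regression" else None,
            mode=mode, n_perm=n_perm, seed=seed, **kwargs,
        )
        df.insert(0, "region", region)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if min_regions_display > 0 and len(out):
        sig = out.loc[out["p_adj"] < 0.05]
        keep = sig.groupby("set_name").size()
        keep = set(keep[keep >= min_regions_display].index)
        out = out.loc[out["set_name"].isin(keep)].reset_index(drop=True)
    return out


def _stable_hash(text: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")
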