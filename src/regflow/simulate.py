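"""Synthetic inputs with planted ground truth for every pipeline stage.

Generators emulate the statistical structure of the real inputs the
pipeline targets — GWAS summary statistics, per-region TWAS gene tables
with shared cross-region effects, negative-binomial count matrices with
sex-specific and sex-opposite planted effects plus covariates, and
layered signed regulatory networks with planted active/inactive master
regulators — at desk scale, deterministically per seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from regflow.io import SignedNetwork, build_signed_network
from regflow.twas_meta import z_to_p

logger = logging.getLogger("regflow")

GENOME_WIDE_P = 5e-8


@dataclasses.dataclass
class GroundTruth:
    """Planted signals to recover: what each generator actually encoded."""

    signal_genes_up: set[str] = dataclasses.field(default_factory=set)
    signal_genes_down: set[str] = dataclasses.field(default_factory=set)
    enriched_sets: dict[str, str] = dataclasses.field(default_factory=dict)
    planted_de: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    active_tfs: set[str] = dataclasses.field(default_factory=set)
    inactive_tfs: set[str] = dataclasses.field(default_factory=set)
    planted_mrs: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal_genes_up & self.signal_genes_down:
            raise ValueError("up and down signal gene sets overlap")

    def to_json(self, path: str | Path) -> None:
        data = {
            "signal_genes_up": sorted(self.signal_genes_up),
            "signal_genes_down": sorted(self.signal_genes_down),
            "enriched_sets": self.enriched_sets,
            "planted_de": self.planted_de,
            "active_tfs": sorted(self.active_tfs),
            "inactive_tfs": sorted(self.inactive_tfs),
            "planted_mrs": self.planted_mrs,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            signal_genes_up=set(d["signal_genes_up"]),
            signal_genes_down=set(d["signal_genes_down"]),
            enriched_sets=d["enriched_sets"],
            planted_de=d["planted_de"],
            active_tfs=set(d["active_tfs"]),
            inactive_tfs=set(d["inactive_tfs"]),
            planted_mrs=d["planted_mrs"],
        )


def merge_ground_truth(*parts: GroundTruth) -> GroundTruth:
    out = GroundTruth()
    for p in parts:
        out.signal_genes_up |= p.signal_genes_up
        out.signal_genes_down |= p.signal_genes_down
        out.enriched_sets.update(p.enriched_sets)
        for sex, m in p.planted_de.items():
            out.planted_de.setdefault(sex, {}).update(m)
        out.active_tfs |= p.active_tfs
        out.inactive_tfs |= p.inactive_tfs
        out.planted_mrs.update(p.planted_mrs)
    return out


# ---------------------------------------------------------------------------
# gene models and GWAS summary statistics
# ---------------------------------------------------------------------------


def simulate_gene_models(
    n_genes: int,
    seed: int = 0,
    chroms: tuple[str, ...] = ("1", "2", "3"),
    span_bp: int = 10_000_000,
    gene_len: tuple[int, int] = (2_000, 200_000),
) -> pd.DataFrame:
    """Random non-degenerate gene bodies spread over a few chromosomes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        length = int(rng.integers(gene_len[0], gene_len[1]))
        start = int(rng.integers(1, max(2, span_bp - length)))
        rows.append(
            {
                "gene_id": f"G{i:05d}",
                "symbol": f"SYM{i:05d}",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    return pd.DataFrame(rows)


def simulate_gwas(
    genes: pd.DataFrame,
    n_snps: int,
    signal_loci: list[tuple[str, int, float]] | None = None,
    seed: int = 0,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """SNP table with uniform null p-values and planted significant loci.

    Each (gene_id, n_sig_snps, neglog10p_scale) triple places that many
    SNPs inside the gene's +/- window with -log10 p drawn as
    ``-log10(5e-8) + Exponential(mean=scale)`` — an exponential tail
    conditioned on genome-wide significance (memorylessness makes the
    shift equivalent to truncation), so planted SNPs are significant by
    construction. Null SNP p ~ Uniform(0, 1); positions uniform over each
    chromosome's covered span.
    """
    signal_loci = signal_loci or []
    rng = np.random.default_rng(seed)
    n_signal = sum(k for _, k, _ in signal_loci)
    if n_snps < n_signal:
        raise ValueError(f"n_snps={n_snps} < total planted SNPs {n_signal}")
    gene_idx = genes.set_index("gene_id")
    spans = {
        chrom: int(sub["end"].max() + window_bp)
        for chrom, sub in genes.groupby("chrom")
    } or {"1": 10_000_000}

    rows = []
    counter = 0

    def _emit(chrom: str, pos: int, p: float) -> None:
        nonlocal counter
        alleles = rng.choice(list("ACGT"), size=2, replace=False)
        rows.append(
            {
                "snp_id": f"rs{counter:07d}",
                "chrom": chrom,
                "pos": int(pos),
                "allele_ref": alleles[0],
                "allele_alt": alleles[1],
                "pvalue": float(p),
                "effect": float(rng.normal(0.0, 0.1)),
            }
        )
        counter += 1

    floor_neglog = -np.log10(GENOME_WIDE_P)
    for gene_id, n_sig, scale in signal_loci:
        if gene_id not in gene_idx.index:
            raise ValueError(f"signal gene {gene_id!r} absent from gene table")
        g = gene_idx.loc[gene_id]
        lo = max(1, int(g["start"]) - window_bp)
        hi = int(g["end"]) + window_bp
        for _ in range(n_sig):
            neglog = floor_neglog + rng.exponential(scale)
            _emit(str(g["chrom"]), rng.integers(lo, hi + 1), 10.0 ** (-neglog))

    chrom_names = list(spans)
    for _ in range(n_snps - n_signal):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        _emit(chrom, rng.integers(1, spans[chrom] + 1), rng.uniform(0.0, 1.0))

    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "allele_ref", "allele_alt", "pvalue", "effect"],
    )
    return df


# ---------------------------------------------------------------------------
# TWAS gene-statistic tables
# ---------------------------------------------------------------------------

BRAIN_REGIONS = tuple(f"region{i:02d}" for i in range(1, 16))


def simulate_twas_tables(
    n_genes: int,
    n_regions: int = 15,
    n_up: int = 0,
    n_down: int = 0,
    effect_mu: float = 4.0,
    effect_sd: float = 0.5,
    r2_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-region gene z-score tables with shared cross-region effects.

    Signal gene g carries a latent effect mu_g ~ +/-N(effect_mu,
    effect_sd^2) shared across regions (region z = mu_g + N(0, 1));
    null genes are independent N(0, 1) per region. cv-r2 is uniform over
    ``r2_range`` per (gene, region).
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    if effect_mu < 0:
        raise ValueError("effect_mu must be >= 0")
    if not (0 < r2_range[0] <= r2_range[1] <= 1):
        raise ValueError("r2_range must lie within (0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    regions = list(BRAIN_REGIONS[:n_regions]) if n_regions <= 15 else [
        f"region{i:02d}" for i in range(1, n_regions + 1)
    ]
    mu = np.zeros(n_genes)
    mu[:n_up] = rng.normal(effect_mu, effect_sd, size=n_up)
    mu[n_up : n_up + n_down] = -rng.normal(effect_mu, effect_sd, size=n_down)

    frames = []
    for region in regions:
        z = mu + rng.standard_normal(n_genes)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "region": region,
                    "zscore": z,
                    "pvalue": [z_to_p(v) for v in z],
                    "cv_r2": rng.uniform(r2_range[0], r2_range[1], size=n_genes),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    gt = GroundTruth(
        signal_genes_up=set(gene_ids[:n_up]),
        signal_genes_down=set(gene_ids[n_up : n_up + n_down]),
    )
    return table, gt


def simulate_gene_sets(
    gt: GroundTruth,
    all_genes: list[str],
    n_random_sets: int = 20,
    set_size: int = 20,
    seed: int = 0,
) -> tuple[list[tuple[str, str, list[str]]], GroundTruth]:
    """GMT catalogue: one planted set per signal direction + random decoys."""
    rng = np.random.default_rng(seed)
    sets: list[tuple[str, str, list[str]]] = []
    gt_out = GroundTruth(enriched_sets=dict(gt.enriched_sets))
    for name, pool, direction in (
        ("PLANTED_UP", sorted(gt.signal_genes_up), "up"),
        ("PLANTED_DOWN", sorted(gt.signal_genes_down), "down"),
    ):
        if len(pool) >= 2:
            members = list(
                rng.choice(pool, size=min(set_size, len(pool)), replace=False)
            )
            sets.append((name, f"planted {direction}-enriched set", members))
            gt_out.enriched_sets[name] = direction
    for i in range(n_random_sets):
        members = list(rng.choice(all_genes, size=set_size, replace=False))
        sets.append((f"RANDOM{i:03d}", "random decoy set", members))
    return sets, gt_out


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_EFFECTS = {
    # covariate -> (sd of per-gene log2 coefficient, case shift in covariate SD)
    # strong enough that covariate-unaware testing is visibly miscalibrated
    "age": (0.5, 1.2),
    "PMI": (0.2, 0.5),
    "pH": (0.2, -0.5),
    "RIN": (0.2, 0.5),
}

_COVARIATE_DISTS = {
    "age": (45.0, 12.0),
    "PMI": (24.0, 8.0),
    "pH": (6.7, 0.25),
    "RIN": (7.0, 1.0),
}


def simulate_counts(
    n_genes: int,
    samples_per_arm: dict[tuple[str, str], int],
    planted_de: dict[tuple[str, str], float] | None = None,
    baseline_logmean_range: tuple[float, float] = (2.0, 9.0),
    dispersion: float = 0.05,
    libsize_range: tuple[float, float] = (2e6, 4e6),
    covariate_effects: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Negative-binomial counts with sex-specific planted fold changes.

    ``samples_per_arm`` maps (sex, region) -> n per diagnosis arm (the
    stratum gets n cases + n controls). ``planted_de`` maps
    (gene_id, sex) -> log2 fold change applied to cases of that sex in
    every region. Covariates shift per-gene means log-linearly and are
    distributed with a diagnosis-dependent offset, so covariate-unaware
    analysis is measurably miscalibrated.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    planted_de = planted_de or {}
    covariate_effects = (
        DEFAULT_COVARIATE_EFFECTS if covariate_effects is None else covariate_effects
    )
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for gene_id, _sex in planted_de:
        if gene_id not in gene_pos:
            raise ValueError(f"planted DE gene {gene_id!r} out of range")

    base_log2 = rng.uniform(*baseline_logmean_range, size=n_genes)
    rel = 2.0**base_log2
    rel = rel / rel.sum()
    cov_names = list(covariate_effects)
    cov_beta = {
        name: rng.normal(0.0, covariate_effects[name][0], size=n_genes)
        for name in cov_names
    }

    meta_rows = []
    cols: dict[str, np.ndarray] = {}
    for (sex, region), n_arm in sorted(samples_per_arm.items()):
        if n_arm < 1:
            raise ValueError(f"zero samples in arm ({sex}, {region})")
        for diagnosis in ("MDD", "control"):
            for k in range(n_arm):
                sid = f"S_{sex}_{region}_{diagnosis}_{k:02d}"
                covs = {}
                log2shift = np.zeros(n_genes)
                for name in cov_names:
                    mu0, sd0 = _COVARIATE_DISTS.get(name, (0.0, 1.0))
                    shift = covariate_effects[name][1] if diagnosis == "MDD" else 0.0
                    value = rng.normal(mu0 + shift * sd0, sd0)
                    covs[name] = value
                    log2shift += cov_beta[name] * (value - mu0) / sd0
                if diagnosis == "MDD":
                    for (gene_id, de_sex), lfc in planted_de.items():
                        if de_sex == sex:
                            log2shift[gene_pos[gene_id]] += lfc
                lib = rng.uniform(*libsize_range)
                mu = lib * rel * 2.0**log2shift
                lam = rng.gamma(1.0 / dispersion, mu * dispersion)
                cols[sid] = rng.poisson(lam)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "diagnosis": diagnosis,
                        "sex": sex,
                        "region": region,
                        **covs,
                    }
                )
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    gt_de: dict[str, dict[str, float]] = {}
    for (gene_id, sex), lfc in planted_de.items():
        gt_de.setdefault(sex, {})[gene_id] = lfc
    return counts, meta, GroundTruth(planted_de=gt_de)


# ---------------------------------------------------------------------------
# regulatory layer: regulons, signed network, tpm
# ---------------------------------------------------------------------------

_CANDIDATE_ROLES = ("receptor", "ligand", "kinase", "phosphatase")


def simulate_regulatory_layer(
    n_tfs: int = 5,
    targets_per_tf: int = 10,
    n_candidates: int = 6,
    n_intermediates: int = 10,
    planted_mrs: dict[str, str] | None = None,
    max_depth: int = 2,
    n_unexpressed_decoys: int = 0,
    decoy_tf_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SignedNetwork, pd.DataFrame, GroundTruth]:
    """Layered candidate -> intermediate -> TF network with planted MRs.

    TF ground-truth states are drawn first; each planted MR (candidate id
    -> "active"/"inactive") is wired to every TF through its own chain of
    ``max_depth - 1`` intermediates with edge signs chosen so that
    hypothesis x path-sign product reproduces the TF state (a unique
    shortest path per TF). Non-planted candidates connect to a random
    subset of TFs with fully random signs. Regulon target signatures are
    implied by TF state x interaction mode (see
    :func:`signature_from_tf_states`). The tpm table gives every emitted
    node tpm > 1 except ``n_unexpressed_decoys`` extra wired-in decoys at
    tpm 0.5.
    """
    planted_mrs = planted_mrs or {}
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    candidates = [f"C{i:02d}" for i in range(n_candidates)]
    unknown = set(planted_mrs) - set(candidates)
    if unknown:
        raise ValueError(f"planted MR(s) not among candidates: {sorted(unknown)}")
    for hyp in planted_mrs.values():
        if hyp not in ("active", "inactive"):
            raise ValueError(f"MR hypothesis must be active/inactive, got {hyp!r}")
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    if planted_mrs and max_depth < 1:
        raise ValueError("planted MR cannot reach any TF at depth 0")

    roles: dict[str, str] = {t: "TF" for t in tfs}
    for i, c in enumerate(candidates):
        roles[c] = _CANDIDATE_ROLES[i % len(_CANDIDATE_ROLES)]

    tf_state = {t: int(rng.choice([1, -1])) for t in tfs}
    edges: list[tuple[str, int, str]] = []
    inter_counter = 0

    def _new_intermediate() -> str:
        nonlocal inter_counter
        node = f"I{inter_counter:03d}"
        inter_counter += 1
        roles[node] = "other"
        return node

    def _wire_chain(src: str, tf: str, forced_product: int | None) -> None:
        """Chain src -> I ... I -> tf of length max_depth with optional
        forced sign product (unique path: fresh intermediates)."""
        chain = [src] + [_new_intermediate() for _ in range(max_depth - 1)] + [tf]
        signs = [int(rng.choice([1, -1])) for _ in range(len(chain) - 1)]
        if forced_product is not None:
            prod = int(np.prod(signs[:-1])) if len(signs) > 1 else 1
            signs[-1] = forced_product * prod
        for a, b, s in zip(chain[:-1], chain[1:], signs):
            edges.append((a, s, b))

    for mr, hyp in planted_mrs.items():
        h = 1 if hyp == "active" else -1
        for tf in tfs:
            # predicted = h * path_sign must equal tf_state
            _wire_chain(mr, tf, forced_product=h * tf_state[tf])

    n_decoy_tfs = max(1, int(round(decoy_tf_fraction * n_tfs)))
    for c in candidates:
        if c in planted_mrs:
            continue
        chosen = rng.choice(tfs, size=min(n_decoy_tfs, n_tfs), replace=False)
        for tf in chosen:
            _wire_chain(c, tf, forced_product=None)

    # extra free-floating intermediates keep the graph from being purely planted
    for _ in range(max(0, n_intermediates - inter_counter)):
        node = _new_intermediate()
        edges.append((node, int(rng.choice([1, -1])), tfs[int(rng.integers(n_tfs))]))

    # regulons: disjoint target blocks per TF
    reg_rows = []
    for i, tf in enumerate(tfs):
        for j in range(targets_per_tf):
            reg_rows.append(
                {
                    "tf": tf,
                    "target": f"T{i * targets_per_tf + j:04d}",
                    "mode": int(rng.choice([1, -1])),
                    "confidence": float(rng.uniform(0.5, 1.0)),
                }
            )
    regulons = pd.DataFrame(reg_rows, columns=["tf", "target", "mode", "confidence"])

    unexpressed = []
    for i in range(n_unexpressed_decoys):
        node = f"X{i:02d}"
        roles[node] = _CANDIDATE_ROLES[i % len(_CANDIDATE_ROLES)]
        edges.append((node, int(rng.choice([1, -1])), tfs[int(rng.integers(n_tfs))]))
        unexpressed.append(node)

    network = build_signed_network(edges, roles)
    tpm_rows = [
        {"gene_id": n, "tpm": 0.5 if n in unexpressed else float(rng.uniform(2.0, 50.0))}
        for n in sorted(network.nodes())
    ]
    tpm = pd.DataFrame(tpm_rows, columns=["gene_id", "tpm"])

    gt = GroundTruth(
        active_tfs={t for t, s in tf_state.items() if s == 1},
        inactive_tfs={t for t, s in tf_state.items() if s == -1},
        planted_mrs=dict(planted_mrs),
    )
    if planted_mrs and max_depth > 0:
        # every planted MR reaches every TF by construction; sanity-check one
        from regflow.regulators import signed_shortest_paths

        for mr in planted_mrs:
            reach = signed_shortest_paths(network, mr, max_len=max_depth)
            if not any(t in reach for t in tfs):
                raise ValueError(f"planted MR {mr!r} has no path to any TF")
    return regulons, network, tpm, gt


def signature_from_tf_states(
    regulons: pd.DataFrame,
    gt: GroundTruth,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    n_background: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Transcription signature implied by planted TF states.

    Targets of a TF in state s shift by s x mode x effect; background
    genes are pure noise.
    """
    rng = np.random.default_rng(seed)
    state = {t: 1 for t in gt.active_tfs} | {t: -1 for t in gt.inactive_tfs}
    signature: dict[str, float] = {}
    for row in regulons.itertuples():
        s = state.get(row.tf, 0)
        signature[row.target] = float(
            s * row.mode * effect + rng.normal(0.0, noise_sd)
        )
    for i in range(n_background):
        signature[f"BG{i:04d}"] = float(rng.normal(0.0, noise_sd))
    return signature
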