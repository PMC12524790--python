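"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are tab-separated UTF-8 with a header row. Genomic
coordinates are 1-based inclusive throughout. Missing values are encoded
as "NA"; readers drop rows with unparseable values in required numeric
columns and log how many were dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("regflow")

SUMMARY_STAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "allele_ref",
    "allele_alt",
    "pvalue",
    "effect",
]

GENE_MODEL_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]

GENE_STAT_COLUMNS = ["gene_id", "region", "zscore", "pvalue", "cv_r2"]

REGULON_COLUMNS = ["tf", "target", "mode", "confidence"]

#: accepted edge-sign tokens, case-insensitive, normalised to +1 / -1
_SIGN_TOKENS = {
    "+1": 1,
    "1": 1,
    "+": 1,
    "activate": 1,
    "activates": 1,
    "activating": 1,
    "-1": -1,
    "-": -1,
    "−1": -1,  # unicode minus
    "inhibit": -1,
    "inhibits": -1,
    "inhibiting": -1,
}

NODE_ROLES = {"TF", "kinase", "phosphatase", "receptor", "ligand", "other"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV into a typed table.

    Required columns: snp_id, chrom, pos, allele_ref, allele_alt, pvalue,
    effect. Rows whose p-value does not parse to a number in (0, 1] are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[SUMMARY_STAT_COLUMNS].copy()
    n_in = len(df)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    df["effect"] = pd.to_numeric(df["effect"], errors="coerce")
    ok = (
        df["pvalue"].notna()
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & df["pos"].notna()
        & (df["pos"] >= 1)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("read_summary_stats: dropped %d/%d unparseable rows", n_dropped, n_in)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{path}: duplicate snp_id {dup!r}")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a gene-model TSV (1-based inclusive start/end)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[GENE_MODEL_COLUMNS].copy()
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(int)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(int)
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise FormatError(f"{path}: start > end for gene {bad!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    return df


def write_gene_models(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into (name, description, members) triples.

    Duplicate members within a set are deduplicated (first occurrence kept);
    a line with fewer than three fields is an error.
    """
    out: list[tuple[str, str, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            out.append((name, desc, members))
    return out


def write_gmt(sets: Iterable[tuple[str, str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# signed network
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SignedNetwork:
    """Directed graph with edge signs in {+1, -1} and node roles.

    ``graph`` is a :class:`networkx.MultiDiGraph`; each edge carries a
    ``sign`` attribute. ``roles`` maps node -> role. ``conflicts`` lists
    (source, target) pairs present with both signs.
    """

    graph: nx.MultiDiGraph
    roles: dict[str, str]
    conflicts: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def has_conflicts(self) -> bool:
        return bool(self.conflicts)

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)]

    def nodes_with_role(self, roles: set[str]) -> list[str]:
        return [n for n in self.graph.nodes if self.roles.get(n, "other") in roles]


def parse_sign(token: str | int, *, row: int | None = None) -> int:
    key = str(token).strip().lower()
    if key not in _SIGN_TOKENS:
        where = f" at row {row}" if row is not None else ""
        raise FormatError(f"unrecognised edge sign {token!r}{where}")
    return _SIGN_TOKENS[key]


def build_signed_network(
    edges: Iterable[tuple[str, int, str]], roles: Mapping[str, str]
) -> SignedNetwork:
    """Assemble a SignedNetwork from (source, sign, target) triples.

    Parallel duplicates with identical sign are collapsed; contradictory
    duplicates (same pair, both signs) are both retained and flagged.
    """
    seen: dict[tuple[str, str], set[int]] = {}
    g = nx.MultiDiGraph()
    for src, sign, dst in edges:
        if sign not in (1, -1):
            raise FormatError(f"edge sign must be +1/-1, got {sign!r}")
        signs = seen.setdefault((src, dst), set())
        if sign in signs:
            continue
        signs.add(sign)
        g.add_edge(src, dst, sign=sign)
    for node in roles:
        if node not in g:
            g.add_node(node)
    conflicts = sorted(pair for pair, signs in seen.items() if len(signs) == 2)
    if conflicts:
        logger.warning("signed network: %d contradictory edge pairs flagged", len(conflicts))
    role_map = {n: roles.get(n, "other") for n in g.nodes}
    return SignedNetwork(graph=g, roles=role_map, conflicts=conflicts)


def read_signed_network(edge_path: str | Path, node_role_path: str | Path) -> SignedNetwork:
    """Read SIF-like edge TSV (source, sign, target) plus a node-role TSV."""
    edf = pd.read_csv(edge_path, sep="\t", dtype=str, comment="#")
    for col in ("source", "sign", "target"):
        if col not in edf.columns:
            raise FormatError(f"{edge_path}: missing required column {col!r}")
    triples = [
        (row.source, parse_sign(row.sign, row=i + 2), row.target)
        for i, row in enumerate(edf.itertuples())
    ]
    rdf = pd.read_csv(node_role_path, sep="\t", dtype=str, comment="#")
    for col in ("node", "role"):
        if col not in rdf.columns:
            raise FormatError(f"{node_role_path}: missing required column {col!r}")
    roles = {}
    for i, row in enumerate(rdf.itertuples()):
        if row.role not in NODE_ROLES:
            raise FormatError(f"{node_role_path}: row {i + 2}: unknown role {row.role!r}")
        roles[row.node] = row.role
    return build_signed_network(triples, roles)


def write_signed_network(
    net: SignedNetwork, edge_path: str | Path, node_role_path: str | Path
) -> None:
    rows = [
        {"source": u, "sign": s, "target": v} for u, v, s in sorted(net.edges())
    ]
    pd.DataFrame(rows, columns=["source", "sign", "target"]).to_csv(
        edge_path, sep="\t", index=False
    )
    role_rows = [{"node": n, "role": r} for n, r in sorted(net.roles.items())]
    pd.DataFrame(role_rows, columns=["node", "role"]).to_csv(
        node_role_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# regulons / gene stats / generic tables
# ---------------------------------------------------------------------------


def read_regulons(path: str | Path) -> pd.DataFrame:
    """Read a TF-regulon TSV: tf, target, mode (+1/-1 vocab), confidence."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REGULON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[REGULON_COLUMNS].copy()
    df["mode"] = [parse_sign(m, row=i + 2) for i, m in enumerate(df["mode"])]
    df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
    if ((df["confidence"] <= 0) | (df["confidence"] > 1)).any():
        raise FormatError(f"{path}: regulon confidence must lie in (0, 1]")
    if df.duplicated(subset=["tf", "target"]).any():
        raise FormatError(f"{path}: duplicate (tf, target) rows")
    return df


def write_regulons(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    """Read a per-(gene, region) TWAS statistics TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "region": str}, comment="#")
    missing = [c for c in GENE_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[GENE_STAT_COLUMNS].copy()
    bad = (df["pvalue"] <= 0) | (df["pvalue"] > 1)
    if bad.any():
        raise FormatError(f"{path}: pvalue outside (0, 1]")
    return df


def write_gene_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df.astype(int)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "diagnosis", "sex"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    return df


def read_tpm(path: str | Path) -> pd.DataFrame:
    """Read a tpm table: gene_id, then one column per region (or 'tpm')."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'gene_id'")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration & manifest
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide thresholds and parameters (YAML-serialisable)."""

    snp_p: float = 5e-8
    window_bp: int = 10_000
    gene_alpha: float = 0.05
    consistency_alpha: float = 0.05
    min_regions: int = 3
    meta_alpha: float = 0.05
    deg_soft_lfc: float = 0.5
    deg_soft_p: float = 0.05
    deg_strict_lfc: float = 1.0
    deg_strict_p: float = 0.05
    min_cpm: float = 1.0
    tpm_min: float = 1.0
    tf_alpha: float = 0.05
    max_path_len: int = 5
    min_score: int = 2
    min_set_size: int = 5
    max_set_size: int = 500
    n_perm: int = 1000
    seed: int = 0
    paths: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = [
            "snp_p", "gene_alpha", "consistency_alpha", "meta_alpha",
            "deg_soft_lfc", "deg_soft_p", "deg_strict_lfc", "deg_strict_p",
            "min_cpm", "tpm_min", "tf_alpha",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")
        if self.min_regions < 1:
            raise ValueError("RunConfig.min_regions must be >= 1")
        if self.max_path_len < 1:
            raise ValueError("RunConfig.max_path_len must be >= 1")
        if self.window_bp < 0:
            raise ValueError("RunConfig.window_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    *,
    command: str,
    config: RunConfig,
    inputs: Mapping[str, str],
    outputs: Mapping[str, str],
) -> None:
    """Write a JSON run-manifest sufficient to re-execute the stage."""
    import regflow

    manifest = {
        "command": command,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": dict(inputs),
        "outputs": dict(outputs),
        "versions": {"regflow": regflow.__version__},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
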