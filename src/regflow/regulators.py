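"""Stage 5: master-regulator inference on signed signaling networks.

TF activity is scored from regulons against a transcription signature
with a permutation null; the signed network is pruned to the expressed
gene set; each candidate regulator (receptor, ligand, kinase,
phosphatase) is scored by whether the sign products of its shortest
paths to TFs, under an "active" or "inactive" hypothesis, explain the
observed TF states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from regflow.io import SignedNetwork, build_signed_network

logger = logging.getLogger("regflow")

DEFAULT_CANDIDATE_ROLES = {"receptor", "ligand", "kinase", "phosphatase"}
MIN_REGULON_SIZE = 5


# ---------------------------------------------------------------------------
# TF activity
# ---------------------------------------------------------------------------


def _regulon_map(regulons: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {tf: sub for tf, sub in regulons.groupby("tf", sort=True)}


def _tf_score(x: np.ndarray, mode: np.ndarray, lik: np.ndarray) -> float:
    denom = np.sqrt((lik**2).sum())
    if denom == 0:
        return 0.0
    return float((mode * lik * x).sum() / denom)


def tf_activity(
    signature: dict[str, float],
    regulons: pd.DataFrame,
    weights: dict[str, float] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    tf_alpha: float = 0.05,
    min_regulon_size: int = MIN_REGULON_SIZE,
) -> pd.DataFrame:
    """Score each TF's activity against a signed transcription signature.

    score(t) = sum_j mode_j * likelihood_j * w_j * x_j
               / sqrt(sum_j (likelihood_j * w_j)^2)
    over regulon targets present in the signature. The null permutes
    signature values over genes; state is "active" when p < tf_alpha with
    positive NES, "inactive" when negative, "ns" otherwise.
    """
    genes = np.array(list(signature))
    values = np.array([signature[g] for g in genes], dtype=float)
    w_map = weights or {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(values) for _ in range(n_perm)]) if n_perm else None

    rows = []
    for tf, sub in _regulon_map(regulons).items():
        present = sub.loc[sub["target"].isin(gene_pos)]
        if len(present) < min_regulon_size:
            logger.warning(
                "tf_activity: regulon %r has %d usable targets (< %d), skipped",
                tf, len(present), min_regulon_size,
            )
            continue
        idx = np.array([gene_pos[t] for t in present["target"]])
        mode = present["mode"].to_numpy(dtype=float)
        lik = present["confidence"].to_numpy(dtype=float) * np.array(
            [w_map.get(t, 1.0) for t in present["target"]]
        )
        score = _tf_score(values[idx], mode, lik)
        null = np.array([_tf_score(p[idx], mode, lik) for p in perms])
        pvalue = (int((np.abs(null) >= abs(score) - 1e-12).sum()) + 1) / (n_perm + 1)
        sd = float(null.std(ddof=0))
        nes = float((score - null.mean()) / sd) if sd > 0 else 0.0
        if pvalue < tf_alpha and nes > 0:
            state = "active"
        elif pvalue < tf_alpha and nes < 0:
            state = "inactive"
        else:
            state = "ns"
        rows.append(
            {
                "tf_id": tf,
                "score": score,
                "nes": nes,
                "pvalue": float(pvalue),
                "state": state,
            }
        )
    return pd.DataFrame(rows, columns=["tf_id", "score", "nes", "pvalue", "state"])


def tf_states_from_activity(activity: pd.DataFrame) -> dict[str, int]:
    """Observed TF directions {+1 active, -1 inactive}; ns TFs are 0."""
    mapping = {"active": 1, "inactive": -1, "ns": 0}
    return {t: mapping[s] for t, s in zip(activity["tf_id"], activity["state"])}


# ---------------------------------------------------------------------------
# network pruning and signed shortest paths
# ---------------------------------------------------------------------------


def prune_network(network: SignedNetwork, expressed: set[str]) -> SignedNetwork:
    """Subgraph induced on the expressed node set."""
    keep = [n for n in network.graph.nodes if n in expressed]
    sub = network.graph.subgraph(keep)
    edges = [(u, d["sign"], v) for u, v, d in sub.edges(data=True)]
    roles = {n: network.roles[n] for n in keep}
    return build_signed_network(edges, roles)


def signed_shortest_paths(
    network: SignedNetwork, source: str, max_len: int = 5
) -> dict[str, tuple[int, int]]:
    """BFS to depth ``max_len`` with sign-consensus propagation.

    Returns node -> (distance, path_sign) where path_sign is the product
    of edge signs if every shortest path from source to the node agrees,
    else 0 (ambiguous). Self-loops never contribute; the source itself is
    not reported.
    """
    g = network.graph
    if source not in g:
        raise KeyError(f"source {source!r} not in network")
    dist: dict[str, int] = {source: 0}
    signs: dict[str, set[int]] = {source: {1}}
    frontier = [source]
    for d in range(1, max_len + 1):
        nxt: list[str] = []
        layer_signs: dict[str, set[int]] = {}
        for u in frontier:
            for _, v, data in g.out_edges(u, data=True):
                if v == u:
                    continue  # self-loop
                if v in dist and dist[v] < d:
                    continue
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
                acc = layer_signs.setdefault(v, set())
                acc.update(s * data["sign"] for s in signs[u])
        for v, s in layer_signs.items():
            signs[v] = s
        frontier = nxt
        if not frontier:
            break
    out = {}
    for node, d in dist.items():
        if node == source:
            continue
        s = signs[node]
        out[node] = (d, next(iter(s)) if len(s) == 1 else 0)
    return out


# ---------------------------------------------------------------------------
# causal agreement scoring
# ---------------------------------------------------------------------------


@dataclass
class RegulatorScore:
    score: int
    n_correct: int
    n_incorrect: int
    n_ambiguous: int
    n_unexplained: int


def score_regulator(
    path_signs: dict[str, int],
    tf_states: dict[str, int],
    hypothesis: int,
) -> RegulatorScore:
    """Agreement between hypothesised downstream effects and TF states.

    For each reachable TF: predicted = hypothesis * path_sign; a match
    with the observed state counts as correct, the opposite as incorrect.
    Ambiguous paths (sign 0) and unobserved TF states (0) are tallied
    separately and never enter the score.
    """
    if hypothesis not in (1, -1):
        raise ValueError("hypothesis must be +1 or -1")
    n_correct = n_incorrect = n_ambiguous = n_unexplained = 0
    for tf, observed in tf_states.items():
        if tf not in path_signs:
            continue
        sign = path_signs[tf]
        if sign == 0:
            n_ambiguous += 1
            continue
        if observed == 0:
            n_unexplained += 1
            continue
        predicted = hypothesis * sign
        if predicted == observed:
            n_correct += 1
        else:
            n_incorrect += 1
    return RegulatorScore(
        score=n_correct - n_incorrect,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_ambiguous=n_ambiguous,
        n_unexplained=n_unexplained,
    )


MR_COLUMNS = [
    "regulator_id", "role", "hypothesis", "score", "n_correct", "n_incorrect",
    "n_ambiguous", "n_unexplained", "tie", "twas_support", "dge_support", "retained",
]


def find_master_regulators(
    network: SignedNetwork,
    tf_states: dict[str, int],
    candidate_roles: set[str] | None = None,
    max_len: int = 5,
    twas_genes: set[str] | None = None,
    deg_genes: set[str] | None = None,
    min_score: int = 2,
    require_both: bool = False,
) -> pd.DataFrame:
    """Rank candidate regulators by causal agreement with observed TFs.

    Both hypotheses (active = +1, inactive = -1) are scored per candidate
    and the better one kept (an exact tie reports both rows, flagged).
    Ranking is by score desc, then n_correct desc, then regulator id.
    A regulator is retained iff score >= min_score and its gene has
    TWAS and/or DE support (OR by default; AND with ``require_both``).
    """
    if not tf_states:
        raise ValueError("tf_states is empty")
    candidate_roles = candidate_roles or DEFAULT_CANDIDATE_ROLES
    twas_genes = twas_genes or set()
    deg_genes = deg_genes or set()
    rows = []
    for node in sorted(network.nodes_with_role(candidate_roles)):
        paths = signed_shortest_paths(network, node, max_len)
        tf_paths = {t: s for t, (_, s) in paths.items() if t in tf_states}
        scored = {h: score_regulator(tf_paths, tf_states, h) for h in (1, -1)}
        if scored[1].score > scored[-1].score:
            best = [(1, scored[1])]
        elif scored[-1].score > scored[1].score:
            best = [(-1, scored[-1])]
        else:
            best = [(1, scored[1]), (-1, scored[-1])]
        for hyp, sc in best:
            support_t = node in twas_genes
            support_d = node in deg_genes
            supported = (support_t and support_d) if require_both else (support_t or support_d)
            rows.append(
                {
                    "regulator_id": node,
                    "role": network.roles.get(node, "other"),
                    "hypothesis": "active" if hyp == 1 else "inactive",
                    "score": sc.score,
                    "n_correct": sc.n_correct,
                    "n_incorrect": sc.n_incorrect,
                    "n_ambiguous": sc.n_ambiguous,
                    "n_unexplained": sc.n_unexplained,
                    "tie": len(best) == 2,
                    "twas_support": support_t,
                    "dge_support": support_d,
                    "retained": supported and sc.score >= min_score,
                }
            )
    out = pd.DataFrame(rows, columns=MR_COLUMNS)
    if len(out):
        out = out.sort_values(
            by=["score", "n_correct", "regulator_id"],
            ascending=[False, False, True],
            kind="stable",
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# cross-stratum orchestration
# ---------------------------------------------------------------------------


def run_regulators(
    strata_signatures: dict[str, dict[str, float]],
    regulons: pd.DataFrame,
    network: SignedNetwork,
    expressed_by_stratum: dict[str, set[str]],
    twas_genes: set[str] | None = None,
    deg_genes: set[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    tf_alpha: float = 0.05,
    max_len: int = 5,
    min_score: int = 2,
    require_both: bool = False,
    weights_by_stratum: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum TF activity + MR inference and a state matrix.

    ``expressed_by_stratum`` gives the expressed node set used to prune
    the network in each stratum (tpm > 1 for TWAS strata, filtered count
    gene lists for transcriptomic strata). The state matrix encodes, per
    regulator x stratum: "active"/"inactive" when retained, "candidate"
    when scored but not retained, "" when absent.
    """
    long_frames = []
    matrix: dict[str, dict[str, str]] = {}
    for i, (stratum, signature) in enumerate(sorted(strata_signatures.items())):
        expressed = expressed_by_stratum.get(stratum, set(network.nodes()))
        pruned = prune_network(network, set(expressed))
        w = (weights_by_stratum or {}).get(stratum)
        activity = tf_activity(
            signature, regulons, w, n_perm=n_perm, seed=seed + i, tf_alpha=tf_alpha
        )
        states = {t: s for t, s in tf_states_from_activity(activity).items() if s != 0}
        if not states:
            logger.warning("run_regulators: stratum %r has no significant TFs, skipped", stratum)
            continue
        mr = find_master_regulators(
            pruned, states, max_len=max_len,
            twas_genes=twas_genes, deg_genes=deg_genes,
            min_score=min_score, require_both=require_both,
        )
        mr.insert(0, "stratum", stratum)
        long_frames.append(mr)
        for row in mr.itertuples():
            cell = row.hypothesis if row.retained else ("candidate" if row.score > 0 else "")
            prev = matrix.setdefault(row.regulator_id, {})
            # on hypothesis ties keep the first (already rank-ordered)
            if stratum not in prev or prev[stratum] == "":
                prev[stratum] = cell
    long_table = (
        pd.concat(long_frames, ignore_index=True)
        if long_frames
        else pd.DataFrame(columns=["stratum", *MR_COLUMNS])
    )
    strata = sorted(strata_signatures)
    mat = pd.DataFrame(
        [
            {"regulator_id": reg, **{s: matrix[reg].get(s, "") for s in strata}}
            for reg in sorted(matrix)
        ],
        columns=["regulator_id", *strata],
    )
    return long_table, mat
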