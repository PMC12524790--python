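"""Independent reference implementations used only to check the package.

Each oracle deliberately avoids the code path (and where possible the
library calls) of the implementation it validates.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# chi-square upper tail via series / continued fraction (no scipy)
# ---------------------------------------------------------------------------


def _gamma_series_p(a: float, x: float) -> float:
    """Regularised lower incomplete gamma P(a, x) by power series."""
    term = 1.0 / a
    total = term
    n = a
    for _ in range(10_000):
        n += 1.0
        term *= x / n
        total += term
        if abs(term) < abs(total) * 1e-16:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))

def _gamma_contfrac_q(a: float, x: float) -> float:
    """Regularised upper incomplete gamma Q(a, x) by continued fraction."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 10_000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return h * math.exp(-x + a * math.log(x) - math.lgamma(a))


def chi2_sf(stat: float, df: float) -> float:
    """Upper tail of chi-square(df) at stat."""
    if stat <= 0:
        return 1.0
    a = df / 2.0
    x = stat / 2.0
    if x < a + 1.0:
        return 1.0 - _gamma_series_p(a, x)
    return _gamma_contfrac_q(a, x)


# ---------------------------------------------------------------------------
# BH: smallest q at which each element is rejected
# ---------------------------------------------------------------------------


def bh_rejections(pvalues: list[float], q: float) -> list[bool]:
    """Step-up BH rejection set at level q (direct definition)."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    r = 0
    for rank, i in enumerate(indexed, start=1):
        # epsilon absorbs float associativity between q*k/m and p*m/k routes
        if pvalues[i] <= q * rank / m + 1e-12:
            r = rank
    cutoff = pvalues[indexed[r - 1]] if r else -1.0
    return [p <= cutoff if r else False for p in pvalues]


def bh_adjusted_oracle(pvalues: list[float]) -> list[float]:
    """Adjusted p_i = smallest q in the finite candidate grid at which
    element i is rejected by step-up BH."""
    m = len(pvalues)
    candidates = sorted({min(1.0, p * m / k) for p in pvalues for k in range(1, m + 1)})
    out = []
    for i in range(m):
        adj = 1.0
        for q in candidates:
            if bh_rejections(pvalues, q)[i]:
                adj = q
                break
        out.append(adj)
    return out


# ---------------------------------------------------------------------------
# exhaustive signed-shortest-path enumeration
# ---------------------------------------------------------------------------


def enumerate_signed_paths(
    edges: list[tuple[str, int, str]], source: str, max_len: int
) -> dict[str, tuple[int, int]]:
    """All simple directed paths up to max_len by DFS; per target the
    minimal length and consensus sign (0 when min-length paths disagree)."""
    adj: dict[str, list[tuple[str, int]]] = {}
    for u, s, v in edges:
        if u != v:
            adj.setdefault(u, []).append((v, s))
    found: dict[str, list[tuple[int, int]]] = {}

    def dfs(node: str, visited: set[str], depth: int, sign: int) -> None:
        if depth == max_len:
            return
        for nxt, s in adj.get(node, []):
            if nxt in visited:
                continue
            found.setdefault(nxt, []).append((depth + 1, sign * s))
            dfs(nxt, visited | {nxt}, depth + 1, sign * s)

    dfs(source, {source}, 0, 1)
    out = {}
    for node, hits in found.items():
        dmin = min(d for d, _ in hits)
        signs = {s for d, s in hits if d == dmin}
        out[node] = (dmin, signs.pop() if len(signs) == 1 else 0)
    return out


# ---------------------------------------------------------------------------
# reference TMM (plain-loop recode of the same trimming contract)
# ---------------------------------------------------------------------------


def _quantile(sorted_vals: list[float], q: float) -> float:
    """Linear-interpolation quantile on a pre-sorted list."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def tmm_reference(counts: list[list[int]], trim_m: float = 0.30, trim_a: float = 0.05):
    """TMM factors for a genes x samples integer matrix (list of rows)."""
    n_genes = len(counts)
    n_samples = len(counts[0])
    lib = [sum(counts[g][j] for g in range(n_genes)) for j in range(n_samples)]
    uq = []
    for j in range(n_samples):
        pos = sorted(
            counts[g][j] / lib[j] * 1e6 for g in range(n_genes) if counts[g][j] > 0
        )
        uq.append(_quantile(pos, 0.75) if pos else 0.0)
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(uq[j] - mean_uq))

    factors = [1.0] * n_samples
    for j in range(n_samples):
        if j == ref:
            continue
        m_vals, a_vals, v_vals = [], [], []
        for g in range(n_genes):
            o, r = counts[g][j], counts[g][ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * math.log2(po * pr))
                v_vals.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not m_vals:
            continue
        if max(m_vals) - min(m_vals) < 1e-10:
            factors[j] = 2.0 ** m_vals[0]
            continue
        ms = sorted(m_vals)
        as_ = sorted(a_vals)
        m_lo, m_hi = _quantile(ms, trim_m), _quantile(ms, 1 - trim_m)
        a_lo, a_hi = _quantile(as_, trim_a), _quantile(as_, 1 - trim_a)
        num = den = 0.0
        kept = 0
        for m, a, v in zip(m_vals, a_vals, v_vals):
            if m_lo <= m <= m_hi and a_lo <= a <= a_hi:
                num += m / v
                den += 1.0 / v
                kept += 1
        if kept:
            factors[j] = 2.0 ** (num / den)
    log_gm = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_gm) for f in factors]
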