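"""Independent brute-force / closed-form oracles used by the tests.

Everything here is deliberately naive (O(n*m) scans, exact rational
arithmetic, textbook formulas) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


# ---------------------------------------------------------------- intervals
def brute_union(segments: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of [s, e) segments by per-bp membership (bookended fuse)."""
    if not segments:
        return []
    lo = min(s for s, _ in segments)
    hi = max(e for _, e in segments)
    covered = [False] * (hi - lo)
    for s, e in segments:
        for i in range(s - lo, e - lo):
            covered[i] = True
    out = []
    i = 0
    n = hi - lo
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            out.append((i + lo, j + lo))
            i = j
        else:
            i += 1
    return out


def brute_overlap_pairs(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> int:
    """Number of (a, b) pairs sharing >= 1 bp."""
    n = 0
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca == cb and sa < eb and sb < ea:
                n += 1
    return n


def brute_best_copy(
    locus: tuple[str, int, int], copies: list[tuple[str, str, int, int]]
) -> str | None:
    """copy_id with the largest overlap; ties to smallest copy_id.

    copies: (copy_id, chrom, start, end).
    """
    best = None
    for cid, chrom, s, e in copies:
        if chrom != locus[0]:
            continue
        ov = max(0, min(e, locus[2]) - max(s, locus[1]))
        if ov <= 0:
            continue
        key = (-ov, cid)
        if best is None or key < best[0]:
            best = (key, cid)
    return best[1] if best else None


# ---------------------------------------------------------------- statistics
def exact_binom_upper(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), exact rational enumeration."""
    if k <= 0:
        return 1.0
    pf = Fraction(p)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def exact_binom_lower(k: int, n: int, p: float) -> float:
    """P(X <= k), exact."""
    pf = Fraction(p)
    total = Fraction(0)
    for i in range(0, min(k, n) + 1):
        total += math.comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def hypergeom_pmf_frac(k: int, N: int, K: int, n: int) -> Fraction:
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def exact_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact enumeration."""
    total = sum(
        (hypergeom_pmf_frac(i, N, K, n) for i in range(max(k, 0), min(K, n) + 1)),
        Fraction(0),
    )
    return float(total)


def exact_fisher_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric pmfs <= observed pmf."""
    a, b = table[0]
    c, d = table[1]
    N = a + b + c + d
    K = a + b  # row 1 total
    n = a + c  # col 1 total
    obs = hypergeom_pmf_frac(a, N, K, n)
    total = Fraction(0)
    for k in range(max(0, n + K - N), min(K, n) + 1):
        pmf = hypergeom_pmf_frac(k, N, K, n)
        if pmf <= obs:
            total += pmf
    return float(total)


def welch_t_p(a: list[float], b: list[float]) -> tuple[float, float]:
    """Welch unequal-variance t statistic and two-sided p (textbook formulas)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


def paired_t_p(a: list[float], b: list[float]) -> tuple[float, float]:
    """Paired t statistic and two-sided p (textbook formula)."""
    from scipy.stats import t as tdist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    md = sum(d) / n
    sd = math.sqrt(sum((x - md) ** 2 for x in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    return t, 2 * tdist.sf(abs(t), n - 1)
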