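"""Count statistics implemented from first principles.

Everything the pipeline reports rests on the hypergeometric law: the
upper-tail overrepresentation p-value behind gene-set enrichment, the
conditional 2x2 Fisher exact test, Benjamini-Hochberg FDR control across
the tested sets, and the simple proportions and odds ratios used for
contingency summaries.

The hypergeometric tail is computed with exact integer arithmetic for
population sizes up to 10,000 and in log-gamma space beyond that.  The
two-sided Fisher convention is the minimum-likelihood rule (sum the
probabilities of all tables with the same margins that are no more likely
than the observed one, with a 1 + 1e-7 relative tolerance on "no more
likely") — the dominant convention in statistical software; two-sided
definitions genuinely differ, so it is stated here explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

_EXACT_N_LIMIT = 10_000
_FISHER_RELTOL = 1 + 1e-7


# ----------------------------------------------------------------------
# hypergeometric
# ----------------------------------------------------------------------

def _check_hypergeom_args(k: int, K: int, n: int, N: int) -> None:
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")


def hypergeom_point(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n)."""
    _check_hypergeom_args(k, K, n, N)
    if n - k > N - K:
        return 0.0
    if N <= _EXACT_N_LIMIT:
        return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
    return math.exp(
        _lchoose(K, k) + _lchoose(N - K, n - k) - _lchoose(N, n)
    )


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k): draw n from a population of N containing K successes.

    Exact (integer arithmetic, one final division) for N <= 10,000;
    log-space summation beyond that.
    """
    _check_hypergeom_args(k, K, n, N)
    hi = min(K, n)
    if k <= max(0, n - (N - K)):
        return 1.0
    if N <= _EXACT_N_LIMIT:
        num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, hi + 1))
        return num / math.comb(N, n)
    lse = None
    ld = _lchoose(N, n)
    for j in range(k, hi + 1):
        lt = _lchoose(K, j) + _lchoose(N - K, n - j) - ld
        lse = lt if lse is None else max(lse, lt) + math.log1p(math.exp(-abs(lse - lt)))
    return min(1.0, math.exp(lse))


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, original order restored.

    q_(i) = min over j >= i of m * p_(j) / j, clipped at 1.
    """
    p = list(p_values)
    for x in p:
        if not 0 <= x <= 1:
            raise ValueError(f"p-value {x} outside [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


# ----------------------------------------------------------------------
# overrepresentation analysis
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int                # overlap
    K: int                # set size within the universe
    n: int                # candidate count
    N: int                # universe size
    p_value: float
    q_value: float
    fold_enrichment: float


def ora(
    candidates: Iterable[str],
    sets: Dict[str, Iterable[str]],
    universe: Iterable[str],
) -> List[EnrichmentResult]:
    """Hypergeometric overrepresentation of a candidate gene list.

    Candidates outside the universe are logged out (dropped); set members
    are intersected with the universe before K is computed.  BH-FDR is
    applied across all sets tested in this one call.  Rows are sorted by
    p ascending, ties broken by set name.
    """
    import logging

    logger = logging.getLogger(__name__)
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    cand = {g.upper() for g in candidates}
    outside = cand - uni
    if outside:
        logger.warning(
            "%d candidate gene(s) outside the universe dropped: %s",
            len(outside), ", ".join(sorted(outside)[:5]),
        )
        cand &= uni
    N, n = len(uni), len(cand)
    rows = []
    for name, members in sets.items():
        mem = {g.upper() for g in members} & uni
        K = len(mem)
        k = len(mem & cand)
        p = hypergeom_upper_tail(k, K, n, N) if K and n else 1.0
        fold = (k / n) / (K / N) if K and n else 0.0
        rows.append((name, k, K, p, fold))
    qs = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(name, k, K, n, N, p, q, fold)
        for (name, k, K, p, fold), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def write_enrichment_tsv(results: List[EnrichmentResult], path) -> None:
    from pathlib import Path

    header = ("set_name", "overlap_k", "set_size_K", "candidates_n",
              "universe_N", "p_value", "q_value", "fold_enrichment")
    lines = ["\t".join(header)]
    for r in results:
        lines.append("\t".join((
            r.set_name, str(r.k), str(r.K), str(r.n), str(r.N),
            f"{r.p_value:.6g}", f"{r.q_value:.6g}", f"{r.fold_enrichment:.6g}",
        )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# 2x2 tables
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwo:
    """Contingency table [[a, b], [c, d]]; rows = group, cols = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def fisher_exact_2x2(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins.

    Conditional on the margins, the cell `a` determines the table; its
    law is hypergeometric.  The two-sided p sums the point probabilities
    of every table at least as extreme (no more likely, within a 1+1e-7
    relative factor) as the observed one.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # exact integer point weights: comb(r1, a) * comb(r2, c1 - a)
    weights = [math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)]
    total = sum(weights)
    observed = weights[t.a - lo]
    cutoff = observed * _FISHER_RELTOL
    num = sum(w for w in weights if w <= cutoff)
    return min(1.0, num / total)


def odds_ratio(t: TwoByTwo, haldane: bool = False) -> float:
    """(a*d)/(b*c); with ``haldane`` 0.5 is added to every cell when any is 0.

    Without the correction a zero in b or c raises, and a zero in a or d
    returns 0.0.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        raise ZeroDivisionError(
            "odds ratio undefined (b*c = 0); use haldane=True for the corrected estimate"
        )
    return (a * d) / (b * c)


def proportion_percent(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    from decimal import ROUND_HALF_UP, Decimal

    pct = Decimal(100) * Decimal(count) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))
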