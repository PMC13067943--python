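"""Independent reference implementations used as test oracles.

Everything here is written rule-by-rule from the definitions, deliberately
avoiding the package's vectorized code paths (and scipy shortcuts where the
point is to check them).
"""

from __future__ import annotations

import itertools
import math


def classify_one(rec: dict, cfg) -> tuple[str, bool]:
    """Scalar gating reference: decision order written out rule by rule.

    ``rec`` holds already-normalized intensities (dll3_cyt, epi_cyt,
    cd45_cyt, dapi_nuc, area_um2).
    """
    dll3 = rec["dll3_cyt"] > cfg.dll3_threshold
    epi = rec["epi_cyt"] > cfg.epithelial_threshold
    if rec["cd45_cyt"] > cfg.hematopoietic_threshold:
        return "leukocyte", dll3
    nucleated = rec["dapi_nuc"] >= cfg.nucleation_threshold
    intact = rec["area_um2"] >= cfg.min_area_um2
    if (not nucleated or not intact) and (dll3 or epi):
        return "fragment", dll3
    if epi and dll3:
        return "CTC_dual", dll3
    if epi:
        return "CTC_epithelial_only", dll3
    if dll3:
        return "CTC_DLL3_only", dll3
    return "negative", dll3


def ucell_brute(expr, signature_idx, max_rank) -> float:
    """Signature score by definition: per-gene ranks computed as
    (#strictly greater) + (#equal + 1)/2, undetected genes at the capped
    rank, then the rank-sum statistic."""
    n = len(signature_idx)
    if not any(expr[i] > 0 for i in signature_idx):
        return 0.0
    ranks = []
    for i in signature_idx:
        if expr[i] == 0:
            rank = max_rank + 1
        else:
            greater = sum(1 for v in expr if v > expr[i])
            equal = sum(1 for v in expr if v == expr[i])
            rank = min(greater + (equal + 1) / 2.0, max_rank + 1)
        ranks.append(rank)
    u = sum(ranks) - n * (n + 1) / 2.0
    return min(max(1.0 - u / (n * max_rank), 0.0), 1.0)


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating every group assignment of
    the combined sample (tie-free inputs): 2 * min(tail) capped at 1."""
    combined = sorted(list(x) + list(y))
    assert len(set(combined)) == len(combined), "oracle assumes no ties"
    rank_of = {v: r + 1 for r, v in enumerate(combined)}
    n1 = len(x)
    u_obs = sum(rank_of[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(combined)), n1):
        r = sum(rank_of[combined[i]] for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    le = sum(1 for u in us if u <= u_obs) / len(us)
    ge = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2.0 * min(le, ge))


def _binom_cdf(x, n, p) -> float:
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k)
               for k in range(0, x + 1))


def clopper_pearson_brute(x, n, alpha=0.05, tol=1e-10):
    """Exact binomial interval by bisection on the binomial tails."""
    if x == 0:
        lower = 0.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:  # P(X >= x | p) = alpha/2
            mid = (lo + hi) / 2
            if 1 - _binom_cdf(x - 1, n, mid) < alpha / 2:
                lo = mid
            else:
                hi = mid
        lower = (lo + hi) / 2
    if x == n:
        upper = 1.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:  # P(X <= x | p) = alpha/2
            mid = (lo + hi) / 2
            if _binom_cdf(x, n, mid) > alpha / 2:
                lo = mid
            else:
                hi = mid
        upper = (lo + hi) / 2
    return lower, upper


def holm_brute(pvalues):
    """Holm step-down by its definition: sort, multiply by (m - i), running
    maximum, cap at 1, undo the sort."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for step, i in enumerate(order):
        running = max(running, (m - step) * pvalues[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def venn_brute(positivity_rows, genes):
    """Region counts by per-cell set logic."""
    regions = {}
    none = 0
    for r in range(1, len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            regions[frozenset(combo)] = 0
    for row in positivity_rows:
        pos = frozenset(g for g in genes if row[g])
        if not pos:
            none += 1
        else:
            regions[pos] += 1
    return regions, none
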