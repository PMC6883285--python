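"""Independent brute-force reference computations for the stability methods.

Everything here is written with plain Python loops and the ``statistics``
module (or tiny closed forms) so it shares no code path with the package's
vectorized implementations.
"""

from __future__ import annotations

import itertools
import math
import statistics
from typing import Mapping, Sequence


def sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1)."""
    return statistics.stdev(values)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def average_ranks(values: Sequence[float]) -> list[float]:
    """Ascending ranks with ties averaged (competition-free ranking)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


# --- BestKeeper ---------------------------------------------------------------

def bestkeeper_bruteforce(cq: Sequence[Sequence[float]]):
    """Per-gene SD, BKI, r with BKI, and the mean ranking score.

    ``cq`` is samples x genes (list of rows).  Returns dict with keys
    ``sd``, ``bki``, ``r``, ``mean_rank_score`` (all lists over genes except
    ``bki`` over samples).
    """
    n = len(cq)
    k = len(cq[0])
    sds = [sd([cq[s][g] for s in range(n)]) for g in range(k)]
    bki = [
        math.exp(sum(math.log(cq[s][g]) for g in range(k)) / k) for s in range(n)
    ]
    rs = [pearson([cq[s][g] for s in range(n)], bki) for g in range(k)]
    sd_rank = average_ranks(sds)
    r_rank = average_ranks([-r for r in rs])
    score = [(a + b) / 2 for a, b in zip(sd_rank, r_rank)]
    return {"sd": sds, "bki": bki, "r": rs, "mean_rank_score": score}


# --- comparative delta-Cq ------------------------------------------------------

def deltacq_bruteforce(cq: Sequence[Sequence[float]]):
    """Full pairwise SD(dCq) matrix and per-gene mean."""
    n = len(cq)
    k = len(cq[0])
    pair = [[0.0] * k for _ in range(k)]
    for g in range(k):
        for h in range(k):
            if g == h:
                continue
            diffs = [cq[s][g] - cq[s][h] for s in range(n)]
            pair[g][h] = sd(diffs)
    mean_sd = [sum(pair[g][h] for h in range(k) if h != g) / (k - 1) for g in range(k)]
    return {"pair_sd": pair, "mean_sd": mean_sd}


# --- geNorm --------------------------------------------------------------------

def genorm_m_bruteforce(
    cq: Sequence[Sequence[float]], efficiencies: Sequence[float] | None = None
) -> list[float]:
    """M per gene: mean SD of pairwise log2 expression ratios."""
    n = len(cq)
    k = len(cq[0])
    if efficiencies is None:
        logq = [[-cq[s][g] for g in range(k)] for s in range(n)]
    else:
        means = [sum(cq[s][g] for s in range(n)) / n for g in range(k)]
        logq = [
            [(means[g] - cq[s][g]) * math.log2(efficiencies[g]) for g in range(k)]
            for s in range(n)
        ]
    m = []
    for g in range(k):
        sds = []
        for h in range(k):
            if h == g:
                continue
            ratios = [logq[s][g] - logq[s][h] for s in range(n)]
            sds.append(sd(ratios))
        m.append(sum(sds) / len(sds))
    return m


def genorm_stepwise_bruteforce(cq, genes):
    """Worst-first exclusion order by exhaustive M recomputation."""
    remaining = list(range(len(genes)))
    order = []
    while len(remaining) > 2:
        sub = [[row[g] for g in remaining] for row in cq]
        m = genorm_m_bruteforce(sub)
        worst_pos = max(range(len(remaining)), key=lambda i: m[i])
        order.append(genes[remaining[worst_pos]])
        remaining.pop(worst_pos)
    return order, [genes[i] for i in remaining]


def genorm_v_bruteforce(cq, best_first_cols: Sequence[int]) -> dict[int, float]:
    """V(n/n+1) on the given best-first column order (E = 2)."""
    n = len(cq)
    k = len(best_first_cols)
    means = [sum(cq[s][g] for s in range(n)) / n for g in range(len(cq[0]))]
    logq = [[means[g] - cq[s][g] for g in range(len(cq[0]))] for s in range(n)]
    out = {}
    for m in range(2, k):
        cols_n = best_first_cols[:m]
        cols_n1 = best_first_cols[: m + 1]
        diffs = [
            sum(logq[s][g] for g in cols_n) / m
            - sum(logq[s][g] for g in cols_n1) / (m + 1)
            for s in range(n)
        ]
        out[m] = sd(diffs)
    return out


# --- NormFinder ----------------------------------------------------------------

def normfinder_bruteforce(cq, groups: Sequence[str]):
    """Stability values via straight-loop implementation of the model.

    ``cq``: samples x genes; ``groups``: label per sample (>= 2 labels).
    Returns dict with ``rho`` (per gene), ``sigma2`` and ``d_shrunk``
    (gene x group label), ``gamma_sq`` and ``best_pair``.
    """
    n = len(cq)
    k = len(cq[0])
    labels = list(dict.fromkeys(groups))
    G = len(labels)
    rows_by = {lab: [s for s in range(n) if groups[s] == lab] for lab in labels}

    sigma2: dict[str, list[float]] = {}
    a: dict[str, list[float]] = {}
    for lab in labels:
        rows = rows_by[lab]
        ng = len(rows)
        gene_means = [sum(cq[s][g] for s in rows) / ng for g in range(k)]
        sample_means = [sum(cq[s][g] for g in range(k)) / k for s in rows]
        tot = sum(gene_means) / k
        v = []
        for g in range(k):
            acc = 0.0
            for idx, s in enumerate(rows):
                z = cq[s][g] - gene_means[g] - sample_means[idx] + tot
                acc += z * z
            v.append(acc / (ng - 1))
        sig = [
            max(0.0, k / (k - 2) * v[g] - sum(v) / ((k - 1) * (k - 2)))
            for g in range(k)
        ]
        sigma2[lab] = sig
        a[lab] = [gene_means[g] - tot for g in range(k)]

    N = n
    d: dict[str, list[float]] = {}
    for g in range(k):
        wavg = sum(len(rows_by[lab]) * a[lab][g] for lab in labels) / N
        for lab in labels:
            d.setdefault(lab, [0.0] * k)
            d[lab][g] = a[lab][g] - wavg

    u = {lab: [sigma2[lab][g] / len(rows_by[lab]) for g in range(k)] for lab in labels}
    sum_d2 = sum(d[lab][g] ** 2 for lab in labels for g in range(k))
    mean_u = sum(u[lab][g] for lab in labels for g in range(k)) / (G * k)
    gamma_sq = max(0.0, sum_d2 / ((G - 1) * (k - 1)) - mean_u)

    d_shrunk = {lab: [0.0] * k for lab in labels}
    stab = {lab: [0.0] * k for lab in labels}
    for lab in labels:
        for g in range(k):
            ug = u[lab][g]
            if gamma_sq == 0.0:
                d_shrunk[lab][g] = 0.0
                stab[lab][g] = math.sqrt(ug)
            else:
                c = gamma_sq / (gamma_sq + ug)
                d_shrunk[lab][g] = d[lab][g] * c
                stab[lab][g] = abs(d_shrunk[lab][g]) + math.sqrt(gamma_sq * ug / (gamma_sq + ug))
    rho = [sum(stab[lab][g] for lab in labels) / G for g in range(k)]

    post_var = {
        lab: [
            (gamma_sq * u[lab][g] / (gamma_sq + u[lab][g])) if gamma_sq > 0 else u[lab][g]
            for g in range(k)
        ]
        for lab in labels
    }
    best = None
    for i, j in itertools.combinations(range(k), 2):
        vals = []
        for lab in labels:
            dp = 0.5 * (d_shrunk[lab][i] + d_shrunk[lab][j])
            vp = 0.25 * (post_var[lab][i] + post_var[lab][j])
            vals.append(abs(dp) + math.sqrt(vp))
        pr = sum(vals) / G
        if best is None or pr < best[1]:
            best = ((i, j), pr)
    return {
        "rho": rho,
        "sigma2": sigma2,
        "d_shrunk": d_shrunk,
        "gamma_sq": gamma_sq,
        "best_pair": best,
    }


# --- quantification ------------------------------------------------------------

def fold_changes_bruteforce(
    cq: Mapping[str, Mapping[str, float]],
    target: str,
    references: Sequence[str],
    groups: Mapping[str, str],
    calibrator: str,
) -> dict[str, float]:
    """2^-ddCq per sample from dictionaries, straight from the definition."""
    samples = list(cq)
    dcq = {
        s: cq[s][target] - sum(cq[s][r] for r in references) / len(references)
        for s in samples
    }
    cal = [dcq[s] for s in samples if groups[s] == calibrator]
    base = sum(cal) / len(cal)
    return {s: 2.0 ** (-(dcq[s] - base)) for s in samples}


def anova_bruteforce(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int]]:
    """One-way ANOVA F from the sums-of-squares table."""
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), (df_b, df_w)
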