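"""Independent brute-force oracles used by the unit and acceptance tests.

Each function here is a direct, position-by-position (or table-by-table)
enumeration of the statistic it checks, deliberately written without sharing
any code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_ks_es(ordered_genes, gene_set, scores, weight_exponent):
    """Weighted-KS enrichment score by walking every position of the list."""
    gene_set = set(gene_set)
    n = len(ordered_genes)
    hits = [g in gene_set for g in ordered_genes]
    k = sum(hits)
    weights = [abs(s) ** weight_exponent for s, h in zip(scores, hits) if h]
    total = sum(weights) or float(k)
    if sum(weights) == 0:
        weights = [1.0] * k
    running = 0.0
    pos_ext = 0.0
    neg_ext = 0.0
    wi = 0
    for i in range(n):
        if hits[i]:
            running += weights[wi] / total
            wi += 1
        else:
            running -= 1.0 / (n - k)
        pos_ext = max(pos_ext, running)
        neg_ext = min(neg_ext, running)
    # equal-magnitude extrema resolve to the positive deviation
    return pos_ext if pos_ext >= -neg_ext - 1e-12 else neg_ext


def brute_ssgsea(ordered_in_set, tau):
    """ssGSEA integral statistic from an ordered in-set indicator vector."""
    n = len(ordered_in_set)
    k = sum(ordered_in_set)
    rank_weights = [(n - i) ** tau for i in range(n)]  # position i (0-based)
    denom = sum(w for w, h in zip(rank_weights, ordered_in_set) if h)
    cum_in = cum_out = 0.0
    score = 0.0
    for i in range(n):
        if ordered_in_set[i]:
            cum_in += rank_weights[i] / denom
        else:
            cum_out += 1.0 / (n - k)
        score += cum_in - cum_out
    return score


def brute_km(times, events):
    """Product-limit table: [(event time, S(t))] computed row by row."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    n = len(times)
    s = 1.0
    table = []
    at_risk = n
    i = 0
    while i < n:
        t = times[i]
        d = 0
        c = 0
        while i < n and times[i] == t:
            if events[i]:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            table.append((t, s))
        at_risk -= d + c
    return table


def brute_logrank(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square via observed-minus-expected sums."""
    times_a = np.asarray(times_a, float); events_a = np.asarray(events_a, int)
    times_b = np.asarray(times_b, float); events_b = np.asarray(events_b, int)
    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    event_times = np.unique(all_times[all_events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = (times_a >= t).sum()
        n_b = (times_b >= t).sum()
        n = n_a + n_b
        d = ((all_times == t) & (all_events == 1)).sum()
        d_a = ((times_a == t) & (events_a == 1)).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def brute_mannwhitney_u(x_low, x_high):
    """U = #{pairs (a in low group, b in high group) with a < b}, ties half."""
    u = 0.0
    for a in x_low:
        for b in x_high:
            if a < b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u
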