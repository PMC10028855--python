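"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as naive, loop-based arithmetic on plain Python
structures, deliberately avoiding the code paths (and wherever possible the
libraries) used by the package itself.
"""

import math


def dot_scores(matrix, weights):
    """matrix: dict gene -> list of values per observation; weights: dict."""
    n_obs = len(next(iter(matrix.values())))
    return [sum(weights[g] * matrix[g][j] for g in matrix) for j in range(n_obs)]


def zscore_mean_scores(matrix, directions):
    """Per-gene z across observations (sample sd), averaged with sign flips."""
    genes = list(matrix)
    n = len(matrix[genes[0]])
    zrows = {}
    for g in genes:
        vals = matrix[g]
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / (n - 1)
        sd = math.sqrt(var)
        zrows[g] = [0.0] * n if sd == 0 else [(v - mean) / sd for v in vals]
    out = []
    for j in range(n):
        total = 0.0
        for g in genes:
            sign = -1.0 if directions[g] == "down" else 1.0
            total += sign * zrows[g][j]
        out.append(total / len(genes))
    return out


def up_down_scores(matrix, directions):
    up = [g for g in matrix if directions[g] == "up"]
    down = [g for g in matrix if directions[g] == "down"]
    n = len(matrix[up[0]])
    out = []
    for j in range(n):
        mu_up = sum(matrix[g][j] for g in up) / len(up)
        mu_down = sum(matrix[g][j] for g in down) / len(down) if down else 0.0
        out.append(mu_up - mu_down)
    return out


def midranks(values):
    """Ascending mid-ranks: rank = (#less) + (#equal + 1) / 2."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def ssgsea_score(genes, values, gene_set, alpha):
    """Step-by-step single-observation enrichment walk."""
    ranks = midranks(values)
    # walk order: descending rank, residual ties lexicographic by gene id
    order = sorted(range(len(genes)), key=lambda i: (-ranks[i], genes[i]))
    in_set = [genes[i] in gene_set for i in order]
    n = len(genes)
    n_set = sum(in_set)
    w_total = sum(abs(ranks[order[i]]) ** alpha for i in range(n) if in_set[i])
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in range(n):
        if in_set[i]:
            p_in += abs(ranks[order[i]]) ** alpha / w_total
        else:
            p_out += 1.0 / (n - n_set)
        es += p_in - p_out
    return es


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def complete_linkage(dist):
    """Naive O(n^3) complete-linkage agglomeration from a full distance matrix.

    Returns the list of merge heights in merge order and the partitions after
    each merge (list of sets of original indices).  Ties merge the pair with
    the lowest indices first.
    """
    clusters = [{i} for i in range(len(dist))]
    heights = []
    partitions = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i][j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        heights.append(d)
        partitions.append([set(c) for c in clusters])
    return heights, partitions


def silhouette_mean(dist, labels):
    n = len(labels)
    uniq = sorted(set(labels))
    total = 0.0
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue  # singleton contributes 0
        a = sum(dist[i][j] for j in own) / len(own)
        b = min(
            sum(dist[i][j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in uniq
            if c != labels[i]
        )
        total += 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return total / n


def logrank_chi2(times_a, events_a, times_b, events_b):
    """Two-sample log-rank chi-square via expected-events arithmetic."""
    data = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk_a = sum(1 for tt, _, g in data if tt >= t and g == 0)
        at_risk_b = sum(1 for tt, _, g in data if tt >= t and g == 1)
        n = at_risk_a + at_risk_b
        d = sum(1 for tt, e, _ in data if tt == t and e == 1)
        d_a = sum(1 for tt, e, g in data if tt == t and e == 1 and g == 0)
        e_a = d * at_risk_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (at_risk_a / n) * (at_risk_b / n) * (n - d) / (n - 1)
    return (o_minus_e**2) / var if var > 0 else 0.0


def bh_adjust(pvals):
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * n / rank_from_end)
        adj[i] = val
        prev = val
    return adj
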