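"""Independent straight-line re-implementation of the scoring recipe.

Used as the test oracle for the vectorised engine: plain Python loops,
``math.erfc`` for the normal CDF, and a hand-written Benjamini-Hochberg
step-up.  Deliberately shares no code with the package.
"""

import math


def bf_normalize(counts, pseudocount, scale):
    total = sum(counts)
    return [pseudocount + c * scale / total for c in counts]


def bf_phi(z):
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def bf_bh(pvalues):
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def bf_sample_sd(values):
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def bf_run_contrast(guides, genes, ctrl_counts, trt_counts,
                    pseudocount, scale, window, min_std):
    """One control/treated pair scored from scratch; returns unit -> fields."""
    n = len(guides)
    nc = bf_normalize(ctrl_counts, pseudocount, scale)
    nt = bf_normalize(trt_counts, pseudocount, scale)
    fc = [math.log2(nt[i] / nc[i]) for i in range(n)]

    # rank by normalised control count descending, ties by guide id
    order = sorted(range(n), key=lambda i: (-nc[i], guides[i]))
    fc_ranked = [fc[i] for i in order]
    z = {}
    for rank, i in enumerate(order):
        lo = max(0, rank - window)
        hi = min(n - 1, rank + window)
        sd = max(bf_sample_sd(fc_ranked[lo : hi + 1]), min_std)
        z[guides[i]] = fc[i] / sd

    units = {}
    for i in range(n):
        units.setdefault(genes[i], []).append(z[guides[i]])
    names = sorted(units)
    sumz = {u: sum(units[u]) for u in names}
    numobs = {u: len(units[u]) for u in names}
    raw = {u: sumz[u] / math.sqrt(numobs[u]) for u in names}
    mean = sum(raw.values()) / len(names)
    sd = math.sqrt(sum((raw[u] - mean) ** 2 for u in names) / len(names))
    normz = {u: (raw[u] - mean) / sd for u in names}
    p_left = {u: bf_phi(normz[u]) for u in names}
    p_right = {u: bf_phi(-normz[u]) for u in names}
    fdr_left = dict(zip(names, bf_bh([p_left[u] for u in names])))
    fdr_right = dict(zip(names, bf_bh([p_right[u] for u in names])))
    return {
        u: {
            "NUMOBS": numobs[u],
            "SUMZ": sumz[u],
            "NORMZ": normz[u],
            "P_LEFT": p_left[u],
            "P_RIGHT": p_right[u],
            "FDR_LEFT": fdr_left[u],
            "FDR_RIGHT": fdr_right[u],
        }
        for u in names
    }
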