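"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over genes/samples/times, kept
deliberately separate from the package's vectorized code paths.
"""

import math

from scipy.stats import norm


def brute_force_funnel(
    values,          # dict gene -> dict sample -> log2 value
    tumors,          # list of tumor sample ids
    refs,            # list of reference sample ids
    cna,             # dict gene -> dict sample -> call
    family,          # list of family gene ids
    z_cut=2.0,
    alpha=0.05,
    min_ref_sd=0.01,
    sum_mode="all",
):
    """Enumerate the full selection funnel with explicit loops."""
    mean, sd = {}, {}
    for g in family:
        xs = [values[g][r] for r in refs]
        m = sum(xs) / len(xs)
        var = sum((x - m) ** 2 for x in xs) / (len(xs) - 1)
        mean[g], sd[g] = m, math.sqrt(var)
    screenable = [g for g in family if sd[g] > min_ref_sd]

    z = {
        g: {t: (values[g][t] - mean[g]) / sd[g] for t in tumors} for g in screenable
    }
    cohort = [t for t in tumors if any(z[g][t] >= z_cut for g in screenable)]

    stats = {}
    for g in screenable:
        if sum_mode == "all":
            s = sum(z[g][t] for t in cohort)
        elif sum_mode == "positive":
            s = sum(z[g][t] for t in cohort if z[g][t] > 0)
        else:
            s = sum(z[g][t] for t in cohort if z[g][t] >= z_cut)
        n = sum(1 for t in cohort if z[g][t] >= z_cut)
        stats[g] = (s, n, n * s)

    def threshold(idx):
        vals = [stats[g][idx] for g in screenable]
        vals += [0.0] * (len(family) - len(screenable))
        m = sum(vals) / len(vals)
        var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
        s = math.sqrt(var)
        return m if s == 0 else m + norm.ppf(1 - alpha) * s

    thr_s, thr_n, thr_w = threshold(0), threshold(1), threshold(2)
    part1 = {g for g in screenable if stats[g][0] > thr_s and stats[g][2] > thr_w}
    part2 = {g for g in screenable if stats[g][1] > thr_n and stats[g][2] > thr_w}
    shared = part1 & part2
    amplified = {
        g for g in family if g in cna and any(v == 2 for v in cna[g].values())
    }
    return {
        "part1": part1,
        "part2": part2,
        "shared": shared,
        "amplified": amplified,
        "overexpressed": shared & amplified,
        "thresholds": (thr_s, thr_n, thr_w),
        "m": len(cohort),
    }


def anova_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    if ssw == 0:
        return float("inf") if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def km_hand(times, events):
    """Product-limit estimator by explicit risk-set bookkeeping."""
    order = sorted(set(times))
    s = 1.0
    out = []
    for t in order:
        at_risk = sum(1 for x in times if x >= t)
        deaths = sum(1 for x, e in zip(times, events) if x == t and e)
        if deaths:
            s *= 1 - deaths / at_risk
        out.append((t, s))
    return out


def logrank_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square via observed-minus-expected tabulation."""
    event_times = sorted(
        {t for t, e in zip(times_a, events_a) if e}
        | {t for t, e in zip(times_b, events_b) if e}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = sum(1 for x in times_a if x >= t)
        n2 = sum(1 for x in times_b if x >= t)
        d1 = sum(1 for x, e in zip(times_a, events_a) if x == t and e)
        d2 = sum(1 for x, e in zip(times_b, events_b) if x == t and e)
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return (o_minus_e**2) / var if var > 0 else 0.0
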