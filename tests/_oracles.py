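"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately recompute statistics by direct enumeration, sharing no
code with the implementation paths they check.
"""

import itertools

import numpy as np


def running_sum_es(abs_metrics, member_positions):
    """Enrichment statistic by a literal position-by-position running sum."""
    n = len(abs_metrics)
    members = set(int(i) for i in member_positions)
    k = len(members)
    total = sum(abs_metrics[i] for i in members)
    best, best_abs = 0.0, -1.0
    p_hit = p_miss = 0.0
    for i in range(n):
        if i in members:
            p_hit += abs_metrics[i] / total
        else:
            p_miss += 1.0 / (n - k)
        value = p_hit - p_miss
        if abs(value) > best_abs + 1e-15:
            best, best_abs = value, abs(value)
    return best


def exhaustive_es_null(abs_metrics, k):
    """ES of every size-k subset of positions, by full enumeration."""
    n = len(abs_metrics)
    return np.array([
        running_sum_es(abs_metrics, subset)
        for subset in itertools.combinations(range(n), k)
    ])


def exact_two_sided_es_pvalue(abs_metrics, member_positions):
    """Two-sided permutation p over the complete subset population.

    Tail counts use a small tolerance so subsets that tie the observed
    statistic mathematically are counted as ties even when floating-point
    summation order leaves them an ulp apart.
    """
    es = running_sum_es(abs_metrics, member_positions)
    null = exhaustive_es_null(abs_metrics, len(member_positions))
    eps = 1e-9 * max(1.0, abs(es))
    p_up = np.mean(null >= es - eps)
    p_down = np.mean(null <= es + eps)
    return es, min(1.0, 2.0 * min(p_up, p_down))


def exhaustive_median_rank_null(n_terms, n_interventions):
    """Median of every possible tuple of per-intervention ranks (T^I tuples)."""
    tuples = itertools.product(range(1, n_terms + 1), repeat=n_interventions)
    return np.array([float(np.median(t)) for t in tuples])


def exact_two_sided_median_pvalue(n_terms, observed_ranks):
    """Two-sided median-rank p by full enumeration of the uniform null."""
    observed = float(np.median(observed_ranks))
    null = exhaustive_median_rank_null(n_terms, len(observed_ranks))
    p_up = np.mean(null <= observed)
    p_down = np.mean(null >= observed)
    return observed, min(1.0, 2.0 * min(p_up, p_down))


def fisher_two_sided_pvalue(table):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
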