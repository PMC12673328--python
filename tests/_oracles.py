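"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration, all-pairs
averages, direct set counting — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_hmm(emis: np.ndarray, decay: np.ndarray, q: np.ndarray):
    """Exhaustive 2-state HMM quantities for one sample chain.

    emis: (n_sites, 2) linear emission likelihoods; decay[i] = exp(-t d_i)
    with decay[0] unused; q[i] the stationary probability of state 0 used in
    both the initial distribution and the re-entry term.

    Returns (total_loglik, marginal_p0 per site, best_path, best_path_loglik).
    """
    n = emis.shape[0]
    total = 0.0
    marg = np.zeros(n)
    best_lp = -np.inf
    best_path = None
    for path in itertools.product((0, 1), repeat=n):
        pr = (q[0] if path[0] == 0 else 1.0 - q[0]) * emis[0, path[0]]
        for i in range(1, n):
            stat = q[i] if path[i] == 0 else 1.0 - q[i]
            trans = decay[i] * (path[i] == path[i - 1]) \
                + (1.0 - decay[i]) * stat
            pr *= trans * emis[i, path[i]]
        total += pr
        for i in range(n):
            if path[i] == 0:
                marg[i] += pr
        lp = np.log(pr) if pr > 0 else -np.inf
        if lp > best_lp:
            best_lp = lp
            best_path = path
    return np.log(total), marg / total, np.array(best_path), best_lp


def pairwise_pi(genotypes: np.ndarray, length: int) -> float:
    """Average over all unordered sample pairs of per-site mismatch count,
    divided by the window length.  Missing calls (-1) are skipped per pair."""
    g = np.asarray(genotypes)
    n = g.shape[1]
    diffs = []
    for a, b in itertools.combinations(range(n), 2):
        ok = (g[:, a] >= 0) & (g[:, b] >= 0)
        diffs.append(np.sum(g[ok, a] != g[ok, b]))
    return float(np.mean(diffs) / length) if diffs else 0.0


def count_haplotypes(genotypes: np.ndarray) -> int:
    """Distinct column strings of a (n_sites, n_samples) matrix."""
    return len({tuple(genotypes[:, j]) for j in range(genotypes.shape[1])})


def interval_union_length(intervals, lo, hi) -> int:
    """Integer-grid union length of intervals clipped to [lo, hi)."""
    covered = set()
    for a, b in intervals:
        covered.update(range(max(a, lo), min(b, hi)))
    return len(covered)


def spearman_perm_pvalue(bx: np.ndarray, by: np.ndarray) -> float:
    """Exact two-sided permutation P of Spearman's rho by full enumeration
    (feasible for <= 8 points, used to validate the subset-DP path)."""
    from scipy import stats

    n = len(bx)
    obs = abs(stats.spearmanr(bx, by).statistic)
    ry = stats.rankdata(by)
    count = 0
    total = 0
    rx = stats.rankdata(bx)
    for perm in itertools.permutations(range(n)):
        rho = stats.spearmanr(rx, ry[list(perm)]).statistic
        count += abs(rho) >= obs - 1e-12
        total += 1
    return count / total


def bh_flags_naive(p_values, q):
    """Step-up BH by direct definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags
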