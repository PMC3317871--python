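"""Independent brute-force oracles used by the test suite.

Everything here is written directly from first principles (explicit
loops, exhaustive enumeration) and deliberately shares no code with the
package implementation it checks.
"""

from itertools import combinations, product

import numpy as np


def wc_theta_bruteforce(genotypes, pops):
    """Weir–Cockerham theta for one biallelic locus, transcribed from the
    variance-component formulas with explicit scalar arithmetic."""
    genotypes = np.asarray(genotypes, dtype=float)
    pops = np.asarray(pops)
    keep = genotypes >= 0
    genotypes, pops = genotypes[keep], pops[keep]
    labels = [p for p in dict.fromkeys(pops)]
    r = len(labels)
    n_i, p_i, h_i = [], [], []
    for lab in labels:
        g = genotypes[pops == lab]
        n_i.append(len(g))
        p_i.append(sum(g) / (2 * len(g)))
        h_i.append(sum(1 for x in g if x == 1) / len(g))
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n ** 2 for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c)


def hmm_path_posteriors(z, mu, sigma, A, pi):
    """Exhaustive 3^n enumeration: joint path probabilities, per-site
    marginals gamma, pairwise transition expectations xi, viterbi path."""
    n = len(z)
    dens = np.empty((n, 3))
    for t in range(n):
        for s in range(3):
            dens[t, s] = np.exp(-0.5 * ((z[t] - mu[s]) / sigma[s]) ** 2) / (
                sigma[s] * np.sqrt(2 * np.pi))
    total = 0.0
    gamma = np.zeros((n, 3))
    xi = np.zeros((3, 3))
    best_p, best_path = -1.0, None
    for path in product(range(3), repeat=n):
        p = pi[path[0]] * dens[0, path[0]]
        for t in range(1, n):
            p *= A[path[t - 1], path[t]] * dens[t, path[t]]
        total += p
        for t in range(n):
            gamma[t, path[t]] += p
        for t in range(n - 1):
            xi[path[t], path[t + 1]] += p
        if p > best_p:             # strict: first (lexicographically
            best_p, best_path = p, path    # smallest) max path kept
    return gamma / total, xi / total, np.array(best_path), np.log(total)


def runs_test_exact(values):
    """Exact one-sided (toward fewer runs) p by enumeration over all
    arrangements of the dichotomized labels."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    lab = values[values != med] > med
    n1, n2 = int(lab.sum()), int((~lab).sum())
    obs = 1 + int((lab[1:] != lab[:-1]).sum())
    n = n1 + n2
    le = tot = 0
    for pos in combinations(range(n), n1):
        arr = np.zeros(n, dtype=bool)
        arr[list(pos)] = True
        runs = 1 + int((arr[1:] != arr[:-1]).sum())
        tot += 1
        if runs <= obs:
            le += 1
    return le / tot


def fisher_two_sided_exact(table):
    """Two-sided Fisher p by direct enumeration of the hypergeometric
    support, summing tables no more probable than the observed one."""
    from math import comb
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x) * comb(n - col1, row1 - x)) / comb(n, row1)

    p_obs = prob(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def mwu_exact_greater(x, y):
    """Exact P(rank sum of x >= observed) over all label assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort()
    ranks = np.empty(len(pooled))
    # mid-ranks for ties
    sorted_p = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_p[j + 1] == sorted_p[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    obs = ranks[: len(x)].sum()
    ge = tot = 0
    for comb_idx in combinations(range(len(pooled)), len(x)):
        tot += 1
        if ranks[list(comb_idx)].sum() >= obs - 1e-9:
            ge += 1
    return ge / tot


def sample_hmm(n, mu, sigma, A, pi, rng):
    """Draw (states, observations) from a known Gaussian HMM."""
    states = np.empty(n, dtype=np.int8)
    states[0] = rng.choice(3, p=pi)
    for t in range(1, n):
        states[t] = rng.choice(3, p=A[states[t - 1]])
    z = rng.normal(np.asarray(mu)[states], np.asarray(sigma)[states])
    return states, z


def interval_jaccard(called, truth):
    """Base-pair Jaccard between two interval sets given as lists of
    (chrom, start0, end) half-open tuples (each set non-overlapping)."""
    def by_chrom(iv):
        m = {}
        for c, s, e in iv:
            m.setdefault(c, []).append((s, e))
        return m

    cm, tm = by_chrom(called), by_chrom(truth)
    inter = 0
    for c in set(cm) & set(tm):
        for s, e in cm[c]:
            for s2, e2 in tm[c]:
                inter += max(0, min(e, e2) - max(s, s2))
    size_c = sum(e - s for v in cm.values() for s, e in v)
    size_t = sum(e - s for v in tm.values() for s, e in v)
    union = size_c + size_t - inter
    return inter / union if union else float("nan")
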