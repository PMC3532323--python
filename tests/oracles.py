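"""Independent oracle implementations used only by the tests.

Each oracle is deliberately written as the most literal translation of the
definition it checks (whitening-SVD CCA, brute-force running sums, exhaustive
enumeration), sharing no code with the package.
"""

from itertools import combinations

import numpy as np


def classical_cca(x: np.ndarray, y: np.ndarray):
    """Classical CCA via whitening + SVD. Returns (correlations, u_variates, v_variates)."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cxx = xc.T @ xc / (n - 1)
    cyy = yc.T @ yc / (n - 1)
    cxy = xc.T @ yc / (n - 1)

    def inv_sqrt(c):
        evals, evecs = np.linalg.eigh(c)
        return (evecs / np.sqrt(evals)) @ evecs.T

    kx = inv_sqrt(cxx)
    ky = inv_sqrt(cyy)
    u, s, vt = np.linalg.svd(kx @ cxy @ ky)
    r = min(x.shape[1], y.shape[1])
    w = kx @ u[:, :r]
    v = ky @ vt.T[:, :r]
    return s[:r], xc @ w, yc @ v


def brute_average_precision(ranking, relevant, k):
    """AP@k straight from the definition."""
    hits = 0
    precs = []
    for i, item in enumerate(ranking[:k], start=1):
        if item in relevant:
            hits += 1
            precs.append(hits / i)
    return sum(precs) / len(precs) if precs else 0.0


def brute_enrichment_score(values_by_gene: dict, members: set, exponent: float = 1.0):
    """Literal GSEA running sum over the full ranked gene list."""
    order = sorted(values_by_gene, key=lambda g: (-values_by_gene[g], g))
    nr = sum(abs(values_by_gene[g]) ** exponent for g in order if g in members)
    n_miss = len(order) - len(members)
    running = 0.0
    best = 0.0
    for g in order:
        if g in members:
            running += (abs(values_by_gene[g]) ** exponent) / nr if nr > 0 else 0.0
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def brute_outlier_control(profiles: np.ndarray):
    """Index of the control with largest summed Euclidean distance to the others."""
    sums = []
    for i in range(len(profiles)):
        total = 0.0
        for j in range(len(profiles)):
            if i != j:
                total += float(np.sqrt(((profiles[i] - profiles[j]) ** 2).sum()))
        sums.append(total)
    return int(np.argmax(sums))


def enumerate_overlap_tail(universe: list, term: set, draw_size: int, observed: int):
    """P(overlap >= observed) by exhaustive enumeration of all draws."""
    hits = 0
    total = 0
    for draw in combinations(universe, draw_size):
        total += 1
        if len(term & set(draw)) >= observed:
            hits += 1
    return hits / total
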