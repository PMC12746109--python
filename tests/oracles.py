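"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive (enumeration, recursion, grid search)
and shares no code with the implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import special


# --- span matching ----------------------------------------------------------


def brute_force_match(pred, gold):
    """(COR, PAR) maximized lexicographically over all one-to-one matchings.

    Enumerates every injective assignment of predictions to gold spans; a
    pair contributes COR when extents are equal, PAR when they merely
    overlap, nothing otherwise.
    """
    pred, gold = list(pred), list(gold)
    if len(pred) > len(gold):
        best = (0, 0)
        for chosen in itertools.permutations(range(len(pred)), len(gold)):
            cor = par = 0
            for g_idx, p_idx in enumerate(chosen):
                p, g = pred[p_idx], gold[g_idx]
                if p == g:
                    cor += 1
                elif p[0] < g[1] and p[1] > g[0]:
                    par += 1
            best = max(best, (cor, par))
        return best
    best = (0, 0)
    for chosen in itertools.permutations(range(len(gold)), len(pred)):
        cor = par = 0
        for p_idx, g_idx in enumerate(chosen):
            p, g = pred[p_idx], gold[g_idx]
            if p == g:
                cor += 1
            elif p[0] < g[1] and p[1] > g[0]:
                par += 1
        best = max(best, (cor, par))
    return best


# --- edit distance ----------------------------------------------------------


def naive_levenshtein(a: str, b: str) -> int:
    """Memoized recursive edit distance (independent of the DP implementation)."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def naive_fitting_distance(needle: str, haystack: str) -> int:
    """Min edit distance of needle against every explicit substring."""
    best = len(needle)
    for i in range(len(haystack) + 1):
        for j in range(i, len(haystack) + 1):
            best = min(best, naive_levenshtein(needle, haystack[i:j]))
    return best


# --- discrete power law -----------------------------------------------------


def grid_alpha_mle(x, xmin: int, lo=1.05, hi=5.0, step=1e-4) -> float:
    """Grid maximization of the discrete power-law log-likelihood."""
    x = np.asarray(x, dtype=float)
    alphas = np.arange(lo, hi, step)
    z = special.zeta(alphas, xmin)
    ll = -len(x) * np.log(z) - alphas * np.log(x).sum()
    return float(alphas[np.argmax(ll)])


# --- triads -----------------------------------------------------------------


def brute_force_triads(strains, edges):
    """All triads by explicit triple enumeration over (s_i, compound, s_j).

    ``edges`` is an iterable of (source, target, relation_type).  Returns a
    sorted list of (type, strain_a, strain_b, compound) with symmetric types
    stored on sorted pairs and directed types ordered actor-first.
    """
    edge_set = set(edges)
    compounds = sorted(
        {t for _, t, _ in edge_set if t[0] == "COMPOUND"}
        | {s for s, _, _ in edge_set if s[0] == "COMPOUND"}
    )
    strains = sorted(strains)
    found = set()
    for c in compounds:
        for si in strains:
            for sj in strains:
                if si == sj:
                    continue
                if (si, c, "DEGRADES") in edge_set and (sj, c, "DEGRADES") in edge_set:
                    a, b = sorted((si, sj))
                    found.add(("competition", a, b, c))
                if (si, c, "PRODUCES") in edge_set and (sj, c, "DEGRADES") in edge_set:
                    found.add(("cross_feeding", si, sj, c))
                if (si, c, "PRODUCES") in edge_set and (c, sj, "INHIBITS") in edge_set:
                    found.add(("direct_inhibition", si, sj, c))
                if (si, c, "PRODUCES") in edge_set and (sj, c, "RESISTS") in edge_set:
                    a, b = sorted((si, sj))
                    found.add(("resistance", a, b, c))
    return sorted(found)


# --- Fisher / BH ------------------------------------------------------------


def brute_force_fisher(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration, exact arithmetic.

    Enumerates all tables with the observed margins; the p-value is the sum
    of probabilities of tables at most as probable as the observed one.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(total)


def reference_bh(pvalues):
    """Hand-written Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# --- betweenness ------------------------------------------------------------


def brute_force_betweenness(nodes, directed_edges):
    """Unnormalized betweenness by explicit shortest-path enumeration (BFS)."""
    nodes = list(nodes)
    adj = {v: [] for v in nodes}
    for u, v in directed_edges:
        if v not in adj[u]:
            adj[u].append(v)
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        # BFS counting shortest paths
        dist = {s: 0}
        sigma = {v: 0.0 for v in nodes}
        sigma[s] = 1.0
        preds = {v: [] for v in nodes}
        queue = [s]
        order = []
        while queue:
            u = queue.pop(0)
            order.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        for t in nodes:
            if t == s or t not in dist:
                continue
            # count, for every intermediate v, the fraction of s-t shortest
            # paths through v, by explicit path enumeration
            paths = []

            def walk(v, acc):
                if v == s:
                    paths.append(list(acc))
                    return
                for p in preds[v]:
                    walk(p, acc + [p])

            walk(t, [])
            for path in paths:
                for v in path:
                    if v != s:
                        bc[v] += 1.0 / len(paths)
    return bc
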