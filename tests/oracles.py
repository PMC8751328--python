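"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations: explicit path enumeration for
betweenness, exact enumeration for the HWE test, multi-start constrained
likelihood maximization for haplotype frequencies, definition-level
partial likelihoods for Cox fits, and threshold search for BH decisions.
None of these share code with the package.
"""

from itertools import permutations
from math import comb

import numpy as np
from scipy.optimize import minimize, minimize_scalar


# ------------------------------------------------------- betweenness oracle

def _all_shortest_paths(adj, s, t):
    """Every shortest simple path from s to t by breadth-limited DFS."""
    best = [None]
    paths = []

    def dfs(node, path):
        if best[0] is not None and len(path) > best[0]:
            return
        if node == t:
            if best[0] is None or len(path) < best[0]:
                best[0] = len(path)
                paths.clear()
            if len(path) == best[0]:
                paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(s, [s])
    return paths


def brute_betweenness(nodes, edges):
    """Relative betweenness by explicit shortest-path enumeration."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    if n < 3:
        return out
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                out[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: c / norm for v, c in out.items()}


# -------------------------------------------------------------- HWE oracle

def brute_hwe_exact(n0, n1, n2):
    """Exact conditional HWE p by full enumeration over het counts."""
    n = n0 + n1 + n2
    n_min = min(n1 + 2 * n2, n1 + 2 * n0)
    if n_min == 0:
        return 1.0
    probs = {}
    for het in range(n_min % 2, n_min + 1, 2):
        hom_min = (n_min - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        # multinomial count of genotype configurations x 2^het phase factor
        weight = (
            comb(n, het) * comb(n - het, hom_min) * 2**het
        )
        probs[het] = weight
    total = sum(probs.values())
    probs = {h: w / total for h, w in probs.items()}
    obs = probs[n1]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


# ------------------------------------------------------- haplotype-EM oracle

def _hap_cells(p):
    pAB, pAb, paB, pab = p
    return np.array(
        [
            [pab**2, 2 * paB * pab, paB**2],
            [2 * pAb * pab, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB],
            [pAb**2, 2 * pAB * pAb, pAB**2],
        ]
    )


def brute_ld_r2(table, n_restarts=50, seed=0):
    """r^2 via direct likelihood maximization over the haplotype simplex.

    Softmax parametrization, multiple random restarts, best likelihood
    wins.  Independent of the EM code path under test.
    """
    table = np.asarray(table, dtype=float)
    rng = np.random.default_rng(seed)

    def nll(theta):
        e = np.exp(theta - theta.max())
        p = e / e.sum()
        cells = np.maximum(_hap_cells(p), 1e-300)
        return -(table * np.log(cells)).sum()

    best = None
    for k in range(n_restarts):
        x0 = np.zeros(4) if k == 0 else rng.normal(scale=2.0, size=4)
        res = minimize(nll, x0, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000))
        if best is None or res.fun < best.fun:
            best = res
    e = np.exp(best.x - best.x.max())
    pAB, pAb, paB, pab = e / e.sum()
    pA = pAB + pAb
    pB = pAB + paB
    D = pAB - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


# ------------------------------------------------------------- Cox oracles

def prentice_partial_loglik(beta, time, event, subcohort, x, ties="breslow"):
    """Definition-level Prentice partial likelihood, one covariate."""
    ll = 0.0
    ev_times = sorted({t for t, e in zip(time, event) if e})
    for t in ev_times:
        deaths = [i for i in range(len(time)) if event[i] and time[i] == t]
        risk = [
            i
            for i in range(len(time))
            if (subcohort[i] and time[i] >= t)
            or (not subcohort[i] and event[i] and time[i] == t)
        ]
        wr = [np.exp(beta * x[i]) for i in risk]
        wd = [np.exp(beta * x[i]) for i in deaths]
        d = len(deaths)
        for l, i in enumerate(deaths):
            ll += beta * x[i]
            if ties == "efron":
                ll -= np.log(sum(wr) - (l / d) * sum(wd))
            else:
                ll -= np.log(sum(wr))
    return ll


def grid_cox_beta(time, event, subcohort, x, ties="breslow", lo=-5, hi=5):
    res = minimize_scalar(
        lambda b: -prentice_partial_loglik(b, time, event, subcohort, x, ties),
        bounds=(lo, hi),
        method="bounded",
        options=dict(xatol=1e-10),
    )
    return float(res.x)


# --------------------------------------------------------------- BH oracle

def brute_bh_reject(pvals, q):
    """BH step-up decisions by exhaustive threshold search."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    best_thresh = -1.0
    for cand in p:
        k = (p <= cand).sum()
        if cand <= q * k / m and cand > best_thresh:
            best_thresh = cand
    return p <= best_thresh if best_thresh >= 0 else np.zeros(m, bool)
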