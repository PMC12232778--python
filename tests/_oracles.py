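"""Independent brute-force reference implementations used only by tests.

These are deliberately written in a different style from the package
(exhaustive loops, grid searches, naive graph traversal) so that agreement
is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Binomial-logistic LRT by direct likelihood maximization on a grid
# ---------------------------------------------------------------------------


def _binom_loglik(k, n, p):
    return float(np.sum(k * math.log(p) + (n - k) * math.log(1.0 - p)))


def _grid_maximize(k, n, lo=1e-6, hi=1.0 - 1e-6, rounds=6, points=200):
    """Maximize a one-proportion binomial log-likelihood by iterative grid
    refinement (no calculus, no Newton)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    best_p, best_ll = None, -np.inf
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        lls = [_binom_loglik(k, n, p) for p in grid]
        i = int(np.argmax(lls))
        if lls[i] > best_ll:
            best_ll, best_p = lls[i], grid[i]
        span = (hi - lo) / points
        lo = max(1e-9, grid[i] - span)
        hi = min(1.0 - 1e-9, grid[i] + span)
    return best_p, best_ll


def grid_lrt(k_case, n_case, k_ctrl, n_ctrl):
    """LRT statistic of the two-proportion binomial model vs pooled, each
    arm maximized independently on a refined grid."""
    _, ll_case = _grid_maximize(k_case, n_case)
    _, ll_ctrl = _grid_maximize(k_ctrl, n_ctrl)
    k_all = np.concatenate([np.atleast_1d(k_case), np.atleast_1d(k_ctrl)])
    n_all = np.concatenate([np.atleast_1d(n_case), np.atleast_1d(n_ctrl)])
    _, ll_pool = _grid_maximize(k_all, n_all)
    return max(0.0, 2.0 * (ll_case + ll_ctrl - ll_pool))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up
# ---------------------------------------------------------------------------


def bh_stepup(p_values):
    """Textbook step-up: q_(i) = min_{j >= i} p_(j) * m / j, in input order."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# GO-DAG clustering reference (components -> split -> re-merge)
# ---------------------------------------------------------------------------


def _edges_undirected(terms, parents):
    """parents: dict term -> set of parent terms (full ontology)."""
    terms = set(terms)
    adj = {t: set() for t in terms}
    for t in terms:
        for u in terms:
            if u in parents.get(t, set()) or t in parents.get(u, set()):
                adj[t].add(u)
                adj[u].add(t)
    return adj


def _bfs_components(terms, parents):
    adj = _edges_undirected(terms, parents)
    seen = set()
    comps = []
    for start in sorted(terms):
        if start in seen:
            continue
        queue = [start]
        comp = set()
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(comp)
    return sorted(comps, key=min)


def _descendants(term, parents, universe):
    """All terms below ``term`` (reachable by repeatedly following child
    links), found by scanning the whole ontology naively."""
    out = set()
    changed = True
    while changed:
        changed = False
        for t in universe:
            if t == term or t in out:
                continue
            if parents.get(t, set()) & (out | {term}):
                out.add(t)
                changed = True
    return out


def _depth(term, parents):
    level = 0
    frontier = {term}
    while frontier:
        if any(not parents.get(t) for t in frontier):
            return level
        nxt = set()
        for t in frontier:
            nxt |= parents.get(t, set())
        frontier = nxt
        level += 1
    return level


def reference_gograph(terms, parents, annotation, limit):
    """Full reference pipeline; returns a sorted list of frozensets."""
    universe = set(parents) | {p for ps in parents.values() for p in ps}
    comps = _bfs_components(set(terms), parents)
    removed = []
    done = []
    work = list(comps)
    while work:
        work.sort(key=lambda c: (-len(c), min(c)))
        cl = work.pop(0)
        if len(cl) < limit:
            done.append(cl)
            continue
        scored = sorted(
            cl, key=lambda t: (-len(_descendants(t, parents, universe) & cl),
                               _depth(t, parents), t))
        top = scored[0]
        removed.append(top)
        rest = cl - {top}
        if rest:
            work.extend(_bfs_components(rest, parents))
    clusters = sorted(done, key=min)
    clusters = [set(c) for c in clusters]
    for term in removed:
        neighbors = set(parents.get(term, set()))
        for t in universe:
            if term in parents.get(t, set()):
                neighbors.add(t)
        cands = [c for c in clusters if len(c) < limit and c & neighbors]
        if not cands:
            clusters.append({term})
            continue

        def jaccard(c):
            tset = set(annotation.get(term, set()))
            cset = set()
            for mtem in c:
                cset |= set(annotation.get(mtem, set()))
            u = tset | cset
            return len(tset & cset) / len(u) if u else 0.0

        best = sorted(cands, key=lambda c: (-jaccard(c), len(c), min(c)))[0]
        best.add(term)
    return sorted((frozenset(c) for c in clusters), key=min)


# ---------------------------------------------------------------------------
# Misc small oracles
# ---------------------------------------------------------------------------


def quadratic_overlap(loci, features):
    """O(n*m) half-open overlap flags."""
    flags = []
    for chrom, s, e in loci:
        hit = any(chrom == fc and s < fe and fs < e
                  for fc, fs, fe in features)
        flags.append(hit)
    return flags


def pca_scores_eig(X):
    """PC scores of rows of X via explicit covariance eigendecomposition."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return Xc @ vecs[:, order]
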