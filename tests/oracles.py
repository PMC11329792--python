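"""Independent brute-force oracles for the structural network measures.

Everything here is deliberately naive: explicit loops, exhaustive path
enumeration, and closed-form chain formulas, sharing no code with the
implementation under test.
"""

import numpy as np


def clean(w):
    a = np.where(np.isnan(w), 0.0, np.asarray(w, float)).copy()
    np.fill_diagonal(a, 0.0)
    return a


def all_simple_paths(a, i, j):
    """Yield every simple path i -> j as a list of nodes."""
    n = a.shape[0]

    def extend(path):
        last = path[-1]
        if last == j:
            yield list(path)
            return
        for nxt in range(n):
            if a[last, nxt] > 0 and nxt not in path:
                yield from extend(path + [nxt])

    yield from extend([i])


def shortest_path_oracle(a, i, j, cost):
    """(best_cost, best_path) by exhaustive enumeration; cost maps (u,v)->real."""
    best, best_path = np.inf, None
    for path in all_simple_paths(a, i, j):
        c = sum(cost(u, v) for u, v in zip(path[:-1], path[1:]))
        if c < best:
            best, best_path = c, path
    return best, best_path


def cosine_oracle(w, i, j):
    a = clean(w)
    u = a[i].copy()
    v = a[j].copy()
    u[[i, j]] = 0.0
    v[[i, j]] = 0.0
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(u @ v / (nu * nv))


def matching_oracle(w, i, j):
    a = clean(w)
    num = den = 0.0
    for k in range(a.shape[0]):
        if k in (i, j):
            continue
        den += a[i, k] + a[j, k]
        if a[i, k] > 0 and a[j, k] > 0:
            num += a[i, k] + a[j, k]
    return num / den if den > 0 else np.nan


def search_info_oracle(w, i, j):
    """-log2 of the walker probability along the 1/w shortest path, averaged
    over the two directions."""
    a = clean(w)
    s = a.sum(axis=1)

    def one_way(src, dst):
        _, path = shortest_path_oracle(a, src, dst, lambda u, v: 1.0 / a[u, v])
        if path is None:
            return np.nan
        prob = 1.0
        for u, v in zip(path[:-1], path[1:]):
            prob *= a[u, v] / s[u]
        return -np.log2(prob)

    return (one_way(i, j) + one_way(j, i)) / 2.0


def path_transitivity_oracle(w, i, j):
    a = clean(w)
    _, path = shortest_path_oracle(a, i, j, lambda u, v: 1.0 / a[u, v])
    if path is None:
        return np.nan
    vals = []
    for x in range(len(path)):
        for y in range(x + 1, len(path)):
            vals.append(matching_oracle(w, path[x], path[y]))
    return float(np.mean(vals))


def mfpt_oracle(w):
    """Symmetrized MFPT from the fundamental-matrix formula
    Z = (I - P + 1 pi)^-1, m_ij = (Z_jj - Z_ij) / pi_j."""
    a = clean(w)
    n = a.shape[0]
    s = a.sum(axis=1)
    p = a / s[:, None]
    pi = s / s.sum()  # stationary law of a reversible walk
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    m = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            m[i, j] = (z[j, j] - z[i, j]) / pi[j]
    out = (m + m.T) / 2.0
    np.fill_diagonal(out, np.nan)
    return out


def navigation_oracle(w, dist, lengths=None):
    """Step-by-step greedy navigation simulator (independent of the library)."""
    a = clean(w)
    n = a.shape[0]
    d = clean(dist)
    hops = np.full((n, n), np.nan)
    tot = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            seen = [i]
            cur = i
            length = 0.0
            while True:
                nbrs = [k for k in range(n) if a[cur, k] > 0]
                if not nbrs:
                    break
                best = min(nbrs, key=lambda k: (d[k, j] if k != j else 0.0, k))
                if best in seen:
                    break
                if lengths is not None:
                    length += lengths[cur, best]
                seen.append(best)
                cur = best
                if cur == j:
                    hops[i, j] = len(seen) - 1
                    tot[i, j] = length
                    break
                if len(seen) > n:
                    break
    return hops, tot


def path_length_oracle(w, lengths, i, j):
    a = clean(w)
    best, _ = shortest_path_oracle(a, i, j, lambda u, v: lengths[u, v])
    return best if np.isfinite(best) else np.nan


def hop_count_oracle(w, i, j):
    """Frontier-expansion BFS written independently."""
    a = clean(w) > 0
    frontier = {i}
    seen = {i}
    hops = 0
    while frontier:
        if j in frontier:
            return hops
        hops += 1
        frontier = {
            k for f in frontier for k in range(a.shape[0]) if a[f, k] and k not in seen
        }
        seen |= frontier
    return np.nan
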