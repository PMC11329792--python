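"""Group structural connectivity and the 13 structural network measures.

Subject-level streamline count/length matrices are aggregated into group
SC-Count and SC-Length matrices (volume-normalized by the geometric mean
volume of the two parcels, optionally zero-thresholded or length-weighted),
and the full stack of weighted network measures is derived from them:

count, length, Euclidean distance, cosine similarity of connection profiles,
flow graph, matching index, navigation count/length, path transitivity,
search information, mean first passage time, shortest-path length (mm) and
minimum hop count.

Conventions (recorded in each matrix's ``meta``):

* edge cost for shortest-path based measures is ``1 / weight`` on the
  aggregated count matrix, the prevailing convention in weighted connectome
  analysis;
* the flow graph is the continuous-time random-walk propagator
  ``diag(s) @ expm(t (P - I))`` with ``P = S^-1 W`` at ``t = 1``;
* inherently directed measures (navigation, search information, MFPT) are
  symmetrized by the arithmetic mean of the two directions;
* navigation failures and unreachable pairs are missing (NaN), not zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, shortest_path

from .atlas import ParcelAtlas, euclidean_distance_matrix
from .matrix import ConnectivityMatrix

__all__ = [
    "AggregationOptions",
    "SCStack",
    "aggregate_counts",
    "aggregate_lengths",
    "cosine_profiles",
    "matching_index",
    "flow_graph",
    "navigate",
    "search_information",
    "path_transitivity",
    "mean_first_passage_time",
    "shortest_path_length_mm",
    "min_hop_count",
    "strength",
    "build_sc_stack",
]

#: canonical measure order of the stack
SC_MEASURES = (
    "count",
    "length",
    "eucl_dist",
    "cosine",
    "flow_graph",
    "matching_index",
    "nav_count",
    "nav_length",
    "path_transitivity",
    "search_info",
    "mfpt",
    "path_length",
    "path_count",
)


@dataclass
class AggregationOptions:
    """Subject-to-group aggregation choices.

    Defaults reproduce the reference analysis: no zeroing threshold, no
    length weighting, geometric-mean volume normalization.
    """

    zero_threshold_fraction: float = 0.0
    length_weighting: str = "none"  # {"none", "multiply", "divide"}
    volume_normalize: bool = True

    def __post_init__(self):
        if not (0.0 <= self.zero_threshold_fraction < 1.0):
            raise ValueError("zero_threshold_fraction must be in [0, 1)")
        if self.length_weighting not in ("none", "multiply", "divide"):
            raise ValueError(f"unknown length_weighting {self.length_weighting!r}")


@dataclass
class SCStack:
    """Named map of the structural measures, all in one atlas order."""

    measures: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> ConnectivityMatrix:
        return self.measures[key]

    def __contains__(self, key) -> bool:
        return key in self.measures

    @property
    def names(self):
        return list(self.measures)

    @property
    def n(self) -> int:
        return next(iter(self.measures.values())).n


def _clean(m, require_nonneg=False) -> np.ndarray:
    """Dense float array with diagonal and NaN as 0 (profile convention)."""
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    a = np.where(np.isnan(v), 0.0, v).astype(float)
    np.fill_diagonal(a, 0.0)
    if require_nonneg and (a < 0).any():
        raise ValueError("matrix must be nonnegative")
    return a


def _require_connected(a: np.ndarray) -> None:
    ncomp, _ = connected_components(csr_matrix(a > 0), directed=False)
    if ncomp != 1:
        raise ValueError(f"graph is disconnected ({ncomp} components)")


def _as_stack(subject_mats) -> np.ndarray:
    arrs = [
        (m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float))
        for m in subject_mats
    ]
    return np.stack(arrs)


def aggregate_counts(
    subject_counts,
    atlas: ParcelAtlas,
    options: AggregationOptions | None = None,
    lengths: ConnectivityMatrix | None = None,
) -> ConnectivityMatrix:
    """Group streamline-count matrix ("sc_count").

    Mean count over subjects, divided by the geometric mean volume
    ``sqrt(vol_i * vol_j)`` of the two parcels; a pair is zeroed when the
    fraction of subjects with a nonzero count is ``<= zero_threshold_fraction``
    (default 0, i.e. a single connected subject keeps the pair).  Optional
    weighting multiplies or divides by the aggregated mean streamline length.
    """
    options = options or AggregationOptions()
    if len(subject_counts) == 0:
        raise ValueError("need at least one subject")
    stack = _as_stack(subject_counts)
    if stack.shape[1] != atlas.n:
        raise ValueError("subject matrices do not match atlas size")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
        mean = np.nanmean(stack, axis=0)
        frac_nonzero = np.mean(np.nan_to_num(stack) > 0, axis=0)
    mean = np.where(frac_nonzero <= options.zero_threshold_fraction, 0.0, mean)
    if options.volume_normalize:
        vols = atlas.volumes
        if np.any(vols <= 0):
            raise ValueError("parcel volumes must be positive")
        mean = mean / np.sqrt(np.outer(vols, vols))
    if options.length_weighting != "none":
        if lengths is None:
            raise ValueError("length weighting requested but no length matrix given")
        lw = np.where(np.isnan(lengths.values), 1.0, lengths.values)
        lw[lw == 0] = 1.0
        mean = mean * lw if options.length_weighting == "multiply" else mean / lw
    meta = {
        "zero_threshold_fraction": options.zero_threshold_fraction,
        "length_weighting": options.length_weighting,
        "volume_normalize": options.volume_normalize,
        "n_subjects": len(subject_counts),
    }
    return ConnectivityMatrix(mean, "sc_count", meta=meta)


def aggregate_lengths(subject_lengths, subject_counts) -> ConnectivityMatrix:
    """Group mean streamline length ("sc_length").

    Per pair, the arithmetic mean over the subjects in which the pair is
    structurally connected (count > 0); pairs connected in no subject are
    missing.
    """
    ls = _as_stack(subject_lengths)
    cs = _as_stack(subject_counts)
    if ls.shape != cs.shape:
        raise ValueError("length and count stacks differ in shape")
    connected = (cs > 0) & ~np.isnan(ls)
    total = np.where(connected, ls, 0.0).sum(axis=0)
    nsub = connected.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(nsub > 0, total / np.maximum(nsub, 1), np.nan)
    return ConnectivityMatrix(out, "sc_length")


def cosine_profiles(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Cosine similarity of connection profiles ("cosine"/"fc_cosine").

    For a pair (i, j) the profiles are rows i and j with entries i and j
    masked to 0 (self-connections and the mutual edge do not inform profile
    similarity).  All-zero profiles yield missing entries.
    """
    a = _clean(m)
    gram = a @ a.T
    sq = a**2
    r = sq.sum(axis=1)
    norm2_i = r[:, None] - sq  # ||row_i with (i,j) masked||^2
    norm2_j = r[None, :] - sq.T
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(norm2_i * norm2_j)
        out = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), np.nan)
    out = np.clip(out, -1.0, 1.0)
    return ConnectivityMatrix(out, "cosine")


def matching_index(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Weighted matching index, values in [0, 1].

    ``M(i,j) = sum_{k != i,j} (w_ik + w_jk) [w_ik>0 and w_jk>0]
             / sum_{k != i,j} (w_ik + w_jk)``.
    """
    a = _clean(m, require_nonneg=True)
    b = (a > 0).astype(float)
    num = a @ b.T + b @ a.T
    r = a.sum(axis=1)
    den = r[:, None] + r[None, :] - 2.0 * a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ConnectivityMatrix(np.clip(out, 0.0, 1.0), "matching_index")


def flow_graph(m: ConnectivityMatrix, t: float = 1.0) -> ConnectivityMatrix:
    """Continuous-time random-walk flow graph at diffusion time ``t``.

    With ``P = S^-1 W`` (S the diagonal strength matrix), the flow is
    ``F(t) = diag(s) expm(t (P - I))``, symmetrized as ``(F + F^T)/2``.
    """
    a = _clean(m, require_nonneg=True)
    _require_connected(a)
    s = a.sum(axis=1)
    p = a / s[:, None]
    f = np.diag(s) @ expm(t * (p - np.eye(len(s))))
    f = (f + f.T) / 2.0
    return ConnectivityMatrix(f, "flow_graph", meta={"t": t})


def navigate(
    counts: ConnectivityMatrix,
    dist: ConnectivityMatrix,
    lengths: ConnectivityMatrix | None = None,
):
    """Greedy geometric navigation on the structural graph.

    From the current node, step to the structurally connected neighbor
    closest (Euclidean) to the target; a dead end or revisit is a failed
    route and the pair is missing.  Returns ``(nav_count, nav_length)``
    symmetrized by the mean of the two directions; ``nav_length`` sums mean
    streamline lengths along the route (requires ``lengths``).
    """
    a = _clean(counts, require_nonneg=True)
    d = np.where(np.isnan(dist.values), np.inf, dist.values)
    np.fill_diagonal(d, 0.0)  # the target itself is at distance 0
    lv = None if lengths is None else lengths.values
    n = a.shape[0]
    neighbors = [np.flatnonzero(a[i] > 0) for i in range(n)]
    hops = np.full((n, n), np.nan)
    wlen = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cur, visited, h, L, ok = i, {i}, 0, 0.0, True
            while cur != j:
                nbr = neighbors[cur]
                if nbr.size == 0:
                    ok = False
                    break
                nxt = int(nbr[np.argmin(d[nbr, j])])
                if nxt in visited:
                    ok = False
                    break
                if lv is not None:
                    step = lv[cur, nxt]
                    L += 0.0 if np.isnan(step) else step
                visited.add(nxt)
                cur = nxt
                h += 1
                if h > n:
                    ok = False
                    break
            if ok:
                hops[i, j] = h
                if lv is not None:
                    wlen[i, j] = L
    nav_count = ConnectivityMatrix(hops, "nav_count", directed=True).symmetrized()
    nav_length = ConnectivityMatrix(wlen, "nav_length", directed=True).symmetrized()
    return nav_count, nav_length


def _shortest_path_tree(a: np.ndarray):
    """Dijkstra with 1/weight edge costs; returns (cost matrix, predecessors)."""
    with np.errstate(divide="ignore"):
        cost = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    return dijkstra(csr_matrix(cost), directed=False, return_predecessors=True)


def _walk(pred_row: np.ndarray, i: int, j: int):
    """Node sequence of the shortest path i -> j, or None if unreachable."""
    if i == j:
        return [i]
    path = [j]
    cur = j
    while cur != i:
        cur = pred_row[cur]
        if cur < 0:
            return None
        path.append(int(cur))
    return path[::-1]


def search_information(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Bits needed by a random walker to follow the shortest path.

    ``SI(i->j) = -log2 prod_{(u,v) on sp(i,j)} w_uv / s_u`` with the shortest
    path taken under 1/weight edge costs; symmetrized by averaging the two
    directions.
    """
    a = _clean(m, require_nonneg=True)
    _, pred = _shortest_path_tree(a)
    s = a.sum(axis=1)
    n = a.shape[0]
    si = np.full((n, n), np.nan)
    with np.errstate(divide="ignore"):
        logp = np.where(a > 0, np.log2(np.where(a > 0, a, 1.0)) - np.log2(s)[:, None], np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            path = _walk(pred[i], i, j)
            if path is None:
                continue
            bits = 0.0
            for u, v in zip(path[:-1], path[1:]):
                bits -= logp[u, v]
            si[i, j] = bits
    return ConnectivityMatrix(si, "search_info", directed=True).symmetrized()


def path_transitivity(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Mean matching index over node pairs of the shortest path.

    For a shortest path (under 1/weight costs) visiting nodes n0..nL, the
    value is the mean of ``M(na, nb)`` over all distinct node pairs on the
    path; a direct 2-node path reduces to ``M(i, j)``.
    """
    a = _clean(m, require_nonneg=True)
    mi = matching_index(m).values
    _, pred = _shortest_path_tree(a)
    n = a.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            path = _walk(pred[i], i, j)
            if path is None:
                continue
            vals = [mi[u, v] for ix, u in enumerate(path) for v in path[ix + 1:]]
            out[i, j] = out[j, i] = float(np.mean(vals))
    return ConnectivityMatrix(out, "path_transitivity")


def mean_first_passage_time(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Expected steps of the random walk ``P = S^-1 W`` to first reach j from i.

    Solved per target from the absorbing-chain linear system
    ``(I - P_{-j}) h = 1``; symmetrized by the mean of the two directions.
    """
    a = _clean(m, require_nonneg=True)
    _require_connected(a)
    n = a.shape[0]
    p = a / a.sum(axis=1)[:, None]
    out = np.full((n, n), np.nan)
    idx = np.arange(n)
    for j in range(n):
        keep = idx != j
        sub = p[np.ix_(keep, keep)]
        h = np.linalg.solve(np.eye(n - 1) - sub, np.ones(n - 1))
        out[keep, j] = h
    return ConnectivityMatrix(out, "mfpt", directed=True).symmetrized()


def shortest_path_length_mm(
    counts: ConnectivityMatrix, lengths: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Minimal total white-matter length of a path in the count-support graph."""
    a = _clean(counts, require_nonneg=True)
    lv = np.where(np.isnan(lengths.values), 0.0, lengths.values)
    if (lv < 0).any():
        raise ValueError("negative streamline length")
    w = np.where(a > 0, lv, 0.0)
    if ((a > 0) & (lv <= 0)).any():
        raise ValueError("zero/undefined length on a structurally connected pair")
    d = dijkstra(csr_matrix(w), directed=False)
    d[np.isinf(d)] = np.nan
    return ConnectivityMatrix(d, "path_length")


def min_hop_count(counts: ConnectivityMatrix) -> ConnectivityMatrix:
    """Minimum number of end-to-end streamline connections linking two parcels."""
    a = (_clean(counts) > 0).astype(float)
    d = shortest_path(csr_matrix(a), method="D", directed=False, unweighted=True)
    d[np.isinf(d)] = np.nan
    return ConnectivityMatrix(d, "path_count")


def strength(m: ConnectivityMatrix) -> np.ndarray:
    """Node strength: row sums excluding the diagonal (missing treated as 0)."""
    return _clean(m).sum(axis=1)


def build_sc_stack(
    subject_counts,
    subject_lengths,
    atlas: ParcelAtlas,
    options: AggregationOptions | None = None,
    flow_t: float = 1.0,
) -> SCStack:
    """Aggregate subjects and compute all 13 structural measures."""
    lengths = aggregate_lengths(subject_lengths, subject_counts)
    counts = aggregate_counts(subject_counts, atlas, options, lengths=lengths)
    dist = euclidean_distance_matrix(atlas)
    nav_count, nav_length = navigate(counts, dist, lengths)
    stack = SCStack(
        {
            "count": counts,
            "length": lengths,
            "eucl_dist": dist,
            "cosine": cosine_profiles(counts),
            "flow_graph": flow_graph(counts, t=flow_t),
            "matching_index": matching_index(counts),
            "nav_count": nav_count,
            "nav_length": nav_length,
            "path_transitivity": path_transitivity(counts),
            "search_info": search_information(counts),
            "mfpt": mean_first_passage_time(counts),
            "path_length": shortest_path_length_mm(counts, lengths),
            "path_count": min_hop_count(counts),
        }
    )
    return stack
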