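"""Macroscale gradient maps and their correlation with SF correspondence.

A gradient map assigns one scalar per parcel: a diffusion-map embedding
component of the FC affinity, the first principal component of functional
activation, activation-weighted semantic dispersion of a parcel's top terms
("functional diversity", low in unimodal and high in transmodal cortex),
lexicon scores (concreteness, category proportions), cortical thickness, or
a plain Cartesian centroid coordinate.  Gradients are compared to the SF map
with R2 and Spearman rank correlation against a permutation null that
randomly reassigns the gradient values to parcels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import eigh

from .atlas import ParcelAtlas
from .functional import ActivationMatrix
from .matrix import ConnectivityMatrix
from .regression import fit_ols

__all__ = [
    "DiffusionSpec",
    "GradientMap",
    "CorrelationReport",
    "TopTermsProfile",
    "diffusion_map",
    "spectral_clusters",
    "eigengap_k",
    "top_terms",
    "functional_diversity",
    "lexical_gradient",
    "activation_pca_first",
    "correlate",
    "vif",
    "thickness_map",
    "axis_coordinate",
]

logger = logging.getLogger(__name__)


@dataclass
class DiffusionSpec:
    t: int = 1  # diffusion time; M^t is the powered Markov matrix
    n_components: int = 10

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("diffusion time t must be >= 1")


@dataclass
class GradientMap:
    values: np.ndarray
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


@dataclass
class CorrelationReport:
    r2: float
    spearman_r: float
    p_null: float
    n_permutations: int
    seed: int
    n: int


@dataclass
class TopTermsProfile:
    """Per-parcel top-k activated terms (indices) and their weights."""

    term_indices: list  # arrays of term indices, weights descending
    weights: list
    k: int


def _affinity(fc: ConnectivityMatrix) -> np.ndarray:
    """NaN-free nonnegative affinity with zero diagonal (no self-edges)."""
    w = np.where(np.isnan(fc.values), 0.0, fc.values).copy()
    np.fill_diagonal(w, 0.0)
    if (w < 0).any():
        logger.warning("negative affinity entries clipped to 0")
        w = np.clip(w, 0.0, None)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    ncomp, _ = connected_components(csr_matrix(w > 0), directed=False)
    if ncomp != 1:
        raise ValueError(f"affinity graph is disconnected ({ncomp} components)")
    return w


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: the largest-magnitude entry is positive."""
    return -v if v[np.argmax(np.abs(v))] < 0 else v


def diffusion_map(fc: ConnectivityMatrix, spec: DiffusionSpec | None = None) -> np.ndarray:
    """Diffusion-map embedding of the FC affinity.

    Right eigenvectors of the powered Markov matrix ``M^t``, ``M = D^-1 W``,
    ordered by eigenvalue magnitude, scaled by ``lambda^t``, with the
    trivial constant eigenvector (eigenvalue 1) dropped.  Returns an
    ``(n, n_components)`` array; column 0 is the principal gradient.
    """
    spec = spec or DiffusionSpec()
    w = _affinity(fc)
    d = w.sum(axis=1)
    dis = 1.0 / np.sqrt(d)
    a = (w * dis[:, None]) * dis[None, :]  # D^-1/2 W D^-1/2, symmetric
    vals, vecs = eigh(a)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of M; the first is constant (eigenvalue 1) -> dropped
    psi = dis[:, None] * vecs
    ncomp = min(spec.n_components, len(vals) - 1)
    comps = np.column_stack(
        [_fix_sign(psi[:, k + 1]) * vals[k + 1] ** spec.t for k in range(ncomp)]
    )
    return comps


def eigengap_k(fc: ConnectivityMatrix, max_k: int = 10) -> int:
    """Cluster count at the largest gap in sorted graph-Laplacian eigenvalues."""
    w = _affinity(fc)
    d = w.sum(axis=1)
    dis = 1.0 / np.sqrt(d)
    lap = np.eye(len(d)) - (w * dis[:, None]) * dis[None, :]
    vals = np.sort(eigh(lap, eigvals_only=True))
    upper = min(max_k, len(vals) - 1)
    gaps = np.diff(vals[: upper + 1])
    return int(np.argmax(gaps)) + 1


def spectral_clusters(fc: ConnectivityMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Graph-Laplacian spectral clustering with the FC as precomputed affinity."""
    w = _affinity(fc)
    n = w.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of parcels {n}")
    if k == 1:
        return np.zeros(n, int)
    from sklearn.cluster import SpectralClustering

    model = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    return model.fit_predict(w)


def top_terms(fa: ActivationMatrix, k: int = 10) -> TopTermsProfile:
    """Per parcel, the k largest-activation terms (positive weights only).

    Parcels with fewer than k nonzero terms keep all their nonzero terms;
    ties are broken by term order (stable sort).
    """
    idx_lists, weight_lists = [], []
    short = 0
    for p in range(fa.n_parcels):
        row = fa.values[p]
        nz = np.flatnonzero(row > 0)
        order = nz[np.argsort(-row[nz], kind="stable")][:k]
        if order.size < k:
            short += 1
        idx_lists.append(order)
        weight_lists.append(row[order])
    if short:
        logger.info("%d parcel(s) had fewer than %d nonzero terms", short, k)
    return TopTermsProfile(term_indices=idx_lists, weights=weight_lists, k=k)


def functional_diversity(profile: TopTermsProfile, embeddings: np.ndarray) -> GradientMap:
    """Activation-weighted semantic dispersion of each parcel's top terms.

    With weights w_i and embeddings e_i, the weighted centroid is
    ``c = sum(w_i e_i) / sum(w_i)`` and the diversity is
    ``sum(w_i ||e_i - c||) / sum(w_i)``.  Terms without an embedding (NaN
    rows) are dropped and the weights renormalized.
    """
    emb = np.asarray(embeddings, float)
    valid = np.all(np.isfinite(emb), axis=1)
    out = np.full(len(profile.term_indices), np.nan)
    dropped = 0
    for p, (ti, w) in enumerate(zip(profile.term_indices, profile.weights)):
        keep = valid[ti]
        if keep.sum() < ti.size:
            dropped += int(ti.size - keep.sum())
        ti, w = ti[keep], w[keep]
        if ti.size == 0 or w.sum() <= 0:
            continue
        e = emb[ti]
        c = (w[:, None] * e).sum(axis=0) / w.sum()
        out[p] = float((w * np.linalg.norm(e - c, axis=1)).sum() / w.sum())
    if dropped:
        logger.info("dropped %d term occurrences without embeddings", dropped)
    return GradientMap(out, "functional_diversity", {"k": profile.k})


def lexical_gradient(
    profile: TopTermsProfile,
    scores: np.ndarray,
    mode: str = "mean_score",
    name: str | None = None,
) -> GradientMap:
    """Lexicon-weighted gradient over each parcel's top terms.

    ``mode="mean_score"``: activation-weighted mean of per-term scores
    (terms missing from the lexicon, NaN, are omitted and weights
    renormalized).  ``mode="category_proportion"``: ``scores`` is a 0/1
    membership vector and the value is the weighted fraction of covered top
    terms in the category.  Parcels with no covered terms are missing.
    """
    if mode not in ("mean_score", "category_proportion"):
        raise ValueError(f"unknown mode {mode!r}")
    s = np.asarray(scores, float)
    out = np.full(len(profile.term_indices), np.nan)
    for p, (ti, w) in enumerate(zip(profile.term_indices, profile.weights)):
        keep = np.isfinite(s[ti])
        ti, w = ti[keep], w[keep]
        if ti.size == 0 or w.sum() <= 0:
            continue
        out[p] = float((w * s[ti]).sum() / w.sum())
    return GradientMap(out, name or mode, {"mode": mode, "k": profile.k})


def activation_pca_first(fa: ActivationMatrix) -> GradientMap:
    """Parcel scores on the first principal axis of the activation matrix.

    Columns (terms) are centered across parcels before the decomposition.
    """
    if fa.n_terms < 2:
        raise ValueError("need at least 2 terms for PCA")
    x = fa.values - fa.values.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("constant activation matrix; PCA undefined")
    from sklearn.decomposition import PCA

    scores = PCA(n_components=1, svd_solver="full").fit_transform(x)[:, 0]
    return GradientMap(_fix_sign(scores), "activation_pc1")


def correlate(
    gradient, sfmap, n_perm: int = 10000, seed: int = 0
) -> CorrelationReport:
    """R2, Spearman r, and permutation-null p between a gradient and the SF map.

    The null randomly reassigns the gradient values to parcels; the add-one
    estimator ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)`` keeps p in
    (0, 1].
    """
    g = np.asarray(getattr(gradient, "values", gradient), float)
    f = np.asarray(getattr(sfmap, "values", sfmap), float)
    ok = np.isfinite(g) & np.isfinite(f)
    if ok.sum() < 10:
        raise ValueError("need at least 10 jointly non-missing parcels")
    g, f = g[ok], f[ok]
    if np.ptp(g) == 0 or np.ptp(f) == 0:
        raise ValueError("constant input; correlation undefined")
    fit = fit_ols(f, g[:, None])
    rho = float(stats.spearmanr(g, f).statistic)
    rg = stats.rankdata(g)
    rf = stats.rankdata(f)
    rf_c = rf - rf.mean()
    rg_c = rg - rg.mean()
    denom = np.sqrt((rg_c**2).sum() * (rf_c**2).sum())
    rng = np.random.default_rng(seed)
    n = len(g)
    exceed = 0
    block = 2000
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        perms = rng.permuted(np.tile(rg_c, (b, 1)), axis=1)
        r_perm = (perms @ rf_c) / denom
        exceed += int((np.abs(r_perm) >= abs(rho) - 1e-12).sum())
    p_null = (1 + exceed) / (1 + n_perm)
    return CorrelationReport(
        r2=fit.r2, spearman_r=rho, p_null=p_null, n_permutations=n_perm, seed=seed, n=n
    )


def vif(maps) -> np.ndarray:
    """Variance inflation factor of each gradient map given the others."""
    arrs = [np.asarray(getattr(m, "values", m), float) for m in maps]
    if len(arrs) < 2:
        raise ValueError("need at least 2 maps")
    X = np.column_stack(arrs)
    ok = np.all(np.isfinite(X), axis=1)
    X = X[ok]
    out = np.empty(X.shape[1])
    for i in range(X.shape[1]):
        others = np.delete(X, i, axis=1)
        try:
            fit = fit_ols(X[:, i], others)
            out[i] = np.inf if fit.r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - fit.r2)
        except ValueError:
            out[i] = np.inf
    return out


def thickness_map(subject_thickness, atlas: ParcelAtlas) -> GradientMap:
    """Mean cortical thickness per parcel across subjects.

    Thickness analyses exclude callosal parcels, so a with-callosum atlas
    variant is rejected.
    """
    if atlas.variant == "with-callosum":
        raise ValueError("thickness analyses require the without-callosum atlas variant")
    stack = np.stack([np.asarray(t, float) for t in subject_thickness])
    if stack.shape[1] != atlas.n:
        raise ValueError("thickness vectors do not match atlas size")
    return GradientMap(stack.mean(axis=0), "thickness", {"n_subjects": stack.shape[0]})


_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


def axis_coordinate(atlas: ParcelAtlas, axis: str) -> GradientMap:
    """Centroid coordinate along a named anatomical axis (mm)."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    return GradientMap(atlas.centroids[:, _AXES[axis]], f"{axis}_coordinate")
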