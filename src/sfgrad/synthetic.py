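"""Synthetic datasets with a planted, recoverable SF coupling gradient.

Every stage of the pipeline is testable without downloads: the generator
emulates the statistical structure the analysis assumes —

* an atlas of parcels on a jittered ellipsoidal shell, regions assigned by
  spatial octant, log-normal volumes;
* per-subject symmetric streamline counts with Poisson law
  ``lambda_ij = count_scale * exp(-d_ij / distance_scale_mm)`` and mean
  streamline lengths ``d_ij * (1 + eps)`` on connected pairs;
* sparse nonnegative parcel×term activations: each term seeds a parcel —
  "high"-coupling terms activate the seed's strong structural (SC-cosine)
  neighborhood with full amplitude, "low"-coupling terms a contiguous core
  plus a systematic spatial scatter at weaker amplitude, so their
  active-active wiring is diluted toward the brain-wide average.
  Structural activation values taper smoothly to zero at the active-set
  boundary, so in the noise-free limit cosine FC is a smooth function of
  the structural field;
* a per-parcel coupling weight g in [0, 1] (by default a smooth gradient
  along the axial coordinate): each (parcel, term) entry follows the
  structural pattern with probability g_p and is otherwise resampled at the
  same sparsity from random noise, so parcel-wise SF correspondence
  increases with g while per-term sparsity is preserved;
* term embeddings in two Gaussian clusters aligned with the planted classes,
  concreteness scores higher for the "high" cluster, and psychometric
  category labels with class-dependent probabilities;
* cortical thickness decreasing along the axial coordinate and with the
  planted gradient.

A single global seed expands into independent per-component child seeds, so
adding one generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Parcel, ParcelAtlas
from .functional import ActivationMatrix
from .matrix import ConnectivityMatrix
from .predictors import EmbeddingMatrix
from .structural import AggregationOptions, aggregate_counts, cosine_profiles

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_atlas",
    "generate_structural",
    "generate_activation",
    "generate_embeddings_and_lexicons",
    "generate_thickness",
    "generate_dataset",
    "write_dataset",
]

_COMPONENTS = ("atlas", "structural", "activation", "embeddings", "thickness")

_CATEGORIES = ("perceptual", "cognitive", "biological")
# P(category | planted class): structurally aligned functions skew strongly
# perceptual, weakly coupled ones cognitive
_CATEGORY_PROBS = {
    "high": (0.75, 0.10, 0.15),
    "low": (0.05, 0.80, 0.15),
}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic world (defaults are the toy scale)."""

    n_parcels: int = 120
    n_subjects: int = 40
    n_terms: int = 60
    embedding_dim: int = 150
    distance_scale_mm: float = 15.0  # exponential decay length of counts
    count_scale: float = 80.0  # expected count at zero distance
    activation_sparsity: float = 0.25  # fraction of parcels active per term
    coupling_profile: np.ndarray | None = None  # per-parcel g; default axial gradient
    noise_sd: float = 0.35  # multiplicative jitter on activation values
    high_sf_term_fraction: float = 0.8
    seed: int = 0
    # secondary shape parameters
    shell_semiaxes: tuple = (70.0, 85.0, 60.0)  # mm
    shell_jitter_mm: float = 6.0
    low_term_amplitude: float = 0.5  # activation amplitude of low-coupling terms
    low_term_scale_factor: float = 2.0  # spatial diffuseness of low-term clouds
    cluster_separation: float = 4.0  # embedding cluster distance
    length_noise_sd: float = 0.05
    thickness_base_mm: float = 3.6
    thickness_axial_slope: float = 0.6
    thickness_coupling_slope: float = 0.4
    thickness_noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_parcels < 2 or self.n_subjects < 2 or self.n_terms < 2:
            raise ValueError("n_parcels, n_subjects and n_terms must all be >= 2")
        if not (0 < self.activation_sparsity < 1):
            raise ValueError("activation_sparsity must be in (0, 1)")
        if self.coupling_profile is not None:
            g = np.asarray(self.coupling_profile, float)
            if g.shape != (self.n_parcels,) or not np.all(np.isfinite(g)):
                raise ValueError("coupling_profile must be a finite length-n_parcels vector")
            if g.min() < 0 or g.max() > 1:
                raise ValueError("coupling weights must lie in [0, 1]")
            self.coupling_profile = g

    def child_rng(self, component: str) -> np.random.Generator:
        """Independent generator for one component, derived from the seed."""
        idx = _COMPONENTS.index(component)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_COMPONENTS))[idx])


@dataclass
class SyntheticDataset:
    atlas: ParcelAtlas
    subject_counts: list
    subject_lengths: list
    activation: ActivationMatrix
    embeddings: EmbeddingMatrix
    concreteness: pd.Series
    categories: pd.Series
    thickness: np.ndarray
    planted_gradient: np.ndarray
    planted_term_class: pd.Series
    sc_count: ConnectivityMatrix = None
    sc_cosine: ConnectivityMatrix = None


def generate_atlas(config: SyntheticConfig) -> ParcelAtlas:
    """Parcels on a jittered ellipsoidal shell; octant regions; log-normal volumes."""
    rng = config.child_rng("atlas")
    n = config.n_parcels
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    centroids = u * np.asarray(config.shell_semiaxes) + rng.normal(
        scale=config.shell_jitter_mm, size=(n, 3)
    )
    volumes = np.maximum(1.0, np.round(rng.lognormal(mean=np.log(500.0), sigma=0.4, size=n)))
    parcels = []
    for i in range(n):
        octant = "".join("+" if c >= 0 else "-" for c in centroids[i])
        parcels.append(
            Parcel(
                id=i,
                name=f"parcel_{i:04d}",
                region=f"octant_{octant}",
                centroid=tuple(centroids[i]),
                volume=float(volumes[i]),
            )
        )
    return ParcelAtlas(parcels)


def _distances(atlas: ParcelAtlas) -> np.ndarray:
    c = atlas.centroids
    return np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)


def _maxmin_spread(d: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Greedy max-min design: k points mutually far apart (deterministic)."""
    chosen = [start]
    for _ in range(k - 1):
        rest = np.setdiff1d(np.arange(d.shape[0]), chosen)
        chosen.append(int(rest[np.argmax(d[np.ix_(rest, chosen)].min(axis=1))]))
    return np.array(chosen)


def generate_structural(config: SyntheticConfig, atlas: ParcelAtlas):
    """Per-subject Poisson streamline counts and noisy streamline lengths."""
    rng = config.child_rng("structural")
    d = _distances(atlas)
    lam = config.count_scale * np.exp(-d / config.distance_scale_mm)
    n = atlas.n
    iu, ju = np.triu_indices(n, k=1)
    counts, lengths = [], []
    for _ in range(config.n_subjects):
        c = np.zeros((n, n))
        c[iu, ju] = rng.poisson(lam[iu, ju])
        c = c + c.T
        eps = np.abs(rng.normal(scale=config.length_noise_sd, size=(n, n)))
        eps = (eps + eps.T) / 2.0
        length = np.where(c > 0, d * (1.0 + eps), np.nan)
        np.fill_diagonal(c, np.nan)
        np.fill_diagonal(length, np.nan)
        counts.append(ConnectivityMatrix(c, "subject_count"))
        lengths.append(ConnectivityMatrix(length, "subject_length"))
    return counts, lengths


def default_coupling_profile(config: SyntheticConfig, atlas: ParcelAtlas) -> np.ndarray:
    """Smooth planted gradient along the axial (z) coordinate, in [0.3, 1].

    The floor reflects that no cortical territory is fully decoupled from its
    white-matter scaffold; coupling then decreases smoothly from one pole of
    the axial axis to the other.
    """
    z = atlas.centroids[:, 2]
    return 0.3 + 0.7 * (z - z.min()) / (z.max() - z.min())


def default_term_classes(config: SyntheticConfig) -> pd.Series:
    """First ceil(fraction * n_terms) terms are "high", the rest "low"."""
    n_high = int(np.ceil(config.high_sf_term_fraction * config.n_terms))
    names = [f"term_{k:03d}" for k in range(config.n_terms)]
    return pd.Series(
        ["high"] * n_high + ["low"] * (config.n_terms - n_high), index=names, name="class"
    )


def generate_activation(
    config: SyntheticConfig,
    atlas: ParcelAtlas,
    sc_cosine: ConnectivityMatrix,
    planted_gradient: np.ndarray,
    planted_term_class: pd.Series,
) -> ActivationMatrix:
    """Sparse nonnegative activations with the planted coupling structure.

    High-coupling terms activate the structural (SC-cosine) neighborhood of
    a seed parcel with values tapering to zero at the neighborhood boundary;
    low-coupling terms activate a diffuse spatial cloud around their seed at
    reduced amplitude.  Entry (p, k) follows this structural pattern with
    probability ``g_p`` and is otherwise resampled as sparse noise at the
    same sparsity, so each term's expected active fraction equals
    ``activation_sparsity`` for any coupling profile.
    """
    rng = config.child_rng("activation")
    n, n_terms = atlas.n, config.n_terms
    g = np.asarray(planted_gradient, float)
    sim = np.where(np.isnan(sc_cosine.values), 0.0, sc_cosine.values).copy()
    np.fill_diagonal(sim, 1.0)  # a seed belongs to its own neighborhood
    d = _distances(atlas)
    m = max(2, int(round(config.activation_sparsity * n)))
    classes = planted_term_class.to_numpy()
    # High-coupling terms seed the strongly coupled half of the cortex (the
    # planted world is coherent: functions whose activation follows structure
    # live where structure-function coupling is high), on a spatially spread
    # (max-min) design so their neighborhoods tile that cortex evenly.
    # Low-coupling terms seed anywhere.
    n_high = int((classes == "high").sum())
    pool = np.flatnonzero(g >= np.median(g))
    spread = pool[_maxmin_spread(d[np.ix_(pool, pool)], min(n_high, pool.size),
                                 start=int(rng.integers(pool.size)))]
    seeds = np.empty(n_terms, int)
    seeds[classes == "high"] = spread[:n_high]
    low_pool = np.flatnonzero(g < np.median(g))
    if low_pool.size == 0:  # constant coupling profile
        low_pool = np.arange(n)
    seeds[classes != "high"] = rng.choice(low_pool, size=int((classes != "high").sum()))

    S = np.zeros((n, n_terms))
    for k in range(n_terms):
        s = seeds[k]
        if classes[k] == "high":
            order = np.argsort(-sim[:, s], kind="stable")
            support = order[:m]
            tau = sim[order[m], s] if m < n else 0.0
            S[support, k] = (sim[support, s] - tau) / max(1.0 - tau, 1e-12)
        else:
            # structurally scattered: a contiguous core near the seed keeps
            # the term spatially coherent, and the rest of the active set is
            # a systematic spatial scatter (every k-th parcel by distance
            # rank), so active-active wiring is diluted toward the brain-wide
            # average and the fold change stays low
            order = np.argsort(d[:, s], kind="stable")
            m_core = max(2, (2 * m) // 3)
            n_far = m - m_core
            far_ranks = m_core + np.floor(
                np.arange(n_far) / max(n_far, 1) * (n - m_core)
            ).astype(int)
            support = np.concatenate([order[:m_core], order[far_ranks]])
            scale = config.low_term_scale_factor * config.distance_scale_mm
            prof = np.exp(-d[support, s] / scale)
            S[support, k] = config.low_term_amplitude * prof / prof.max()

    # multiplicative value jitter, vanishing as noise_sd -> 0
    jitter = np.maximum(0.0, 1.0 + config.noise_sd * rng.normal(size=S.shape))
    A = S * jitter
    # coupling mixing: parcel p follows the structural pattern for an exact
    # quota of round(g_p * n_terms) terms and is resampled as sparse noise at
    # the same sparsity for the rest (the exact quota avoids binomial noise
    # in each parcel's effective coupling)
    amp = np.where(classes == "high", 1.0, config.low_term_amplitude)[None, :]
    n_resample = np.round((1.0 - g) * n_terms).astype(int)
    keep = np.ones((n, n_terms), bool)
    for p in range(n):
        if n_resample[p] > 0:
            keep[p, rng.choice(n_terms, size=n_resample[p], replace=False)] = False
    noise_active = rng.random((n, n_terms)) < (m / n)
    # noise values are class-neutral: a decoupled parcel samples terms (and
    # hence semantic clusters) indiscriminately, which is what makes its
    # top-term profile semantically diverse
    noise_vals = noise_active * (0.3 + 0.7 * rng.random((n, n_terms)))
    A = np.where(keep, A, noise_vals)
    # no all-zero parcel rows: give such parcels their best structural term
    dead = ~A.any(axis=1)
    if dead.any():
        for p in np.flatnonzero(dead):
            k = int(np.argmax(S[p]))
            A[p, k] = S[p, k] if S[p, k] > 0 else 0.5
    terms = list(planted_term_class.index)
    return ActivationMatrix(A, terms)


def generate_embeddings_and_lexicons(
    config: SyntheticConfig, planted_term_class: pd.Series
):
    """Clustered embeddings, concreteness scores, and category labels."""
    rng = config.child_rng("embeddings")
    classes = planted_term_class.to_numpy()
    n_terms = len(classes)
    offset = np.zeros(config.embedding_dim)
    offset[0] = config.cluster_separation / 2.0
    # word embeddings have strongly decaying spectra: within-cluster variance
    # concentrates in a few leading directions (effective dimension ~ 2x the
    # decay length), so cluster membership is visible to isotropic dispersion
    # measures and not only to linear classifiers
    scales = np.exp(-np.arange(config.embedding_dim) / 20.0)
    vectors = rng.normal(size=(n_terms, config.embedding_dim)) * scales[None, :]
    vectors += np.where(classes == "high", 1.0, -1.0)[:, None] * offset[None, :]
    emb = EmbeddingMatrix(list(planted_term_class.index), vectors)
    conc = np.where(
        classes == "high",
        rng.normal(3.8, 0.4, size=n_terms),
        rng.normal(2.6, 0.4, size=n_terms),
    )
    concreteness = pd.Series(
        np.clip(conc, 1.0, 5.0), index=planted_term_class.index, name="concreteness"
    )
    cats = [
        rng.choice(_CATEGORIES, p=_CATEGORY_PROBS[c]) for c in classes
    ]
    categories = pd.Series(cats, index=planted_term_class.index, name="category")
    return emb, concreteness, categories


def generate_thickness(
    config: SyntheticConfig, atlas: ParcelAtlas, planted_gradient: np.ndarray
) -> np.ndarray:
    """Thickness decreasing along the axial coordinate and the coupling gradient."""
    rng = config.child_rng("thickness")
    z = atlas.centroids[:, 2]
    zhat = (z - z.min()) / max(z.max() - z.min(), 1e-12)
    t = (
        config.thickness_base_mm
        - config.thickness_axial_slope * zhat
        - config.thickness_coupling_slope * np.asarray(planted_gradient, float)
        + rng.normal(scale=config.thickness_noise_sd, size=atlas.n)
    )
    return np.maximum(t, 0.5)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write every component plus a manifest of the planted truths."""
    import json
    from pathlib import Path

    from .atlas import save_atlas
    from .matrix import write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_atlas(ds.atlas, out / "atlas_positions.csv", out / "atlas_index.csv")
    checksum = ds.atlas.checksum()
    for i, (c, l) in enumerate(zip(ds.subject_counts, ds.subject_lengths)):
        write_matrix(c, out / f"subject_{i:04d}_count.npz", checksum)
        write_matrix(l, out / f"subject_{i:04d}_length.npz", checksum)
    ds.activation.to_csv(out / "activation.csv")
    ds.embeddings.to_csv(out / "embeddings.csv")
    ds.concreteness.rename_axis("term").to_csv(out / "concreteness.csv")
    ds.categories.rename_axis("term").to_csv(out / "categories.csv")
    pd.DataFrame({"thickness": ds.thickness}).to_csv(out / "thickness.csv", index=False)
    manifest = {
        "atlas_checksum": checksum,
        "n_subjects": len(ds.subject_counts),
        "planted_gradient": [float(x) for x in ds.planted_gradient],
        "planted_term_class": ds.planted_term_class.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate every component, mutually indexed by one atlas and term list."""
    config = config or SyntheticConfig()
    atlas = generate_atlas(config)
    subject_counts, subject_lengths = generate_structural(config, atlas)
    sc_count = aggregate_counts(subject_counts, atlas, AggregationOptions())
    sc_cos = cosine_profiles(sc_count)
    gradient = (
        config.coupling_profile
        if config.coupling_profile is not None
        else default_coupling_profile(config, atlas)
    )
    term_class = default_term_classes(config)
    activation = generate_activation(config, atlas, sc_cos, gradient, term_class)
    emb, concreteness, categories = generate_embeddings_and_lexicons(config, term_class)
    thickness = generate_thickness(config, atlas, gradient)
    return SyntheticDataset(
        atlas=atlas,
        subject_counts=subject_counts,
        subject_lengths=subject_lengths,
        activation=activation,
        embeddings=emb,
        concreteness=concreteness,
        categories=categories,
        thickness=thickness,
        planted_gradient=np.asarray(gradient, float),
        planted_term_class=term_class,
        sc_count=sc_count,
        sc_cosine=sc_cos,
    )
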