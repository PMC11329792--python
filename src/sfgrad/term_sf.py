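"""Structure-function correspondence by specific function (term).

For each functional term, parcels are split into active (nonzero activation)
and inactive sets.  The volume-normalized streamline counts between all
active-active pairs are compared to the counts between all active-inactive
pairs: a term whose co-activated parcels are much more strongly wired than
their connections to inactive parcels has high structure-function coupling.

The comparison is a two-sample rank test (Mann-Whitney U, two-sided; exact
permutation enumeration for small samples, tie-corrected normal
approximation otherwise) plus a fold change — mean active-active count over
mean active-inactive count.  Terms with too few active-active connections
are filtered; the rest are classified high/low by a Bonferroni-corrected p
threshold and a fold-change percentile cutoff among the significant terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcelAtlas
from .functional import ActivationMatrix
from .matrix import ConnectivityMatrix

__all__ = [
    "TermSFConfig",
    "TermSFResult",
    "active_split",
    "pair_vectors",
    "term_test",
    "classify_terms",
    "mean_active_distance",
    "run_term_sf",
]

logger = logging.getLogger(__name__)

#: largest combined sample size for which the exact permutation p is used
EXACT_LIMIT = 16


@dataclass
class TermSFConfig:
    activation_tolerance: float = 1e-12
    min_aa_connections: int = 50  # nonzero active-active count pairs required
    alpha: float = 0.05  # Bonferroni-corrected family level
    fc_percentile: float = 20.0  # log2FC cutoff percentile among significant terms
    count_nonzero_pairs_only: bool = True  # a "connection" requires streamlines

    def __post_init__(self):
        if not (0.0 < self.fc_percentile < 100.0):
            raise ValueError("fc_percentile must be in (0, 100)")


@dataclass
class TermSFResult:
    term: str
    n_active: int = 0
    n_aa_pairs: int = 0
    n_ai_pairs: int = 0
    statistic: float = np.nan
    p_raw: float = np.nan
    p_corrected: float = np.nan
    fold_change: float = np.nan
    log2_fold_change: float = np.nan
    sf_class: str = "filtered"  # {high, low, not_significant, filtered}


def active_split(fa: ActivationMatrix, term: str, tol: float = 1e-12):
    """Indices of active (|z| > tol) and inactive parcels for one term."""
    k = fa.term_index(term) if isinstance(term, str) else int(term)
    col = fa.values[:, k]
    active = np.flatnonzero(np.abs(col) > tol)
    inactive = np.flatnonzero(~(np.abs(col) > tol))
    return active, inactive


def pair_vectors(sc_count: ConnectivityMatrix, active, inactive):
    """Streamline-count vectors for active-active and active-inactive pairs.

    All unordered active pairs and all active×inactive pairs enter,
    including zero-count pairs (absence of streamlines is data).
    """
    active = np.asarray(active, int)
    inactive = np.asarray(inactive, int)
    if np.intersect1d(active, inactive).size:
        raise ValueError("active and inactive sets overlap")
    v = np.where(np.isnan(sc_count.values), 0.0, sc_count.values)
    if active.size >= 2:
        ia, ja = np.triu_indices(active.size, k=1)
        aa = v[active[ia], active[ja]]
    else:
        aa = np.empty(0)
    ai = v[np.ix_(active, inactive)].ravel() if active.size and inactive.size else np.empty(0)
    return aa, ai


def _exact_rank_p(x: np.ndarray, y: np.ndarray) -> tuple:
    """Two-sided exact permutation p of the Mann-Whitney U statistic.

    Enumerates every split of the pooled sample; handles ties via midranks.
    p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    total = comb(len(pooled), nx)
    le = ge = 0
    for idx in combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(u_obs), p


def term_test(aa: np.ndarray, ai: np.ndarray):
    """Rank test and fold change comparing active-active vs active-inactive.

    Returns ``(U statistic, two-sided p, fold_change)`` with
    ``fold_change = mean(aa) / mean(ai)``; a zero active-inactive mean leaves
    the fold change undefined (NaN).
    """
    aa = np.asarray(aa, float)
    ai = np.asarray(ai, float)
    if aa.size == 0 or ai.size == 0:
        raise ValueError("both pair vectors must be nonempty")
    if aa.size + ai.size <= EXACT_LIMIT:
        stat, p = _exact_rank_p(aa, ai)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(aa, ai, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    mean_ai = ai.mean()
    fold = aa.mean() / mean_ai if mean_ai > 0 else np.nan
    return stat, p, fold


def mean_active_distance(active, atlas: ParcelAtlas) -> float:
    """Mean pairwise Euclidean distance (mm) among active parcels."""
    active = np.asarray(active, int)
    if active.size < 2:
        return np.nan
    c = atlas.centroids[active]
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    iu, ju = np.triu_indices(active.size, k=1)
    return float(d[iu, ju].mean())


def run_term_sf(
    fa: ActivationMatrix,
    sc_count: ConnectivityMatrix,
    config: TermSFConfig | None = None,
    atlas: ParcelAtlas | None = None,
) -> list:
    """Test every term; returns classified :class:`TermSFResult` list."""
    config = config or TermSFConfig()
    results = []
    for term in fa.term_names:
        active, inactive = active_split(fa, term, config.activation_tolerance)
        res = TermSFResult(term=term, n_active=int(active.size))
        if active.size < 2 or inactive.size == 0:
            results.append(res)
            continue
        aa, ai = pair_vectors(sc_count, active, inactive)
        res.n_aa_pairs = int((aa > 0).sum()) if config.count_nonzero_pairs_only else aa.size
        res.n_ai_pairs = int(ai.size)
        if res.n_aa_pairs < config.min_aa_connections:
            results.append(res)
            continue
        stat, p, fold = term_test(aa, ai)
        res.statistic, res.p_raw, res.fold_change = stat, p, fold
        res.log2_fold_change = np.log2(fold) if np.isfinite(fold) and fold > 0 else np.nan
        res.sf_class = "tested"  # provisional until classification
        if not np.isfinite(res.log2_fold_change):
            res.sf_class = "filtered"
        results.append(res)
    return classify_terms(results, config)


def classify_terms(results, config: TermSFConfig | None = None) -> list:
    """Assign high/low/not_significant/filtered classes.

    Bonferroni correction runs over the terms that survive the
    active-active connection filter; among significant terms the
    ``fc_percentile``-th percentile (linear interpolation) of log2 fold
    change separates high (>= cutoff) from low (< cutoff).
    """
    config = config or TermSFConfig()
    tested = [r for r in results if np.isfinite(r.p_raw) and r.sf_class != "filtered"]
    tested_ids = {id(r) for r in tested}
    m = len(tested)
    for r in results:
        if id(r) not in tested_ids:
            r.sf_class = "filtered"
            continue
        r.p_corrected = min(1.0, r.p_raw * m)
    sig = [r for r in tested if r.p_corrected < config.alpha]
    if not sig:
        logger.warning("no terms significant after Bonferroni correction")
        for r in tested:
            r.sf_class = "not_significant"
        return results
    cutoff = float(np.percentile([r.log2_fold_change for r in sig], config.fc_percentile))
    for r in tested:
        if r.p_corrected >= config.alpha:
            r.sf_class = "not_significant"
        elif r.log2_fold_change >= cutoff:
            r.sf_class = "high"
        else:
            r.sf_class = "low"
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Tabular (CSV-ready) view of term results."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "n_active": r.n_active,
                "n_aa_pairs": r.n_aa_pairs,
                "n_ai_pairs": r.n_ai_pairs,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "fold_change": r.fold_change,
                "log2_fold_change": r.log2_fold_change,
                "sf_class": r.sf_class,
            }
            for r in results
        ]
    )
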