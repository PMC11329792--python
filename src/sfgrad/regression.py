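"""SC→FC regression: global fits, node-based cross-validated model selection,
and the parcel-wise structure-function correspondence map.

The response is always a vector of FC values over parcel pairs and the
predictors are structural measures over the same pairs.  Cross-validation
folds hold out *parcels* (node-based splitting): a fold's test pairs connect
two held-out parcels, so the model is scored on completely unseen
relationships.  Out-of-sample performance is

    R2_OOS = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar_OOS)^2

per fold, with ``ybar_OOS`` the held-out mean, adjusted for the number of
predictors.  The optimal predictor subset per size is found by exhaustive
search minimizing training RSS; the reported size is the smallest whose mean
out-of-sample adjusted R2 lies within one standard error of the best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .atlas import ParcelAtlas
from .matrix import ConnectivityMatrix, upper_triangle_vector
from .structural import SCStack

__all__ = [
    "PairTable",
    "CVFolds",
    "OLSFit",
    "ModelSelectionResult",
    "SFMap",
    "build_pair_table",
    "fit_ols",
    "oos_r2",
    "node_folds",
    "exhaustive_selection",
    "parcelwise_sf",
    "region_zscores",
]


@dataclass
class PairTable:
    """Aligned response/predictor columns over upper-triangle parcel pairs."""

    y: np.ndarray
    X: np.ndarray  # (n_pairs, n_predictors), no intercept column
    predictors: list
    pairs: tuple  # (i_idx, j_idx), i < j
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def subset(self, names) -> np.ndarray:
        cols = [self.predictors.index(nm) for nm in names]
        return self.X[:, cols]


def build_pair_table(
    sc: SCStack, fc: ConnectivityMatrix, predictors=None
) -> PairTable:
    """Vectorize FC (response) and SC measures (predictors) over pairs.

    Rows with any missing value in the response or any requested predictor
    are dropped listwise; the dropped count is recorded.
    """
    predictors = list(predictors) if predictors is not None else list(sc.names)
    y, (iu, ju) = upper_triangle_vector(fc)
    cols = []
    for name in predictors:
        v, _ = upper_triangle_vector(sc[name])
        if v.shape != y.shape:
            raise ValueError(f"measure {name!r} not aligned with FC matrix")
        cols.append(v)
    X = np.column_stack(cols) if cols else np.empty((y.shape[0], 0))
    ok = np.isfinite(y)
    if X.shape[1]:
        ok &= np.all(np.isfinite(X), axis=1)
    if not ok.any():
        raise ValueError("pair table is empty after dropping missing rows")
    return PairTable(
        y=y[ok], X=X[ok], predictors=predictors, pairs=(iu[ok], ju[ok]),
        n_dropped=int((~ok).sum()),
    )


@dataclass
class OLSFit:
    coef: np.ndarray  # [intercept, slopes...]
    r2: float
    adj_r2: float
    mse: float
    n: int
    p: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return self.coef[0] + X @ self.coef[1:]


def _adjust_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_ols(y: np.ndarray, X: np.ndarray, predictors=None) -> OLSFit:
    """Least-squares fit with intercept.

    Raises on rank deficiency, naming the collinear columns when predictor
    names are given.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than p+1={p + 1} observations, got {n}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        names = list(predictors) if predictors else [f"x{k}" for k in range(p)]
        raise ValueError(f"rank-deficient design (rank {rank} < {p + 1}); columns: {names}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return OLSFit(coef=coef, r2=r2, adj_r2=_adjust_r2(r2, n, p), mse=rss / n, n=n, p=p)


def oos_r2(y_test: np.ndarray, y_hat: np.ndarray) -> float:
    """Out-of-sample R2 against the held-out mean; <= 1, can be negative."""
    y_test = np.asarray(y_test, float)
    y_hat = np.asarray(y_hat, float)
    if y_test.shape[0] < 2:
        raise ValueError("need at least 2 test points")
    tss = float(((y_test - y_test.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant test response; out-of-sample R2 undefined")
    return 1.0 - float(((y_test - y_hat) ** 2).sum()) / tss


@dataclass
class CVFolds:
    """Node-based (parcel-wise) cross-validation folds."""

    parcel_sets: list  # k arrays of held-out parcel indices
    seed: int
    n_parcels: int

    @property
    def k(self) -> int:
        return len(self.parcel_sets)

    def pair_masks(self, iu: np.ndarray, ju: np.ndarray, fold: int):
        """(train_mask, test_mask): test pairs join two held-out parcels,
        train pairs join two retained parcels; mixed pairs enter neither."""
        held = np.zeros(self.n_parcels, bool)
        held[self.parcel_sets[fold]] = True
        test = held[iu] & held[ju]
        train = ~held[iu] & ~held[ju]
        return train, test


def node_folds(atlas, k: int, seed: int = 0) -> CVFolds:
    """Random partition of parcels into k folds of near-equal size."""
    n = atlas.n if isinstance(atlas, ParcelAtlas) else int(atlas)
    if k > n:
        raise ValueError(f"k={k} exceeds atlas size {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sets = [np.sort(chunk) for chunk in np.array_split(perm, k)]
    if any(len(s) < 2 for s in sets):
        raise ValueError("each fold must hold out at least 2 parcels (no test pairs otherwise)")
    return CVFolds(parcel_sets=sets, seed=seed, n_parcels=n)


@dataclass
class ModelSelectionResult:
    per_size: pd.DataFrame  # size, subset, mean/sem of OOS adj R2 and MSE
    chosen_subset: tuple
    chosen_size: int
    rule: str
    k: int
    n_dropped: int = 0
    excluded_candidates: tuple = ()


def _gram(X: np.ndarray, y: np.ndarray):
    d = np.column_stack([np.ones(X.shape[0]), X])
    return d.T @ d, d.T @ y, float(y @ y)


def exhaustive_selection(
    table: PairTable,
    candidates=None,
    folds: CVFolds | None = None,
    rule: str = "one_sem",
    max_size: int | None = None,
) -> ModelSelectionResult:
    """Best-subset search over SC predictors, scored out of sample.

    For every subset size the training-RSS-minimizing subset is found per
    fold (exhaustively, via precomputed Gram matrices) and scored on the
    fold's held-out pairs.  ``rule`` picks the subset size: ``"one_sem"``
    takes the smallest size within one standard error of the best mean OOS
    adjusted R2; ``"max"`` takes the argmax.  The reported subset per size is
    the RSS-best on the full table (deterministic across folds).
    """
    candidates = list(candidates) if candidates is not None else list(table.predictors)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    if folds is None:
        raise ValueError("cross-validation folds are required")
    cols = {nm: table.predictors.index(nm) for nm in candidates}
    Xraw = table.X[:, [cols[nm] for nm in candidates]]
    # standardize predictors: fits with an intercept are invariant to this,
    # and Gram systems stay well conditioned across wildly different scales
    mu, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    excluded = [candidates[i] for i in np.flatnonzero(sd == 0)]
    if excluded:
        # e.g. hop count is 1 on every pair once rows are conditioned on a
        # measure defined only for directly connected pairs; a constant
        # column cannot inform any fit
        logger.warning("excluding constant candidate predictor(s): %s", excluded)
        keep = np.flatnonzero(sd > 0)
        candidates = [candidates[i] for i in keep]
        Xraw, mu, sd = Xraw[:, keep], mu[keep], sd[keep]
        if not candidates:
            raise ValueError("all candidate predictors are constant")
    Xall = (Xraw - mu) / sd
    y = table.y
    iu, ju = table.pairs
    nc = len(candidates)
    max_size = max_size or nc

    def _best_by_train_rss(G, b, subsets):
        """Min-RSS subset via Gram solves (RSS up to the constant y'y)."""
        best_rss, best_sub = np.inf, None
        for sub in subsets:
            ix = [0] + [c + 1 for c in sub]
            Gs = G[np.ix_(ix, ix)]
            try:
                beta = np.linalg.solve(Gs, b[ix])
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Gs, b[ix], rcond=None)[0]
            rss = float(beta @ (Gs @ beta) - 2.0 * beta @ b[ix])
            if np.isfinite(rss) and rss < best_rss:
                best_rss, best_sub = rss, sub
        return best_sub

    fold_data = []
    for f in range(folds.k):
        tr, te = folds.pair_masks(iu, ju, f)
        if te.sum() < 2 or tr.sum() < nc + 2:
            raise ValueError(f"fold {f} has too few train/test pairs")
        G_tr, b_tr, _ = _gram(Xall[tr], y[tr])
        fold_data.append((tr, te, G_tr, b_tr))
    G_full, b_full, _ = _gram(Xall, y)

    subsets_by_size = {s: list(combinations(range(nc), s)) for s in range(1, max_size + 1)}
    rows = []
    for s, subsets in subsets_by_size.items():
        oos_vals, mse_vals = [], []
        for tr, te, G_tr, b_tr in fold_data:
            sub = _best_by_train_rss(G_tr, b_tr, subsets)
            # score the fold-best subset by explicit refit and prediction
            # (min-norm lstsq: duplicate measures, e.g. nav_length == length
            # on directly connected pairs, must not abort the search)
            Xs = Xall[:, list(sub)]
            d_tr = np.column_stack([np.ones(int(tr.sum())), Xs[tr]])
            beta = np.linalg.lstsq(d_tr, y[tr], rcond=None)[0]
            pred = beta[0] + Xs[te] @ beta[1:]
            r2 = oos_r2(y[te], pred)
            n_te = int(te.sum())
            oos_vals.append(_adjust_r2(r2, n_te, s))
            mse_vals.append(float(((y[te] - pred) ** 2).mean()))
        best = _best_by_train_rss(G_full, b_full, subsets)
        best_names = tuple(candidates[c] for c in best)
        oos_vals = np.array(oos_vals)
        mse_vals = np.array(mse_vals)
        sem = oos_vals.std(ddof=1) / np.sqrt(len(oos_vals)) if len(oos_vals) > 1 else 0.0
        rows.append(
            {
                "size": s,
                "subset": best_names,
                "mean_oos_adj_r2": oos_vals.mean(),
                "sem_oos_adj_r2": sem,
                "mean_mse": mse_vals.mean(),
                "sem_mse": mse_vals.std(ddof=1) / np.sqrt(len(mse_vals))
                if len(mse_vals) > 1
                else 0.0,
            }
        )
    per_size = pd.DataFrame(rows)
    best_ix = int(per_size["mean_oos_adj_r2"].idxmax())
    if rule == "max":
        chosen_ix = best_ix
    elif rule == "one_sem":
        threshold = per_size.loc[best_ix, "mean_oos_adj_r2"] - per_size.loc[best_ix, "sem_oos_adj_r2"]
        ok = per_size[per_size["mean_oos_adj_r2"] >= threshold]
        chosen_ix = int(ok["size"].idxmin())
    else:
        raise ValueError(f"unknown rule {rule!r}")
    chosen = per_size.loc[chosen_ix]
    return ModelSelectionResult(
        per_size=per_size,
        chosen_subset=tuple(chosen["subset"]),
        chosen_size=int(chosen["size"]),
        rule=rule,
        k=folds.k,
        n_dropped=table.n_dropped,
        excluded_candidates=tuple(excluded),
    )


@dataclass
class SFMap:
    """Per-parcel structure-function correspondence (adjusted R2)."""

    values: np.ndarray
    subset: tuple
    n_pairs_used: np.ndarray = None

    @property
    def zscored(self) -> np.ndarray:
        v = self.values
        mu = np.nanmean(v)
        sd = np.nanstd(v, ddof=0)
        if sd <= 1e-12 * max(1.0, abs(mu)):  # constant map
            return np.zeros_like(v)
        return (v - mu) / sd


def parcelwise_sf(
    sc: SCStack, fc: ConnectivityMatrix, subset, atlas: ParcelAtlas | None = None
) -> SFMap:
    """Adjusted R2 of each parcel's FC row regressed on its SC measure rows.

    For parcel p the response is FC(p, q) over all other parcels q and the
    design is the chosen SC measures' rows of p; pairs with any missing value
    are dropped.  Parcels left with fewer than p+2 valid pairs get a missing
    SF value.
    """
    subset = list(subset)
    n = fc.n
    fcv = fc.values
    Xrows = np.stack([sc[nm].values for nm in subset], axis=-1)  # (n, n, p)
    out = np.full(n, np.nan)
    used = np.zeros(n, int)
    p = len(subset)
    for i in range(n):
        y = np.delete(fcv[i], i)
        X = np.delete(Xrows[i], i, axis=0)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        if ok.sum() < p + 2:
            continue
        yi, Xi = y[ok], X[ok]
        # a measure's row can be locally constant (hop count at a hub) or
        # duplicate another's (navigation length equals streamline length on
        # direct connections); min-norm lstsq tolerates this and the
        # adjusted-R2 penalty uses the effective (rank-based) predictor count
        keep = Xi.std(axis=0) > 0
        if not keep.any():
            continue
        design = np.column_stack([np.ones(int(ok.sum())), Xi[:, keep]])
        rank = np.linalg.matrix_rank(design)
        p_eff = rank - 1
        if ok.sum() < p_eff + 2 or p_eff < 1:
            continue
        beta = np.linalg.lstsq(design, yi, rcond=None)[0]
        resid = yi - design @ beta
        tss = float(((yi - yi.mean()) ** 2).sum())
        if tss <= 0:
            continue
        r2 = 1.0 - float(resid @ resid) / tss
        out[i] = _adjust_r2(r2, int(ok.sum()), p_eff)
        used[i] = int(ok.sum())
    return SFMap(values=out, subset=tuple(subset), n_pairs_used=used)


def region_zscores(sfmap: SFMap, atlas: ParcelAtlas) -> pd.DataFrame:
    """Mean ± SEM of the z-scored SF map by atlas region."""
    z = sfmap.zscored
    df = pd.DataFrame({"region": atlas.regions, "z": z}).dropna()
    g = df.groupby("region")["z"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_z", "sem": "sem_z", "count": "n_parcels"})
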