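"""Term embeddings and prediction of term-level SF correspondence.

Embeddings place functional terms in a semantic vector space (default 150
dimensions).  They are either loaded from a precomputed term-indexed table —
the supported no-download path — or estimated from a tokenized corpus with a
positive pointwise-mutual-information co-occurrence factorization (PPMI +
truncated SVD), a classical count-based embedding estimator.

Downstream, a linear-kernel SVM classifies terms as high vs low SF over
stratified 4-fold cross-validation (high SF is the positive class), and a
feedforward network (two 128-unit ReLU hidden layers, single linear output,
MSE loss, adaptive-moment optimizer, early stopping on a 10% inner
validation split) regresses the continuous fold change.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import oos_r2

__all__ = [
    "EmbeddingConfig",
    "EmbeddingMatrix",
    "ClassifierReport",
    "RegressorReport",
    "train_embeddings",
    "svm_classify",
    "nn_regress",
    "component_separation",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    dim: int = 150
    iterations: int = 20  # SVD power iterations
    window: int = 5
    min_count: int = 1
    seed: int = 0


@dataclass
class EmbeddingMatrix:
    """Term → vector map with a fixed dimensionality."""

    terms: list
    vectors: np.ndarray  # (n_terms, dim)
    config: EmbeddingConfig | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.terms):
            raise ValueError("vectors must be (n_terms, dim) aligned with terms")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, term) -> bool:
        return term in self.terms

    def __getitem__(self, term) -> np.ndarray:
        return self.vectors[self.terms.index(term)]

    def missing(self, terms) -> list:
        """Terms without an embedding — listed, never silently dropped."""
        have = set(self.terms)
        return [t for t in terms if t not in have]

    def aligned(self, terms) -> np.ndarray:
        """(len(terms), dim) matrix; rows of absent terms are NaN."""
        out = np.full((len(terms), self.dim), np.nan)
        index = {t: i for i, t in enumerate(self.terms)}
        for k, t in enumerate(terms):
            if t in index:
                out[k] = self.vectors[index[t]]
        return out

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.vectors, index=self.terms)
        df.index.name = "term"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EmbeddingMatrix":
        df = pd.read_csv(path, index_col="term")
        return cls(list(df.index), df.to_numpy(float))


def train_embeddings(corpus, config: EmbeddingConfig | None = None, terms=None) -> EmbeddingMatrix:
    """Estimate word embeddings from a tokenized corpus.

    Co-occurrence counts within a symmetric window are converted to positive
    pointwise mutual information and factorized by truncated SVD; word
    vectors are ``U * sqrt(S)``.  If ``terms`` is given, absent terms are
    logged and listed on the returned matrix as ``missing_terms``.
    """
    config = config or EmbeddingConfig()
    if not corpus:
        raise ValueError("corpus is empty")
    counts = Counter(tok for doc in corpus for tok in doc)
    vocab = sorted(t for t, c in counts.items() if c >= config.min_count)
    index = {t: i for i, t in enumerate(vocab)}
    n = len(vocab)
    cooc = np.zeros((n, n))
    for doc in corpus:
        ids = [index[t] for t in doc if t in index]
        for pos, wi in enumerate(ids):
            lo = max(0, pos - config.window)
            for wj in ids[lo:pos]:
                cooc[wi, wj] += 1.0
                cooc[wj, wi] += 1.0
    total = cooc.sum()
    if total == 0:
        raise ValueError("no co-occurrences in corpus")
    pw = cooc.sum(axis=1) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((cooc / total) / np.outer(pw, pw))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    dim = min(config.dim, n - 1)
    from sklearn.decomposition import TruncatedSVD

    svd = TruncatedSVD(
        n_components=dim, n_iter=config.iterations, random_state=config.seed
    )
    u = svd.fit_transform(ppmi)  # = U * S
    vectors = u / np.sqrt(np.maximum(svd.singular_values_, 1e-12))[None, :]
    if dim < config.dim:
        vectors = np.pad(vectors, ((0, 0), (0, config.dim - dim)))
    emb = EmbeddingMatrix(vocab, vectors, config)
    if terms is not None:
        miss = emb.missing(terms)
        if miss:
            logger.warning("%d term(s) absent from corpus vocabulary: %s", len(miss), miss)
        emb.missing_terms = miss
    return emb


@dataclass
class ClassifierReport:
    fold_aucs: list
    mean_auc: float
    mean_accuracy: float
    folds: int
    seed: int
    roc_points: list = field(default_factory=list)  # (fpr, tpr) arrays per fold


def svm_classify(embeddings, labels, folds: int = 4, seed: int = 0) -> ClassifierReport:
    """Linear-kernel SVM classification of high vs low SF terms.

    Stratified k-fold cross-validation; per-fold ROC/AUC computed from the
    probability of the positive class ("high").
    """
    from sklearn.metrics import roc_auc_score, roc_curve
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    X = np.asarray(getattr(embeddings, "vectors", embeddings), float)
    y = np.asarray([1 if str(l) == "high" else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if min(np.bincount(y)) < folds:
        raise ValueError("too few terms in a class for the requested folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs, accs, rocs = [], [], []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2:
            raise ValueError("single-class test fold")
        clf = SVC(kernel="linear", probability=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X[tr], y[tr])
        prob = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        aucs.append(float(roc_auc_score(y[te], prob)))
        accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        fpr, tpr, _ = roc_curve(y[te], prob)
        rocs.append((fpr, tpr))
    return ClassifierReport(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        mean_accuracy=float(np.mean(accs)),
        folds=folds,
        seed=seed,
        roc_points=rocs,
    )


@dataclass
class RegressorReport:
    oos_r2: float  # mean across folds
    fold_r2: list
    spearman_r: float
    p: float
    predictions: pd.DataFrame  # term index, actual, predicted
    folds: int
    seed: int
    train_config: dict = field(default_factory=dict)


def nn_regress(embeddings, fold_changes, folds: int = 4, seed: int = 0) -> RegressorReport:
    """Feedforward regression of term fold change from embeddings.

    Architecture: input → 128 → 128 → 1 with ReLU hidden activations, MSE
    loss, adaptive-moment optimizer, at most 500 epochs with early stopping
    on a 10% inner validation split.  Features and target are standardized
    on each training fold.  Reports the mean across folds of the
    out-of-sample R2 and the Spearman correlation of pooled predictions.
    """
    from sklearn.model_selection import KFold
    from sklearn.neural_network import MLPRegressor

    X = np.asarray(getattr(embeddings, "vectors", embeddings), float)
    y = np.asarray(fold_changes, float)
    if len(y) < 20:
        raise ValueError("need at least 20 terms for the regression analysis")
    train_config = {
        "hidden_layer_sizes": (128, 128),
        "activation": "relu",
        "solver": "adam",
        "max_iter": 500,
        "early_stopping": True,
        "validation_fraction": 0.1,
        "n_iter_no_change": 50,
        "learning_rate_init": 0.01,
    }
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_r2, pred_rows = [], []
    for tr, te in kf.split(X):
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        ymu, ysd = y[tr].mean(), y[tr].std() or 1.0
        net = MLPRegressor(random_state=seed, **train_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit((X[tr] - mu) / sd, (y[tr] - ymu) / ysd)
        if not np.isfinite(net.loss_):
            raise RuntimeError(f"training diverged (non-finite loss); config: {train_config}")
        pred = net.predict((X[te] - mu) / sd) * ysd + ymu
        fold_r2.append(oos_r2(y[te], pred))
        pred_rows.extend(zip(te.tolist(), y[te].tolist(), pred.tolist()))
    preds = pd.DataFrame(pred_rows, columns=["index", "actual", "predicted"]).sort_values(
        "index"
    )
    sp = stats.spearmanr(preds["actual"], preds["predicted"])
    return RegressorReport(
        oos_r2=float(np.mean(fold_r2)),
        fold_r2=[float(v) for v in fold_r2],
        spearman_r=float(sp.statistic),
        p=float(sp.pvalue),
        predictions=preds,
        folds=folds,
        seed=seed,
        train_config=train_config,
    )


@dataclass
class SeparationReport:
    p_pca: float
    p_tsne: float
    p_pca_corrected: float
    p_tsne_corrected: float
    pca_component: np.ndarray
    tsne_component: np.ndarray
    perplexity: float
    seed: int


def component_separation(embeddings, classes, seed: int = 0) -> SeparationReport:
    """Do high- and low-SF terms separate along low-dimensional axes?

    Projects the embeddings to their first PCA component and first tSNE
    component (fixed seed; perplexity logged in the report) and compares the
    two classes along each with a two-sided rank-sum test, Bonferroni
    corrected over the two tests.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = np.asarray(getattr(embeddings, "vectors", embeddings), float)
    y = np.asarray([str(c) for c in classes])
    hi, lo = X[y == "high"], X[y == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both classes must be nonempty")
    if min(len(hi), len(lo)) < 3:
        logger.warning("a class has fewer than 3 terms; exact rank test used")
    pca1 = PCA(n_components=1, svd_solver="full").fit_transform(X)[:, 0]
    perplexity = min(30.0, (len(X) - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    tsne1 = tsne.fit_transform(X)[:, 0]
    p_pca = float(
        stats.mannwhitneyu(pca1[y == "high"], pca1[y == "low"], alternative="two-sided").pvalue
    )
    p_tsne = float(
        stats.mannwhitneyu(tsne1[y == "high"], tsne1[y == "low"], alternative="two-sided").pvalue
    )
    return SeparationReport(
        p_pca=p_pca,
        p_tsne=p_tsne,
        p_pca_corrected=min(1.0, 2 * p_pca),
        p_tsne_corrected=min(1.0, 2 * p_tsne),
        pca_component=pca1,
        tsne_component=tsne1,
        perplexity=perplexity,
        seed=seed,
    )
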