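"""Functional connectivity from meta-analytic activations and time series.

Meta-analytic functional connectivity is the cosine similarity between the
per-parcel activation profiles over functional terms: it captures only the
relative pattern of activation across terms, not its magnitude.  The
resting-state path averages Fisher-z transformed Pearson correlations of
parcel time courses across subjects.  FC is never sparsity-thresholded here;
downstream comparisons use rank-based statistics instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ConnectivityMatrix

__all__ = [
    "ActivationMatrix",
    "TimeSeriesMatrix",
    "fc_from_activation",
    "fc_from_timeseries",
    "fc_strength",
]

logger = logging.getLogger(__name__)

#: clipping applied to r before atanh so Fisher z stays finite
R_CLIP = 1.0 - 1e-12


@dataclass
class ActivationMatrix:
    """Parcel×term matrix of mean activation z-scores."""

    values: np.ndarray
    term_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("activation matrix must be 2-D (parcels × terms)")
        if not self.term_names:
            self.term_names = [f"term_{k}" for k in range(self.values.shape[1])]
        if len(self.term_names) != self.values.shape[1]:
            raise ValueError("term_names length does not match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation values must be finite")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]

    @property
    def n_terms(self) -> int:
        return self.values.shape[1]

    def term_index(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in activation matrix") from None

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.term_names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivationMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(float), list(df.columns))


@dataclass
class TimeSeriesMatrix:
    """Parcel×time matrix of one subject's mean parcel time courses."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] < 3:
            raise ValueError("time series must be parcels × time with >= 3 time points")


def fc_from_activation(fa: ActivationMatrix) -> ConnectivityMatrix:
    """Cosine-similarity FC ("fc_cosine") between parcel activation profiles.

    Parcels with an all-zero activation row have undefined similarity; their
    entries are missing and a warning is logged.
    """
    a = fa.values
    norms = np.linalg.norm(a, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d parcel(s) have all-zero activation rows; FC entries missing", zero.sum())
    safe = np.where(zero, 1.0, norms)
    unit = a / safe[:, None]
    out = unit @ unit.T
    out = np.clip(out, -1.0, 1.0)
    out[zero, :] = np.nan
    out[:, zero] = np.nan
    return ConnectivityMatrix(out, "fc_cosine")


def fc_from_timeseries(subjects) -> ConnectivityMatrix:
    """Group resting-state FC ("fc_rsfmri"): mean over subjects of atanh(r).

    Per subject the Pearson correlation of every parcel pair is Fisher-z
    transformed (r clipped to ±(1 − 1e-12)); the group matrix is the mean z
    across subjects.  Constant time series give missing entries.
    """
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    zs = []
    n = None
    for ts in subjects:
        v = ts.values if isinstance(ts, TimeSeriesMatrix) else TimeSeriesMatrix(ts).values
        if n is None:
            n = v.shape[0]
        elif v.shape[0] != n:
            raise ValueError("subjects have differing parcel counts")
        sd = v.std(axis=1)
        const = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(v)
        r[const, :] = np.nan
        r[:, const] = np.nan
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        zs.append(z)
    out = np.mean(np.stack(zs), axis=0)
    return ConnectivityMatrix(out, "fc_rsfmri", meta={"n_subjects": len(subjects)})


def fc_strength(fc: ConnectivityMatrix) -> np.ndarray:
    """Functional node strength: row sums excluding diagonal (missing as 0)."""
    v = np.where(np.isnan(fc.values), 0.0, fc.values)
    np.fill_diagonal(v, 0.0)
    return v.sum(axis=1)
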