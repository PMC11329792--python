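"""Parcel-by-parcel connectivity matrices.

A :class:`ConnectivityMatrix` is the common currency of the package: every
structural (SC) and functional (FC) measure is a square, symmetric,
parcel-ordered real matrix.  Entries that are undefined for a pair (an
unreachable navigation route, a pair connected in no subject, ...) carry the
missing marker ``NaN`` — deliberately distinct from ``0.0``, because a zero
streamline count is data.  Self-edges are never considered, so the diagonal
is always missing.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "upper_triangle_vector",
    "matrix_from_upper_triangle",
    "read_matrix",
    "write_matrix",
]

_SYM_TOL = 1e-10


@dataclass
class ConnectivityMatrix:
    """Square symmetric parcel×parcel matrix with a measure label.

    Parameters
    ----------
    values
        ``(n, n)`` float array. ``NaN`` marks undefined entries; the diagonal
        is forced to ``NaN`` on construction.
    measure
        Short label such as ``"sc_count"`` or ``"fc_cosine"``.
    directed
        If True the matrix is explicitly allowed to be asymmetric (e.g. mean
        first passage time before symmetrization) and symmetry is not checked.
    meta
        Free-form provenance (aggregation options, atlas checksum, ...).
    """

    values: np.ndarray
    measure: str = ""
    directed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        np.fill_diagonal(v, np.nan)
        if not self.directed:
            d = v - v.T
            if np.nanmax(np.abs(np.where(np.isnan(d), 0.0, d)), initial=0.0) > _SYM_TOL:
                raise ValueError(
                    f"matrix '{self.measure}' is asymmetric beyond {_SYM_TOL}; "
                    "pass directed=True before symmetrization"
                )
            # NaN pattern must be symmetric as well
            if not np.array_equal(np.isnan(v), np.isnan(v.T)):
                raise ValueError("missing-entry pattern is asymmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def symmetrized(self, measure: str | None = None) -> "ConnectivityMatrix":
        """Arithmetic mean of the two directions; NaN if either is missing."""
        v = (self.values + self.values.T) / 2.0
        return ConnectivityMatrix(v, measure or self.measure, meta=dict(self.meta))

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            self.values.copy(), self.measure, self.directed, dict(self.meta)
        )


def upper_triangle_vector(m: ConnectivityMatrix | np.ndarray):
    """Vectorize the strict upper triangle in deterministic ``(i < j)`` order.

    Returns ``(values, (rows, cols))`` where missing entries are carried as
    NaN.  The diagonal is never included.
    """
    v = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    iu, ju = np.triu_indices(v.shape[0], k=1)
    return v[iu, ju], (iu, ju)


def matrix_from_upper_triangle(
    vec: np.ndarray, n: int, measure: str = ""
) -> ConnectivityMatrix:
    """Rebuild a symmetric matrix from its upper-triangle vector."""
    vec = np.asarray(vec, float)
    iu, ju = np.triu_indices(n, k=1)
    if vec.shape[0] != iu.shape[0]:
        raise ValueError(f"expected {iu.shape[0]} pair values, got {vec.shape[0]}")
    out = np.full((n, n), np.nan)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return ConnectivityMatrix(out, measure)


def write_matrix(m: ConnectivityMatrix, path, atlas_checksum: str | None = None) -> None:
    """Write to delimited text (``.csv``/``.tsv``) or a compressed ``.npz``.

    Both dialects carry the measure label and, when given, an atlas checksum
    so an atlas/matrix mismatch is detectable at read time.
    """
    path = str(path)
    header = {"measure": m.measure, "directed": m.directed}
    if atlas_checksum is not None:
        header["atlas_checksum"] = atlas_checksum
    header.update({k: v for k, v in m.meta.items() if isinstance(v, (str, int, float, bool))})
    if path.endswith(".npz"):
        np.savez_compressed(path, values=m.values, header=json.dumps(header))
        return
    delim = "\t" if path.endswith(".tsv") else ","
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        np.savetxt(fh, m.values, delimiter=delim)


def read_matrix(path, atlas_checksum: str | None = None) -> ConnectivityMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Raises if an ``atlas_checksum`` is supplied and the file's stored checksum
    disagrees — the matrix was built against a different atlas.
    """
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            values = z["values"]
    else:
        header = {}
        rows = []
        delim = "\t" if path.endswith(".tsv") else ","
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    header[k.strip()] = v.strip()
                elif line.strip():
                    rows.append(line)
        values = np.loadtxt(io.StringIO("".join(rows)), delimiter=delim)
    stored = header.get("atlas_checksum")
    if atlas_checksum is not None and stored is not None and stored != atlas_checksum:
        raise ValueError(
            f"matrix at {path} was written for a different atlas "
            f"(checksum {stored} != {atlas_checksum})"
        )
    directed = str(header.get("directed", "False")) in ("True", "true", "1")
    meta = {k: v for k, v in header.items() if k not in ("measure", "directed")}
    return ConnectivityMatrix(values, header.get("measure", ""), directed, meta)
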