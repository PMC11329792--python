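"""Parcel atlas data model, table IO, and shared geometric operations.

The atlas fixes the coordinate frame for everything spatial in the package:
parcel centroids are millimetre coordinates (for a volumetric atlas, in the
volume's affine frame), volumes are voxel counts, and region labels are the
atlas's anatomical groupings.  Internally parcel indexing is 0-based and
contiguous; file formats may carry 1-based ids which are translated at the
boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import ConnectivityMatrix

__all__ = [
    "Parcel",
    "ParcelAtlas",
    "VoxelLabelVolume",
    "load_atlas",
    "save_atlas",
    "euclidean_distance_matrix",
    "aggregate_voxels_to_parcels",
]


@dataclass(frozen=True)
class Parcel:
    id: int
    name: str
    region: str
    centroid: tuple  # (x, y, z) in mm
    volume: float  # voxel count, > 0

    def __post_init__(self):
        c = np.asarray(self.centroid, float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"parcel {self.id}: centroid must be a finite 3-vector")
        if not (self.volume > 0):
            raise ValueError(f"parcel {self.id}: volume must be > 0, got {self.volume}")
        object.__setattr__(self, "centroid", tuple(float(x) for x in c))


@dataclass
class ParcelAtlas:
    """Ordered collection of parcels with unique contiguous 0-based ids."""

    parcels: list = field(default_factory=list)
    variant: str = "generic"  # "with-callosum" (696) / "without-callosum" (690)

    def __post_init__(self):
        ids = [p.id for p in self.parcels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate parcel ids")
        if ids != list(range(len(ids))):
            raise ValueError("parcel ids must be contiguous 0..n-1 in order")
        if self.variant == "with-callosum" and len(ids) != 696:
            raise ValueError("with-callosum variant must have 696 parcels")
        if self.variant == "without-callosum" and len(ids) != 690:
            raise ValueError("without-callosum variant must have 690 parcels")

    def __len__(self) -> int:
        return len(self.parcels)

    @property
    def n(self) -> int:
        return len(self.parcels)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.parcels], float)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([p.volume for p in self.parcels], float)

    @property
    def regions(self) -> list:
        return [p.region for p in self.parcels]

    @property
    def names(self) -> list:
        return [p.name for p in self.parcels]

    def checksum(self) -> str:
        """Short content hash used to detect atlas/matrix mismatches."""
        h = hashlib.sha1()
        h.update(np.round(self.centroids, 6).tobytes())
        h.update(np.round(self.volumes, 6).tobytes())
        h.update("|".join(self.regions).encode())
        return h.hexdigest()[:12]


def load_atlas(position_table, index_table, variant: str | None = None) -> ParcelAtlas:
    """Build an atlas from a centroid-position table and an index table.

    ``position_table`` needs columns ``id, x, y, z`` (mm); ``index_table``
    needs ``id, name, region, volume``.  Ids may be 1-based on file; they are
    shifted to 0-based when the minimum id is 1.  Row counts must agree and
    ids must be unique.
    """
    pos = _read_table(position_table)
    idx = _read_table(index_table)
    for col in ("id", "x", "y", "z"):
        if col not in pos.columns:
            raise ValueError(f"position table missing column '{col}'")
    for col in ("id", "name", "region", "volume"):
        if col not in idx.columns:
            raise ValueError(f"index table missing column '{col}'")
    if len(pos) != len(idx):
        raise ValueError(f"row counts differ: {len(pos)} positions vs {len(idx)} index rows")
    if pos["id"].duplicated().any() or idx["id"].duplicated().any():
        raise ValueError("duplicate parcel ids in atlas tables")
    merged = pos.merge(idx, on="id", how="inner")
    if len(merged) != len(pos):
        raise ValueError("position and index tables carry different parcel ids")
    merged = merged.sort_values("id").reset_index(drop=True)
    offset = int(merged["id"].min())
    if offset not in (0, 1):
        raise ValueError(f"parcel ids must start at 0 or 1, got {offset}")
    parcels = [
        Parcel(
            id=int(r.id) - offset,
            name=str(r.name_col),
            region=str(r.region),
            centroid=(r.x, r.y, r.z),
            volume=float(r.volume),
        )
        for r in merged.rename(columns={"name": "name_col"}).itertuples(index=False)
    ]
    if variant is None:
        variant = {696: "with-callosum", 690: "without-callosum"}.get(len(parcels), "generic")
    return ParcelAtlas(parcels, variant=variant)


def save_atlas(atlas: ParcelAtlas, position_table, index_table) -> None:
    """Write the two-table on-disk form (1-based ids, round-trips load_atlas)."""
    ids = np.arange(atlas.n) + 1
    c = atlas.centroids
    pd.DataFrame({"id": ids, "x": c[:, 0], "y": c[:, 1], "z": c[:, 2]}).to_csv(
        position_table, index=False
    )
    pd.DataFrame(
        {"id": ids, "name": atlas.names, "region": atlas.regions, "volume": atlas.volumes}
    ).to_csv(index_table, index=False)


def _read_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    sep = "\t" if str(path_or_df).endswith(".tsv") else ","
    return pd.read_csv(path_or_df, sep=sep)


def euclidean_distance_matrix(atlas: ParcelAtlas) -> ConnectivityMatrix:
    """Pairwise Euclidean distance between parcel centroids, in mm."""
    if atlas.n == 0:
        raise ValueError("empty atlas")
    d = squareform(pdist(atlas.centroids))
    return ConnectivityMatrix(d, "eucl_dist")


@dataclass
class VoxelLabelVolume:
    """3-D integer label image: 0 = background, k = parcel id + 1."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def from_nifti(cls, path) -> "VoxelLabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(int), img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine), str(path))


def aggregate_voxels_to_parcels(
    volume: np.ndarray, labels: VoxelLabelVolume, atlas: ParcelAtlas
) -> np.ndarray:
    """Arithmetic mean of a voxelwise map over each parcel's voxels.

    Parcels containing no voxels get NaN.  All voxels within a parcel enter
    the mean, including exact zeros.
    """
    vol = np.asarray(volume, float)
    lab = labels.labels
    if vol.shape != lab.shape:
        raise ValueError(f"volume shape {vol.shape} != label shape {lab.shape}")
    present = np.unique(lab)
    present = present[present > 0]
    if present.size and (present.max() > atlas.n):
        bad = present[present > atlas.n]
        raise ValueError(f"labels {bad.tolist()} exceed atlas size {atlas.n}")
    flat_lab = lab.ravel()
    flat_vol = vol.ravel()
    keep = flat_lab > 0
    sums = np.bincount(flat_lab[keep], weights=flat_vol[keep], minlength=atlas.n + 1)
    counts = np.bincount(flat_lab[keep], minlength=atlas.n + 1)
    out = np.full(atlas.n, np.nan)
    nz = counts[1:] > 0
    out[nz] = sums[1:][nz] / counts[1:][nz]
    return out
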