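"""Integer label volumes and their joint contingency statistics.

A parcellation (atlas) is a 3-D image in which every voxel carries a
non-negative integer: 0 marks background and each value 1..n denotes one
region of interest (ROI).  All comparisons in this package assume the two
volumes live on one shared voxel grid — the standardization premise — so
the central object for any pairwise statistic is the joint contingency
table of voxel counts ``h_ij`` (voxels labeled ``i`` in atlas A and ``j``
in atlas B), with row marginals ``a_i``, column marginals ``b_j`` and
total ``N``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    FormatError,
    GridMismatchError,
    InvalidLabelError,
    CapacityError,
    ParameterError,
)

__all__ = [
    "Parcellation",
    "ContingencyTable",
    "load_parcellation",
    "write_parcellation",
    "list_labels",
    "region_size",
    "region_center",
    "contingency",
]

#: Tolerance for deciding that a float-stored voxel value is an integer label.
INTEGER_TOLERANCE = 1e-6

#: Tolerance (mm) for affine/voxel-size agreement between volumes on one grid.
AFFINE_TOLERANCE = 1e-4

Domain = Literal["all", "union_foreground", "intersection_foreground"]


@dataclasses.dataclass
class Parcellation:
    """A 3-D integer label volume on a world-anchored voxel grid.

    Parameters
    ----------
    labels
        3-D array of non-negative integers; 0 is background.  Stored as
        ``int64`` regardless of the on-disk dtype.
    affine
        4x4 voxel-index -> world-mm transform (NIfTI convention).
    name
        Short atlas identifier, e.g. ``"Yeo-17"``.
    space
        Coordinate-space tag, e.g. ``"MNI152NLin6"``.
    """

    labels: np.ndarray
    affine: np.ndarray
    name: str = "atlas"
    space: str = "MNI152NLin6"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise DimensionalityError(
                f"parcellation must be 3-D, got {labels.ndim}-D"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=INTEGER_TOLERANCE, rtol=0):
                raise InvalidLabelError(
                    "voxel values are not integers within tolerance "
                    f"{INTEGER_TOLERANCE}"
                )
            labels = rounded
        self.labels = labels.astype(np.int64)
        if self.labels.min() < 0:
            raise InvalidLabelError("negative voxel values are not valid labels")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")
        if np.any(self.voxel_size <= 0):
            raise ParameterError("affine encodes non-positive voxel sizes")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths (dx, dy, dz) in mm: column norms of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def same_grid_as(self, other: "Parcellation", atol: float = AFFINE_TOLERANCE) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=atol, rtol=0)
        )


@dataclasses.dataclass
class ContingencyTable:
    """Joint voxel counts between two parcellations on one grid.

    ``counts[i, j]`` is the number of voxels in the comparison domain that
    carry ``row_labels[i]`` in atlas A and ``col_labels[j]`` in atlas B.
    Marginals and the total are redundant with ``counts`` but kept explicit
    because every similarity statistic consumes them directly.
    """

    row_labels: np.ndarray
    col_labels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.row_labels = np.asarray(self.row_labels, dtype=np.int64)
        self.col_labels = np.asarray(self.col_labels, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.row_labels.size, self.col_labels.size):
            raise ParameterError("counts shape does not match label lists")
        if np.any(self.counts < 0):
            raise ParameterError("contingency counts must be non-negative")
        if self.total <= 0:
            raise ParameterError("contingency table must cover at least one voxel")

    @property
    def row_marginals(self) -> np.ndarray:
        """Region sizes ``a_i`` of atlas A within the comparison domain."""
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        """Region sizes ``b_j`` of atlas B within the comparison domain."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """Number of voxels ``N`` in the comparison domain."""
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_parcellation(
    path: str | Path, name: str | None = None, space: str = "MNI152NLin6"
) -> Parcellation:
    """Load a NIfTI-1/2 label volume (plain or gzipped).

    Float-stored data are accepted only when every voxel is within
    ``1e-6`` of an integer; anything else is rejected as invalid labels.
    A 4-D image is accepted only if it holds a single volume.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise DimensionalityError(
                f"{path} holds {data.shape[3]} volumes; a parcellation has one"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path} is {data.ndim}-D, expected 3-D")
    if name is None:
        name = path.name.split("_space-")[0].split(".")[0]
    return Parcellation(labels=data, affine=img.affine, name=name, space=space)


def _disk_dtype(max_label: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    if max_label <= np.iinfo(np.int64).max:
        raise CapacityError(
            f"label {max_label} exceeds the 32-bit unsigned on-disk contract"
        )
    raise CapacityError(f"label {max_label} cannot be stored losslessly")


def write_parcellation(p: Parcellation, path: str | Path) -> None:
    """Write a gzip-compressed NIfTI with the smallest unsigned dtype that
    fits the maximum label."""
    path = Path(path)
    dtype = _disk_dtype(int(p.labels.max(initial=0)))
    img = nib.Nifti1Image(p.labels.astype(dtype), p.affine)
    img.header.set_data_dtype(dtype)
    try:
        nib.save(img, path)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Region interrogation
# ---------------------------------------------------------------------------

def list_labels(p: Parcellation, include_background: bool = False) -> list[int]:
    """Distinct labels present in the volume, strictly increasing."""
    values = np.unique(p.labels)
    if not include_background:
        values = values[values != 0]
    return [int(v) for v in values]


def region_size(p: Parcellation, label: int) -> int:
    """Number of voxels carrying ``label`` (0 when absent)."""
    if label < 0:
        raise ParameterError("labels are non-negative")
    return int(np.count_nonzero(p.labels == label))


def region_center(
    p: Parcellation, label: int, frame: Literal["voxel", "world"] = "voxel"
) -> np.ndarray | None:
    """Unweighted centroid of a region, or None when the label is absent.

    In the voxel frame the centroid is the mean of the 0-based voxel
    indices; in the world frame that mean is mapped through the affine.
    A None return is the lost-ROI convention used in metadata sidecars.
    """
    idx = np.argwhere(p.labels == label)
    if idx.size == 0:
        return None
    center = idx.mean(axis=0)
    if frame == "world":
        center = p.affine[:3, :3] @ center + p.affine[:3, 3]
    elif frame != "voxel":
        raise ParameterError(f"unknown frame {frame!r}")
    return center


# ---------------------------------------------------------------------------
# Contingency table
# ---------------------------------------------------------------------------

def contingency(
    a: Parcellation,
    b: Parcellation,
    domain: Domain = "union_foreground",
    include_background: bool = True,
) -> ContingencyTable:
    """Joint voxel counts between two parcellations on a shared grid.

    Parameters
    ----------
    domain
        Which voxels enter the comparison: ``"all"`` (every grid voxel),
        ``"union_foreground"`` (non-background in at least one atlas, the
        default — it keeps the partitions exhaustive over N while showing
        where one atlas covers tissue the other calls background) or
        ``"intersection_foreground"`` (non-background in both).
    include_background
        When True, label 0 appears as an ordinary row/column wherever it
        occurs inside the domain.  When False, voxels that are background
        in either atlas are dropped from the domain entirely, so the table
        invariants (marginals summing to N) still hold.

    Raises
    ------
    GridMismatchError
        If the two volumes differ in shape or affine beyond ``1e-4``:
        cross-resolution comparison is an explicit resampling step, never
        implicit.
    """
    if not a.same_grid_as(b):
        raise GridMismatchError(
            "parcellations are not on one grid (shape/affine mismatch); "
            "resample explicitly before comparing"
        )
    la = a.labels.ravel()
    lb = b.labels.ravel()
    if domain == "all":
        sel = np.ones(la.shape, dtype=bool)
    elif domain == "union_foreground":
        sel = (la != 0) | (lb != 0)
    elif domain == "intersection_foreground":
        sel = (la != 0) & (lb != 0)
    else:
        raise ParameterError(f"unknown domain {domain!r}")
    if not include_background:
        sel &= (la != 0) & (lb != 0)
    la = la[sel]
    lb = lb[sel]
    if la.size == 0:
        raise ParameterError("comparison domain is empty (N = 0)")
    row_labels, ra = np.unique(la, return_inverse=True)
    col_labels, rb = np.unique(lb, return_inverse=True)
    counts = np.bincount(
        ra * col_labels.size + rb, minlength=row_labels.size * col_labels.size
    ).reshape(row_labels.size, col_labels.size)
    return ContingencyTable(row_labels=row_labels, col_labels=col_labels, counts=counts)


def contingency_from_arrays(
    la: Sequence[int] | np.ndarray, lb: Sequence[int] | np.ndarray
) -> ContingencyTable:
    """Contingency table of two flat label sequences of equal length.

    Convenience for tests and the similarity module; no grid semantics.
    """
    la = np.asarray(la).ravel()
    lb = np.asarray(lb).ravel()
    if la.shape != lb.shape:
        raise ParameterError("label sequences differ in length")
    row_labels, ra = np.unique(la, return_inverse=True)
    col_labels, rb = np.unique(lb, return_inverse=True)
    counts = np.bincount(
        ra * col_labels.size + rb, minlength=row_labels.size * col_labels.size
    ).reshape(row_labels.size, col_labels.size)
    return ContingencyTable(row_labels=row_labels, col_labels=col_labels, counts=counts)
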