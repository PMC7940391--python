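"""Synthetic parcellations with known ground-truth relationships.

Real atlas collections are large binary downloads; everything in this
package is instead exercised on generated parcellations whose structure
is known by construction:

* a Voronoi tessellation of an ellipsoidal "brain" mask gives an
  exhaustive partition with a controllable region count;
* :func:`refine_parcellation` splits each region in place, yielding a
  strict refinement — the synthetic analogue of atlas families built by
  one algorithm at several granularities;
* :func:`subregion_atlas` keeps only some regions, emulating atlases
  that cover a single anatomical sub-structure and therefore share little
  information with whole-brain parcellations;
* :func:`permute_labels` relabels regions bijectively, the oracle for
  relabeling invariance of similarity scores.

All generators are driven by numpy's PCG64 ``default_rng`` and are
bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .core import Parcellation
from .errors import ConsistencyError, DegenerateParameterError, ParameterError

__all__ = [
    "SynthSpec",
    "make_mask",
    "voronoi_parcellation",
    "refine_parcellation",
    "subregion_atlas",
    "permute_labels",
]

#: Voxels processed per chunk in the nearest-seed assignment; bounds the
#: temporary distance matrix at chunk * k doubles.
_CHUNK = 16384


@dataclasses.dataclass
class SynthSpec:
    """Recipe for one synthetic Voronoi parcellation.

    ``semi_axes`` of None means the mask fills the whole grid.  The same
    spec always produces a bitwise-identical volume.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions: int = 50
    seed: int = 0
    semi_axes: tuple[float, float, float] | None = None
    min_region_size: int = 1

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


def make_mask(
    shape: tuple[int, int, int],
    semi_axes: tuple[float, float, float],
    center: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Binary ellipsoid mask on a voxel grid.

    A voxel index x is inside iff sum(((x - c) / r)**2) <= 1.  With the
    default center — the grid midpoint (s - 1)/2 — the mask is exactly
    mirror-symmetric about the first-axis midline.
    """
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ParameterError("ellipsoid semi-axes must be positive")
    if center is None:
        center = tuple((s - 1) / 2.0 for s in shape)
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, semi))
    mask = q <= 1.0
    if not mask.any():
        raise DegenerateParameterError(
            "ellipsoid contains no voxel centers; enlarge the semi-axes"
        )
    return mask


def _nearest_seed(points_mm: np.ndarray, seeds_mm: np.ndarray) -> np.ndarray:
    """Index of the nearest seed per point; ties go to the lowest index
    (argmin returns the first minimum)."""
    out = np.empty(points_mm.shape[0], dtype=np.int64)
    for lo in range(0, points_mm.shape[0], _CHUNK):
        chunk = points_mm[lo : lo + _CHUNK]
        d2 = ((chunk[:, None, :] - seeds_mm[None, :, :]) ** 2).sum(axis=2)
        out[lo : lo + _CHUNK] = np.argmin(d2, axis=1)
    return out


def voronoi_parcellation(spec: SynthSpec, mask: np.ndarray | None = None) -> Parcellation:
    """Voronoi tessellation of the mask into ``n_regions`` labels 1..k.

    Seed voxels are drawn uniformly without replacement from the mask;
    every mask voxel is assigned to the nearest seed in *world* (mm)
    distance, so anisotropic voxel sizes behave correctly.  Every label
    is guaranteed present (each seed is its own nearest seed).  Voxels
    outside the mask stay background.
    """
    if mask is None:
        if spec.semi_axes is not None:
            mask = make_mask(spec.shape, spec.semi_axes)
        else:
            mask = np.ones(spec.shape, dtype=bool)
    if mask.shape != tuple(spec.shape):
        raise ParameterError("mask shape disagrees with spec shape")
    idx = np.argwhere(mask)
    k = spec.n_regions
    if k < 1:
        raise ParameterError("n_regions must be >= 1")
    if k > idx.shape[0]:
        raise ParameterError(
            f"cannot place {k} regions in a mask of {idx.shape[0]} voxels"
        )
    rng = np.random.default_rng(spec.seed)
    seed_rows = rng.choice(idx.shape[0], size=k, replace=False)
    vs = np.asarray(spec.voxel_size, dtype=float)
    assign = _nearest_seed(idx * vs, idx[seed_rows] * vs)
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[tuple(idx.T)] = assign + 1
    sizes = np.bincount(assign, minlength=k)
    if spec.min_region_size > 1 and sizes.min() < spec.min_region_size:
        warnings.warn(
            f"{int((sizes < spec.min_region_size).sum())} region(s) smaller "
            f"than the requested floor of {spec.min_region_size} voxels",
            stacklevel=2,
        )
    return Parcellation(
        labels=labels,
        affine=spec.affine(),
        name=f"synth-k{k}-s{spec.seed}",
        space="synthetic",
    )


def refine_parcellation(
    p: Parcellation, splits_per_region: int, seed: int = 0
) -> Parcellation:
    """Split every region into up to ``splits_per_region`` Voronoi cells.

    The output is a strict refinement of the input: each output region's
    voxel set lies inside exactly one input region.  Regions with fewer
    voxels than the requested split count are kept whole (with a
    warning).  Output labels are renumbered 1..k' in input-label order.
    """
    if splits_per_region < 1:
        raise ParameterError("splits_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    vs = np.asarray(p.voxel_size, dtype=float)
    out = np.zeros_like(p.labels)
    next_label = 1
    kept_whole = 0
    for label in np.unique(p.labels):
        if label == 0:
            continue
        idx = np.argwhere(p.labels == label)
        s = min(splits_per_region, idx.shape[0])
        if s < splits_per_region:
            kept_whole += 1
        seed_rows = rng.choice(idx.shape[0], size=s, replace=False)
        assign = _nearest_seed(idx * vs, idx[seed_rows] * vs)
        out[tuple(idx.T)] = next_label + assign
        next_label += s
    if kept_whole:
        warnings.warn(
            f"{kept_whole} region(s) smaller than {splits_per_region} voxels "
            "were kept whole",
            stacklevel=2,
        )
    return Parcellation(
        labels=out, affine=p.affine.copy(), name=f"{p.name}-refined", space=p.space
    )


def subregion_atlas(p: Parcellation, keep_labels: list[int]) -> Parcellation:
    """Keep only the listed regions; everything else becomes background.

    Emulates limited-coverage atlases (a single anatomical structure
    parcellated finely, the rest of the brain unlabeled).
    """
    if not keep_labels:
        raise ConsistencyError("keep_labels must be non-empty")
    present = set(np.unique(p.labels).tolist())
    missing = [l for l in keep_labels if l not in present]
    if missing:
        raise ConsistencyError(f"labels {missing} absent from the parcellation")
    keep = np.isin(p.labels, keep_labels)
    out = np.where(keep, p.labels, 0)
    return Parcellation(
        labels=out, affine=p.affine.copy(), name=f"{p.name}-sub", space=p.space
    )


def permute_labels(p: Parcellation, seed: int = 0) -> Parcellation:
    """Bijectively remap non-background labels; background untouched."""
    labels = np.unique(p.labels)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ParameterError("no non-background labels to permute")
    rng = np.random.default_rng(seed)
    target = labels[rng.permutation(labels.size)]
    lut = np.zeros(int(p.labels.max()) + 1, dtype=np.int64)
    lut[labels] = target
    out = lut[p.labels]
    return Parcellation(
        labels=out, affine=p.affine.copy(), name=f"{p.name}-perm", space=p.space
    )
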