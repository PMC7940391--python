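"""Nearest-neighbor resampling of label volumes, with ROI-loss accounting.

Nearest-neighbor is the only label-safe interpolation: any averaging
scheme would invent fractional labels.  Its price is that regions
smaller than the target voxel can vanish entirely when downsampling —
the smaller a region, the likelier the loss — so every resampling
returns a :class:`ResampleReport` listing the labels present before but
absent after.  Lost regions are then cataloged with null center/size in
the metadata sidecar via :func:`apply_lost_labels` rather than silently
dropped.

Registration to a template is deliberately not implemented here; the
standard workflow registers with an external tool (e.g. FSL ``flirt``)
and then compares on the shared grid.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import Parcellation, list_labels
from .errors import ConsistencyError, ParameterError
from .metadata import AtlasMetadata

__all__ = ["ResampleReport", "resample_labels", "apply_lost_labels"]


@dataclasses.dataclass
class ResampleReport:
    """Accounting of a label resampling step.

    ``lost_labels`` are the non-background labels with at least one voxel
    before and none after; nearest-neighbor sampling can never invent a
    label, so the label set after is always a subset of the set before.
    """

    source_voxel_size: tuple[float, float, float]
    target_voxel_size: tuple[float, float, float]
    lost_labels: list[int]
    label_counts_before: dict[int, int]
    label_counts_after: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "source_voxel_size": list(self.source_voxel_size),
            "target_voxel_size": list(self.target_voxel_size),
            "lost_labels": list(self.lost_labels),
            "label_counts_before": {str(k): v for k, v in self.label_counts_before.items()},
            "label_counts_after": {str(k): v for k, v in self.label_counts_after.items()},
        }


def resample_labels(
    p: Parcellation, target_voxel_size: float | tuple[float, float, float]
) -> tuple[Parcellation, ResampleReport]:
    """Resample a label volume to a new voxel size on a nested grid.

    The output grid spans the same world extent: its shape is
    ``ceil(source_extent / target_size)`` per axis, and its affine keeps
    the source rotation and origin (the first voxel's world position)
    with the spacing rescaled — so the standard 1/2/4 mm grids nest.
    Each output voxel takes the label of the source voxel whose center is
    nearest to the output voxel's center in world space; an exact halfway
    tie rounds toward the lower index (deterministic).  Resampling to the
    source voxel size is the identity.
    """
    if np.isscalar(target_voxel_size):
        target_voxel_size = (float(target_voxel_size),) * 3
    tvs = np.asarray(target_voxel_size, dtype=float)
    if tvs.shape != (3,) or np.any(tvs <= 0):
        raise ParameterError("target voxel size must be three positive mm values")
    svs = p.voxel_size
    scale = tvs / svs
    shape = np.asarray(p.shape)
    out_shape = np.ceil(shape * svs / tvs).astype(int)
    out_affine = p.affine.copy()
    out_affine[:3, :3] = p.affine[:3, :3] * scale[None, :]

    # With the output affine sharing the source origin and direction, output
    # index j maps to continuous source index j * scale exactly.
    src_idx = []
    for ax in range(3):
        cont = np.arange(out_shape[ax]) * scale[ax]
        # nearest index, halfway ties toward -inf
        idx = np.ceil(cont - 0.5).astype(np.int64)
        src_idx.append(np.clip(idx, 0, shape[ax] - 1))
    out = p.labels[np.ix_(src_idx[0], src_idx[1], src_idx[2])]

    before_labels = list_labels(p, include_background=False)
    before = {l: int(np.count_nonzero(p.labels == l)) for l in before_labels}
    after_counts = np.bincount(out.ravel(), minlength=int(p.labels.max()) + 1)
    after = {l: int(after_counts[l]) for l in before_labels}
    lost = [l for l in before_labels if after[l] == 0]

    resampled = Parcellation(
        labels=out, affine=out_affine, name=p.name, space=p.space
    )
    report = ResampleReport(
        source_voxel_size=tuple(float(v) for v in svs),
        target_voxel_size=tuple(float(v) for v in tvs),
        lost_labels=lost,
        label_counts_before=before,
        label_counts_after=after,
    )
    return resampled, report


def apply_lost_labels(m: AtlasMetadata, r: ResampleReport) -> AtlasMetadata:
    """Null out center and size of every lost region in a metadata document.

    The lost regions stay cataloged — only their center and size become
    null, signaling "this ROI existed at the native resolution but has no
    voxels here".  Raises :class:`ConsistencyError` if a lost label is
    not in the document at all.
    """
    missing = [l for l in r.lost_labels if l not in m.regions]
    if missing:
        raise ConsistencyError(
            f"lost labels {missing} are not cataloged in the metadata"
        )
    out = m.copy()
    for label in r.lost_labels:
        rec = out.regions[label]
        rec.center = None
        rec.size = None
    return out
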