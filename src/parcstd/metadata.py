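"""Atlas metadata sidecars: build, validate, read, write, and the
file-naming convention.

Every standardized atlas image travels with a JSON document holding two
blocks:

* ``"rois"`` — one record per region, keyed by the voxel value as a
  string; each record carries the anatomical name (JSON key ``"label"``,
  null for algorithmically generated atlases), the region center, the
  voxel count (``"size"``), and optional ``"description"`` and
  ``"color"`` ([R, G, B], each 0-255) fields.  A region that exists in
  the catalog but has no voxels at this resolution — an ROI lost to
  downsampling — keeps its record with null center and size.
* ``"metadata"`` — atlas-wide provenance: name, description, native
  coordinate space and source are mandatory; region count, average
  region volume, and the hierarchical/symmetrical flags are optional.

File names follow ``<atlas>_space-<space>_res-<dx>x<dy>x<dz>`` with
extension ``.nii.gz`` for images and ``.json`` for sidecars, e.g.
``Yeo-17_space-MNI152NLin6_res-1x1x1.nii.gz``.
"""

from __future__ import annotations

import copy as _copy
import dataclasses
import json
import re
from pathlib import Path

import numpy as np

from .core import Parcellation, list_labels, region_center, region_size
from .errors import MetadataError, NamingConventionError
from .errors import ParameterError

__all__ = [
    "RegionRecord",
    "AtlasWideBlock",
    "AtlasMetadata",
    "ValidationReport",
    "build_metadata",
    "validate_metadata",
    "read_metadata",
    "write_metadata",
    "make_filename",
    "parse_filename",
    "compute_optional_fields",
    "METADATA_SCHEMA",
]

#: Max |observed - cataloged| center distance (voxels) before a violation.
CENTER_TOLERANCE = 0.5

#: The sidecar schema, fixed by this package (JSON-Schema draft-07 shape).
#: The validator below enforces exactly these constraints in code.
METADATA_SCHEMA: dict = {
    "$schema": "http://json-schema.org/draft-07/schema#",
    "title": "parcstd atlas metadata sidecar",
    "type": "object",
    "required": ["metadata", "rois"],
    "properties": {
        "metadata": {
            "type": "object",
            "required": ["name", "description", "native_space", "source"],
            "properties": {
                "name": {"type": "string", "minLength": 1},
                "description": {"type": "string", "minLength": 1},
                "native_space": {"type": "string", "minLength": 1},
                "source": {"type": "string", "minLength": 1},
                "region_count": {"type": "integer", "minimum": 0},
                "average_region_volume": {"type": "number", "minimum": 0},
                "hierarchical": {"type": "boolean"},
                "symmetrical": {"type": "boolean"},
                "center_frame": {"enum": ["voxel", "world"]},
            },
        },
        "rois": {
            "type": "object",
            "patternProperties": {
                "^[1-9][0-9]*$": {
                    "type": "object",
                    "required": ["label", "center", "size"],
                    "properties": {
                        "label": {"type": ["string", "null"]},
                        "center": {
                            "type": ["array", "null"],
                            "items": {"type": "number"},
                            "minItems": 3,
                            "maxItems": 3,
                        },
                        "size": {"type": ["integer", "null"], "minimum": 1},
                        "description": {"type": "string"},
                        "color": {
                            "type": "array",
                            "items": {"type": "integer", "minimum": 0, "maximum": 255},
                            "minItems": 3,
                            "maxItems": 3,
                        },
                    },
                }
            },
        },
    },
}


@dataclasses.dataclass
class RegionRecord:
    """Per-ROI metadata.  ``label`` is the integer voxel value; ``name``
    the anatomical label (stored under the JSON key ``"label"``), null
    for algorithmic atlases.  ``center`` and ``size`` are null exactly
    when the region is absent from the volume (a lost ROI)."""

    label: int
    name: str | None = None
    center: tuple[float, float, float] | None = None
    size: int | None = None
    description: str | None = None
    color: tuple[int, int, int] | None = None


@dataclasses.dataclass
class AtlasWideBlock:
    """Atlas-wide provenance; the first four fields are mandatory."""

    name: str
    description: str
    native_space: str
    source: str
    region_count: int | None = None
    average_region_volume: float | None = None
    hierarchical: bool | None = None
    symmetrical: bool | None = None
    center_frame: str = "voxel"


@dataclasses.dataclass
class AtlasMetadata:
    """The full sidecar document: region records plus the atlas block."""

    regions: dict[int, RegionRecord]
    atlas: AtlasWideBlock

    def copy(self) -> "AtlasMetadata":
        return _copy.deepcopy(self)


@dataclasses.dataclass
class ValidationReport:
    """Validator outcome: ``violations`` are errors, ``warnings`` advisory."""

    violations: list[str] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == clean
        return self.ok


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------

def _require_atlas_block(atlas: AtlasWideBlock) -> None:
    for field in ("name", "description", "native_space", "source"):
        value = getattr(atlas, field)
        if not isinstance(value, str) or not value.strip():
            raise MetadataError(f"mandatory atlas-wide field {field!r} is missing/empty")


def build_metadata(
    p: Parcellation,
    atlas_block: AtlasWideBlock,
    label_names: dict[int, str] | None = None,
    expected_labels: list[int] | None = None,
) -> AtlasMetadata:
    """Assemble the sidecar document from a label volume.

    One record is created per label in ``expected_labels`` (default: the
    non-background labels observed in the volume).  Expected labels with
    no voxels get null center and size — the lost-ROI convention.
    Anatomical names default to null when not supplied, as appropriate
    for algorithmically generated atlases.  ``region_count`` and
    ``average_region_volume``, when not already set on the atlas block,
    are filled in from the volume.
    """
    _require_atlas_block(atlas_block)
    frame = atlas_block.center_frame
    if frame not in ("voxel", "world"):
        raise MetadataError(f"unknown center_frame {atlas_block.center_frame!r}")
    if expected_labels is None:
        expected_labels = list_labels(p, include_background=False)
    names = label_names or {}
    regions: dict[int, RegionRecord] = {}
    for label in sorted(set(int(l) for l in expected_labels)):
        if label < 1:
            raise MetadataError("region labels must be >= 1 (0 is background)")
        size = region_size(p, label)
        center = region_center(p, label, frame=frame)
        regions[label] = RegionRecord(
            label=label,
            name=names.get(label),
            center=None if center is None else tuple(float(c) for c in center),
            size=size if size > 0 else None,
        )
    atlas = _copy.deepcopy(atlas_block)
    present = [r for r in regions.values() if r.size is not None]
    if atlas.region_count is None:
        atlas.region_count = len(present)
    if atlas.average_region_volume is None and present:
        atlas.average_region_volume = float(np.mean([r.size for r in present]))
    return AtlasMetadata(regions=regions, atlas=atlas)


def compute_optional_fields(
    p: Parcellation, symmetry_fraction: float = 0.95
) -> tuple[int, float, bool]:
    """(region_count, average_region_volume, symmetrical) from a volume.

    ``symmetrical`` is True iff flipping the first spatial axis about the
    grid midline reproduces the foreground *support* (not the label
    identities) for at least ``symmetry_fraction`` of foreground voxels.
    """
    labels = list_labels(p, include_background=False)
    sizes = np.bincount(p.labels.ravel())[1:]
    sizes = sizes[sizes > 0]
    region_count = len(labels)
    average = float(sizes.mean()) if region_count else 0.0
    support = p.labels != 0
    n_fg = int(support.sum())
    if n_fg == 0:
        return region_count, average, False
    overlap = int((support & support[::-1, :, :]).sum())
    symmetrical = overlap / n_fg >= symmetry_fraction
    return region_count, average, symmetrical


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_metadata(
    m: AtlasMetadata, p: Parcellation | None = None
) -> ValidationReport:
    """Check a document against the schema, and optionally against the
    volume it describes.

    Violations (never raised, always reported): missing mandatory
    atlas-wide fields; malformed color; a record whose ``label`` field
    disagrees with its key; center/size nullity mismatch; with a volume:
    exact size mismatches, centers off by more than 0.5 voxel, and labels
    present in the volume but uncatalogued.  Anatomical names containing
    spaces produce warnings only.
    """
    report = ValidationReport()
    for field in ("name", "description", "native_space", "source"):
        value = getattr(m.atlas, field, None)
        if not isinstance(value, str) or not value.strip():
            report.violations.append(f"atlas-wide field '{field}' missing or empty")
    seen: set[int] = set()
    for key, rec in m.regions.items():
        tag = f"region {key}"
        if rec.label != key:
            report.violations.append(
                f"{tag}: record label {rec.label} disagrees with its key"
            )
        if rec.label in seen:
            report.violations.append(f"{tag}: duplicate label")
        seen.add(rec.label)
        if (rec.center is None) != (rec.size is None):
            report.violations.append(
                f"{tag}: center and size must be null together (lost ROI) "
                "or present together"
            )
        if rec.size is not None and rec.size < 1:
            report.violations.append(f"{tag}: size must be >= 1 when present")
        if rec.center is not None and len(rec.center) != 3:
            report.violations.append(f"{tag}: center must have 3 components")
        if rec.color is not None:
            c = rec.color
            if len(c) != 3 or any(
                (not isinstance(v, (int, np.integer))) or v < 0 or v > 255 for v in c
            ):
                report.violations.append(
                    f"{tag}: color must be [R, G, B] with integers in 0..255"
                )
        if rec.name is not None and " " in rec.name:
            report.warnings.append(
                f"{tag}: anatomical name contains spaces; convention is "
                "largest-to-smallest structures joined by underscores"
            )
    if m.atlas.region_count is not None:
        n_present = sum(1 for r in m.regions.values() if r.size is not None)
        if m.atlas.region_count != n_present:
            report.violations.append(
                f"atlas-wide region_count {m.atlas.region_count} differs from "
                f"the {n_present} records with non-null size"
            )
    if p is not None:
        frame = m.atlas.center_frame
        for label in list_labels(p, include_background=False):
            if label not in m.regions:
                report.violations.append(
                    f"uncatalogued label {label} present in the volume"
                )
        for key, rec in m.regions.items():
            observed_size = region_size(p, key)
            cat_size = rec.size if rec.size is not None else 0
            if observed_size != cat_size:
                report.violations.append(
                    f"region {key}: cataloged size {rec.size} but volume has "
                    f"{observed_size} voxels"
                )
                continue
            if rec.center is not None and observed_size > 0:
                observed = region_center(p, key, frame=frame)
                dist = float(np.linalg.norm(np.asarray(rec.center) - observed))
                if dist > CENTER_TOLERANCE:
                    report.violations.append(
                        f"region {key}: cataloged center off by {dist:.3f} "
                        f"(> {CENTER_TOLERANCE}) in the {frame} frame"
                    )
    return report


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _atlas_to_json(atlas: AtlasWideBlock) -> dict:
    out: dict = {
        "name": atlas.name,
        "description": atlas.description,
        "native_space": atlas.native_space,
        "source": atlas.source,
    }
    for field in (
        "region_count",
        "average_region_volume",
        "hierarchical",
        "symmetrical",
    ):
        value = getattr(atlas, field)
        if value is not None:
            out[field] = value
    out["center_frame"] = atlas.center_frame
    return out


def _record_to_json(rec: RegionRecord) -> dict:
    out: dict = {
        "label": rec.name,
        "center": None if rec.center is None else [float(c) for c in rec.center],
        "size": None if rec.size is None else int(rec.size),
    }
    if rec.description is not None:
        out["description"] = rec.description
    if rec.color is not None:
        out["color"] = [int(c) for c in rec.color]
    return out


def write_metadata(m: AtlasMetadata, path: str | Path) -> None:
    """Serialize to UTF-8 JSON, 2-space indent, regions in numeric label
    order and fixed key order — write/read/write is byte-identical."""
    doc = {
        "metadata": _atlas_to_json(m.atlas),
        "rois": {str(k): _record_to_json(m.regions[k]) for k in sorted(m.regions)},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_metadata(path: str | Path) -> AtlasMetadata:
    """Parse and structurally validate a sidecar document.

    Raises :class:`MetadataError` naming the offending field path on any
    schema violation; malformed JSON raises the same with the parser's
    message.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise MetadataError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "metadata" not in doc or "rois" not in doc:
        raise MetadataError(f"{path}: document must have 'metadata' and 'rois' blocks")
    meta = doc["metadata"]
    for field in ("name", "description", "native_space", "source"):
        if field not in meta or not isinstance(meta[field], str) or not meta[field]:
            raise MetadataError(f"{path}: metadata.{field} missing or empty")
    atlas = AtlasWideBlock(
        name=meta["name"],
        description=meta["description"],
        native_space=meta["native_space"],
        source=meta["source"],
        region_count=meta.get("region_count"),
        average_region_volume=meta.get("average_region_volume"),
        hierarchical=meta.get("hierarchical"),
        symmetrical=meta.get("symmetrical"),
        center_frame=meta.get("center_frame", "voxel"),
    )
    regions: dict[int, RegionRecord] = {}
    for key, rec in doc["rois"].items():
        try:
            label = int(key)
        except ValueError as exc:
            raise MetadataError(f"{path}: rois.{key}: key is not an integer") from exc
        if label < 1:
            raise MetadataError(f"{path}: rois.{key}: labels must be >= 1")
        for req in ("label", "center", "size"):
            if req not in rec:
                raise MetadataError(f"{path}: rois.{key}.{req} is required")
        center = rec["center"]
        if center is not None:
            if not isinstance(center, list) or len(center) != 3:
                raise MetadataError(f"{path}: rois.{key}.center must be a 3-vector or null")
            center = tuple(float(c) for c in center)
        size = rec["size"]
        if size is not None and (not isinstance(size, int) or size < 1):
            raise MetadataError(f"{path}: rois.{key}.size must be a positive integer or null")
        color = rec.get("color")
        if color is not None:
            if (
                not isinstance(color, list)
                or len(color) != 3
                or any(not isinstance(v, int) or v < 0 or v > 255 for v in color)
            ):
                raise MetadataError(f"{path}: rois.{key}.color must be [R,G,B] in 0..255")
            color = tuple(color)
        regions[label] = RegionRecord(
            label=label,
            name=rec["label"],
            center=center,
            size=size,
            description=rec.get("description"),
            color=color,
        )
    return AtlasMetadata(regions=regions, atlas=atlas)


# ---------------------------------------------------------------------------
# Filename convention
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9.\-]*$")
_FILE_RE = re.compile(
    r"^(?P<name>[A-Za-z0-9][A-Za-z0-9.\-]*)"
    r"_space-(?P<space>[A-Za-z0-9][A-Za-z0-9.\-]*)"
    r"_res-(?P<res>[^_]+?)"
    r"(?P<ext>\.nii\.gz|\.json)$"
)


def _fmt_res(v: float) -> str:
    f = float(v)
    if f <= 0:
        raise ParameterError("voxel sizes must be positive")
    return str(int(f)) if f == int(f) else repr(f)


def make_filename(
    atlas_name: str,
    space: str,
    voxel_size: tuple[float, float, float],
    kind: str = "image",
) -> str:
    """``<name>_space-<space>_res-<dx>x<dy>x<dz>`` + ``.nii.gz``/``.json``.

    Atlas and space names must be single tokens (letters, digits, ``-``,
    ``.``): underscores and spaces are the convention's field separators
    and may not appear inside a field.
    """
    for value, what in ((atlas_name, "atlas name"), (space, "space tag")):
        if not _NAME_RE.match(value or ""):
            raise NamingConventionError(
                f"{what} {value!r} must be a single token without spaces or underscores"
            )
    if kind not in ("image", "metadata"):
        raise NamingConventionError(f"kind must be 'image' or 'metadata', got {kind!r}")
    res = "x".join(_fmt_res(v) for v in voxel_size)
    ext = ".nii.gz" if kind == "image" else ".json"
    return f"{atlas_name}_space-{space}_res-{res}{ext}"


def parse_filename(filename: str) -> tuple[str, str, tuple[float, float, float], str]:
    """Inverse of :func:`make_filename`; raises on non-conforming names."""
    m = _FILE_RE.match(Path(filename).name)
    if not m:
        raise NamingConventionError(
            f"{filename!r} does not follow <name>_space-<space>_res-<r>x<r>x<r>"
        )
    parts = m.group("res").split("x")
    if len(parts) != 3:
        raise NamingConventionError(
            f"{filename!r}: resolution token must have three 'x'-separated sizes"
        )
    try:
        voxel_size = tuple(float(p) for p in parts)
    except ValueError as exc:
        raise NamingConventionError(f"{filename!r}: non-numeric resolution") from exc
    if any(v <= 0 for v in voxel_size):
        raise NamingConventionError(f"{filename!r}: non-positive resolution")
    kind = "image" if m.group("ext") == ".nii.gz" else "metadata"
    return m.group("name"), m.group("space"), voxel_size, kind
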