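"""Instance-annotation I/O and geometry plumbing.

Reads and writes the two polygon annotation dialects used around the
measurement pipeline (VGG Image Annotator JSON and YOLO-segmentation label
text), rasterizes polygons to per-instance binary masks, tiles large
microscopy frames, and applies geometric augmentations with exact polygon
co-transforms.

Coordinate conventions
----------------------
Pixel coordinates are 0-based with origin at the top-left corner, x growing
rightward (columns) and y growing downward (rows).  Pixel ``(r, c)`` has its
center at the continuous point ``(x=c, y=r)``: a polygon vertex at integer
coordinates lies exactly on a pixel center.  Rasterization uses the even-odd
rule and counts pixels whose center falls on a polygon edge as foreground,
so the operation is deterministic and orientation-independent.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger("fibrometry")

#: Cell classes the pipeline distinguishes.
KNOWN_CLASSES = ("fiber", "vessel")

#: Microns per pixel of the reference imaging setup (10x objective,
#: 0.70x C-mount, DFC7000T camera).
DEFAULT_UM_PER_PX = 0.65


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PolygonAnnotation:
    """One labeled closed polygon outlining a cell instance.

    Vertices are ``(x, y)`` float pixel coordinates; the polygon is closed
    implicitly (last vertex connects back to the first).
    """

    class_label: str
    vertices: np.ndarray  # (N, 2) float array of (x, y)
    confidence: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise AnnotationError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise AnnotationError("polygon needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise AnnotationError("polygon vertices contain NaN/inf")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class ImageAnnotationSet:
    """All polygon annotations of one image."""

    image_id: str
    width_px: int
    height_px: int
    annotations: list[PolygonAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise AnnotationError("image dimensions must be positive")


@dataclass
class InstanceMask:
    """Full binary mask of one cell instance.

    ``grid`` is stored cropped to the instance bounding box; ``offset`` is
    the ``(row, col)`` of the grid's top-left pixel in the parent image.
    Masks of different instances may overlap: macerated cells are
    translucent, so each overlapping cell keeps its complete mask.
    """

    class_label: str
    offset: tuple[int, int]
    grid: np.ndarray  # 2-D bool
    confidence: float | None = None
    instance_id: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise AnnotationError("mask grid must be 2-D")
        if not self.grid.any():
            raise AnnotationError("mask has no foreground pixel")
        r, c = self.offset
        if r < 0 or c < 0:
            raise AnnotationError("mask offset must be non-negative")
        self.offset = (int(r), int(c))

    @property
    def area_px(self) -> int:
        """Foreground pixel count."""
        return int(self.grid.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1) half-open bounding box in parent frame."""
        r, c = self.offset
        return (r, c, r + self.grid.shape[0], c + self.grid.shape[1])

    def to_full_frame(self, height_px: int, width_px: int) -> np.ndarray:
        """Embed the cropped grid into a full-frame boolean array."""
        r0, c0, r1, c1 = self.bbox
        if r1 > height_px or c1 > width_px:
            raise AnnotationError("mask extends beyond the parent frame")
        full = np.zeros((height_px, width_px), dtype=bool)
        full[r0:r1, c0:c1] = self.grid
        return full


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration converting pixel measures to microns."""

    um_per_px: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")


def mask_from_full_frame(
    full: np.ndarray,
    class_label: str,
    confidence: float | None = None,
    instance_id: str | None = None,
) -> InstanceMask:
    """Crop a full-frame boolean array to its bounding box as an InstanceMask."""
    full = np.asarray(full, dtype=bool)
    rows = np.flatnonzero(full.any(axis=1))
    cols = np.flatnonzero(full.any(axis=0))
    if rows.size == 0:
        raise AnnotationError("mask has no foreground pixel")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return InstanceMask(
        class_label=class_label,
        offset=(int(r0), int(c0)),
        grid=full[r0:r1, c0:c1].copy(),
        confidence=confidence,
        instance_id=instance_id,
    )


# ---------------------------------------------------------------------------
# VGG Image Annotator JSON
# ---------------------------------------------------------------------------


def _extract_class_label(region_attributes: dict) -> str | None:
    """Pull a class label out of a VIA region_attributes dict.

    Accepts either an attribute whose *value* is a known class name
    (case-insensitive) or an attribute named ``label``/``class``/``type``.
    Unknown labels are preserved verbatim.
    """
    for value in region_attributes.values():
        if isinstance(value, str) and value.strip().lower() in KNOWN_CLASSES:
            return value.strip().lower()
    for key in ("label", "class", "type"):
        value = region_attributes.get(key)
        if isinstance(value, str) and value.strip():
            return value.strip()
    return None


def _parse_via_regions(
    image_id: str, entry: dict
) -> tuple[list[PolygonAnnotation], int]:
    annotations: list[PolygonAnnotation] = []
    dropped = 0
    regions = entry.get("regions", [])
    if isinstance(regions, dict):  # very old VIA exports use a dict
        regions = [regions[k] for k in sorted(regions)]
    for idx, region in enumerate(regions):
        shape = region.get("shape_attributes")
        if shape is None:
            logger.error("image %r region %d: missing shape_attributes", image_id, idx)
            continue
        if shape.get("name") not in (None, "polygon", "polyline"):
            logger.error(
                "image %r region %d: unsupported shape %r",
                image_id, idx, shape.get("name"),
            )
            continue
        try:
            xs = shape["all_points_x"]
            ys = shape["all_points_y"]
        except KeyError as exc:
            logger.error("image %r region %d: missing %s", image_id, idx, exc)
            continue
        if len(xs) != len(ys):
            logger.error("image %r region %d: x/y length mismatch", image_id, idx)
            continue
        if len(xs) < 3:
            dropped += 1
            continue
        label = _extract_class_label(region.get("region_attributes", {}))
        if label is None:
            label = "fiber"
            logger.warning(
                "image %r region %d: no class attribute, defaulting to 'fiber'",
                image_id, idx,
            )
        elif label not in KNOWN_CLASSES:
            logger.warning(
                "image %r region %d: unknown class label %r preserved",
                image_id, idx, label,
            )
        conf = region.get("region_attributes", {}).get("confidence")
        annotations.append(
            PolygonAnnotation(
                class_label=label,
                vertices=np.column_stack([xs, ys]).astype(float),
                confidence=float(conf) if conf is not None else None,
            )
        )
    return annotations, dropped


def read_vgg_json(path: str | Path) -> list[ImageAnnotationSet]:
    """Read a VGG Image Annotator (VIA) JSON file.

    Both the full project export (``_via_img_metadata``) and the plain
    image-keyed region-list dialect are accepted.  Polygons with fewer than
    3 points are dropped (with a logged count); unknown class labels are
    preserved verbatim with a warning.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed VGG JSON in {path.name}: {exc}") from exc
    if not isinstance(data, dict):
        raise AnnotationError(f"malformed VGG JSON in {path.name}: top level is not an object")

    metadata = data.get("_via_img_metadata", data)
    sets: list[ImageAnnotationSet] = []
    total_dropped = 0
    for key, entry in metadata.items():
        if key.startswith("_via_"):  # project settings blocks
            continue
        if not isinstance(entry, dict) or "regions" not in entry and "filename" not in entry:
            raise AnnotationError(f"malformed VGG JSON: unexpected entry under key {key!r}")
        image_id = entry.get("filename") or key
        annotations, dropped = _parse_via_regions(image_id, entry)
        total_dropped += dropped
        fattr = entry.get("file_attributes", {}) or {}
        width = fattr.get("width")
        height = fattr.get("height")
        if width is None or height is None:
            # VIA does not store image dimensions; fall back to the
            # polygon extent so downstream bounds checks stay meaningful.
            if annotations:
                all_v = np.vstack([a.vertices for a in annotations])
                width = int(np.ceil(all_v[:, 0].max())) + 1
                height = int(np.ceil(all_v[:, 1].max())) + 1
            else:
                width = height = 1
        sets.append(
            ImageAnnotationSet(
                image_id=str(image_id),
                width_px=int(width),
                height_px=int(height),
                annotations=annotations,
            )
        )
    if total_dropped:
        logger.warning("dropped %d region(s) with fewer than 3 points", total_dropped)
    return sets


def write_vgg_json(sets: Sequence[ImageAnnotationSet], path: str | Path) -> None:
    """Write annotation sets as a plain image-keyed VIA JSON file."""
    out: dict = {}
    for aset in sets:
        regions = []
        for ann in aset.annotations:
            attrs: dict = {"label": ann.class_label}
            if ann.confidence is not None:
                attrs["confidence"] = ann.confidence
            regions.append(
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(x) for x in ann.vertices[:, 0]],
                        "all_points_y": [float(y) for y in ann.vertices[:, 1]],
                    },
                    "region_attributes": attrs,
                }
            )
        out[aset.image_id] = {
            "filename": aset.image_id,
            "file_attributes": {"width": aset.width_px, "height": aset.height_px},
            "regions": regions,
        }
    Path(path).write_text(json.dumps(out, indent=1))


# ---------------------------------------------------------------------------
# YOLO segmentation labels
# ---------------------------------------------------------------------------


def write_yolo_seg_labels(
    aset: ImageAnnotationSet, class_order: Sequence[str]
) -> list[str]:
    """Serialize one image's polygons as YOLO-segmentation label lines.

    One line per annotation: class index followed by x y pairs normalized to
    [0, 1] by image width/height, fixed at 6 decimals.
    """
    lines = []
    for ann in aset.annotations:
        if ann.class_label not in class_order:
            raise AnnotationError(
                f"class label {ann.class_label!r} not in class_order {list(class_order)}"
            )
        idx = list(class_order).index(ann.class_label)
        coords = np.empty(ann.vertices.shape, dtype=float)
        coords[:, 0] = ann.vertices[:, 0] / aset.width_px
        coords[:, 1] = ann.vertices[:, 1] / aset.height_px
        nums = " ".join(f"{v:.6f}" for v in coords.ravel())
        lines.append(f"{idx} {nums}")
    return lines


def read_yolo_seg_labels(
    lines: Iterable[str],
    class_order: Sequence[str],
    width_px: int,
    height_px: int,
    image_id: str = "image",
) -> ImageAnnotationSet:
    """Parse YOLO-segmentation label lines back into an annotation set.

    An optional trailing confidence column (odd number of coordinates plus
    one) is accepted, matching prediction exports.
    """
    annotations = []
    for lineno, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        cls_idx = int(parts[0])
        values = [float(v) for v in parts[1:]]
        confidence = None
        if len(values) % 2 == 1:
            confidence = values[-1]
            values = values[:-1]
        if len(values) < 6:
            raise AnnotationError(f"line {lineno + 1}: fewer than 3 polygon points")
        coords = np.array(values, dtype=float).reshape(-1, 2)
        coords[:, 0] *= width_px
        coords[:, 1] *= height_px
        annotations.append(
            PolygonAnnotation(
                class_label=class_order[cls_idx],
                vertices=coords,
                confidence=confidence,
            )
        )
    return ImageAnnotationSet(
        image_id=image_id, width_px=width_px, height_px=height_px,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Rasterization and polygon geometry
# ---------------------------------------------------------------------------


def polygon_area_px2(poly: PolygonAnnotation | np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon, in px^2.

    Orientation-independent; degenerate (collinear) polygons give 0.0.
    """
    v = poly.vertices if isinstance(poly, PolygonAnnotation) else np.asarray(poly, float)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _points_on_boundary(px: np.ndarray, py: np.ndarray, verts: np.ndarray,
                        tol: float = 1e-9) -> np.ndarray:
    """Boolean mask of points lying on any polygon edge (within tol)."""
    on = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 < tol:
            on |= (np.abs(px - x1) < tol) & (np.abs(py - y1) < tol)
            continue
        # perpendicular distance via cross product + projection within segment
        cross = (px - x1) * dy - (py - y1) * dx
        t = ((px - x1) * dx + (py - y1) * dy) / seg2
        on |= (np.abs(cross) <= tol * np.sqrt(seg2)) & (t >= -tol) & (t <= 1 + tol)
    return on


def _points_in_polygon_evenodd(px: np.ndarray, py: np.ndarray,
                               verts: np.ndarray) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test, boundary-inclusive."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)
    return inside | _points_on_boundary(px, py, verts)


def rasterize_polygon(
    poly: PolygonAnnotation, height_px: int, width_px: int
) -> InstanceMask:
    """Rasterize a polygon to a cropped InstanceMask.

    A pixel is foreground iff its center lies inside the polygon by the
    even-odd rule or exactly on its boundary.  Self-intersecting polygons
    are resolved by the same even-odd rule, consistent with the absolute
    shoelace area.
    """
    v = poly.vertices
    # degenerate = all vertices collinear (a self-intersecting polygon can
    # have zero signed area yet positive even-odd coverage)
    rel = v - v[0]
    cross = rel[:, 0, None] * rel[None, :, 1] - rel[:, 1, None] * rel[None, :, 0]
    if np.abs(cross).max() < 1e-12:
        raise AnnotationError("degenerate polygon")
    c0 = max(0, int(np.floor(v[:, 0].min())))
    c1 = min(width_px - 1, int(np.ceil(v[:, 0].max())))
    r0 = max(0, int(np.floor(v[:, 1].min())))
    r1 = min(height_px - 1, int(np.ceil(v[:, 1].max())))
    if c1 < c0 or r1 < r0:
        raise AnnotationError("polygon lies outside the image frame")
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    px, py = np.meshgrid(cols.astype(float), rows.astype(float))
    grid = _points_in_polygon_evenodd(px, py, v)
    if not grid.any():
        raise AnnotationError("degenerate polygon")
    return mask_from_full_frame(
        np.pad(grid, ((r0, max(0, height_px - r1 - 1)), (c0, max(0, width_px - c1 - 1)))),
        class_label=poly.class_label,
        confidence=poly.confidence,
    )


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def tile_image(
    width_px: int, height_px: int, tile_px: int, overlap_frac: float = 0.0
) -> list[tuple[int, int, int, int]]:
    """Compute tile windows ``(row0, col0, rows, cols)`` covering an image.

    Stride is ``floor(tile_px * (1 - overlap_frac))``; the last row/column of
    windows is shifted inward so no window exceeds the image.  Windows are
    returned in row-major order and jointly cover every pixel.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    if tile_px < 64:
        raise ValueError("tile_px must be >= 64")

    def starts(dim: int) -> list[int]:
        if tile_px >= dim:
            return [0]
        stride = max(1, int(np.floor(tile_px * (1 - overlap_frac))))
        out = list(range(0, dim - tile_px + 1, stride))
        if out[-1] + tile_px < dim:
            out.append(dim - tile_px)
        return out

    rows = min(tile_px, height_px)
    cols = min(tile_px, width_px)
    return [
        (r0, c0, rows, cols)
        for r0 in starts(height_px)
        for c0 in starts(width_px)
    ]


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

_SCALE_RE = re.compile(r"^scale\((?P<s>[0-9.]+)\)$")


def augment(
    aset: ImageAnnotationSet, op: str, factor: float | None = None
) -> ImageAnnotationSet:
    """Apply one geometric augmentation with the exact polygon co-transform.

    ``op`` is one of ``rot90``, ``rot180``, ``rot270``, ``fliph``, ``flipv``,
    ``scale`` (with ``factor``) or ``scale(s)``.  Rotations are clockwise.
    Every op is exactly invertible on vertices (scale by its reciprocal).
    """
    w, h = float(aset.width_px), float(aset.height_px)
    m = _SCALE_RE.match(op)
    if m:
        op, factor = "scale", float(m.group("s"))

    if op == "scale":
        if factor is None:
            raise ValueError("scale requires a factor")
        if not 0.5 <= factor <= 2.0:
            raise ValueError("scale factor must be in [0.5, 2.0]")
        tf = lambda v: v * factor
        new_w, new_h = w * factor, h * factor
    elif op == "fliph":
        tf = lambda v: np.column_stack([w - v[:, 0], v[:, 1]])
        new_w, new_h = w, h
    elif op == "flipv":
        tf = lambda v: np.column_stack([v[:, 0], h - v[:, 1]])
        new_w, new_h = w, h
    elif op == "rot90":
        tf = lambda v: np.column_stack([h - v[:, 1], v[:, 0]])
        new_w, new_h = h, w
    elif op == "rot180":
        tf = lambda v: np.column_stack([w - v[:, 0], h - v[:, 1]])
        new_w, new_h = w, h
    elif op == "rot270":
        tf = lambda v: np.column_stack([v[:, 1], w - v[:, 0]])
        new_w, new_h = h, w
    else:
        raise ValueError(f"unknown augmentation op {op!r}")

    return ImageAnnotationSet(
        image_id=aset.image_id,
        width_px=int(round(new_w)),
        height_px=int(round(new_h)),
        annotations=[
            PolygonAnnotation(a.class_label, tf(a.vertices), a.confidence)
            for a in aset.annotations
        ],
    )


# ---------------------------------------------------------------------------
# Train/validation split
# ---------------------------------------------------------------------------


def split_manifest(
    image_ids: Sequence[str], train_frac: float, seed: int
) -> tuple[list[str], list[str]]:
    """Randomly split image ids into train/validation manifests.

    Deterministic given the seed; |train| = round(train_frac * N).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    ids = list(image_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 image ids to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(train_frac * len(ids) + 0.5))
    train = [ids[i] for i in sorted(order[:n_train])]
    val = [ids[i] for i in sorted(order[n_train:])]
    return train, val


def write_manifest(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_manifest(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# Per-instance mask PNGs
# ---------------------------------------------------------------------------


def save_mask_png(
    mask: InstanceMask, height_px: int, width_px: int, path: str | Path
) -> None:
    """Write one instance mask as a full-frame 8-bit PNG (0/255)."""
    full = mask.to_full_frame(height_px, width_px)
    Image.fromarray((full * np.uint8(255))).save(str(path))


def load_mask_png(
    path: str | Path,
    class_label: str | None = None,
    confidence: float | None = None,
    instance_id: str | None = None,
) -> InstanceMask:
    """Read a full-frame instance-mask PNG written by :func:`save_mask_png`.

    When ``class_label``/``instance_id`` are omitted they are parsed from the
    ``{image_id}_{instance_idx}_{class}.png`` filename pattern.
    """
    path = Path(path)
    if class_label is None or instance_id is None:
        stem_parts = path.stem.rsplit("_", 2)
        if len(stem_parts) == 3:
            class_label = class_label or stem_parts[2]
            instance_id = instance_id or f"{stem_parts[0]}_{stem_parts[1]}"
        else:
            class_label = class_label or "fiber"
            instance_id = instance_id or path.stem
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return mask_from_full_frame(
        arr >= 128, class_label=class_label,
        confidence=confidence, instance_id=instance_id,
    )
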