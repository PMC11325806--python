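"""Seeded generator of synthetic macerated-slide scenes.

Produces brightfield-like images of overlapping, translucent elongated
cells — long thin fibers and shorter wider vessels — together with exact
per-instance ground truth (centerline arc length, width, area and the FULL
un-occluded mask of every instance).  This stands in for stained wood
macerate microscopy so the measurement, evaluation and statistics modules
can be exercised end to end with known answers.

Geometry: each cell is a constant-width stadium — a disk of diameter
``width`` swept along a gently curved quadratic Bezier centerline — so the
true length (centerline arc length), width, and area
(``L*w + pi*(w/2)^2``) have closed forms.  Real fibers taper toward their
tips; that is deliberately not modeled.

Optics: the background is a bright field (mean gray ~0.92 of full scale)
with per-pixel Gaussian noise.  Each cell multiplies the transmitted light
by ``exp(-absorbance)`` wherever its mask covers a pixel (Beer-Lambert
stacking), so pixels covered by two cells are darker than pixels covered by
one while both cells keep their complete masks — the translucent-overlap
regime the measurement pipeline must handle.

Default cell-size distributions are scaled from typical aspen macerate
averages (fibers ~310 um x 23 um, vessels ~247 um x 51 um) at the reference
calibration of 0.65 um/px.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import measure as skmeasure

from .annotation_io import (
    ImageAnnotationSet,
    InstanceMask,
    PolygonAnnotation,
    mask_from_full_frame,
    save_mask_png,
    write_vgg_json,
)


class PlacementError(RuntimeError):
    """Raised when a centerline cannot be placed inside the frame."""


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Length distributions are log-normal, parameterized by the (mean, sd) of
    the length itself (not of its log); widths are normal truncated at 3 px.
    ``curvature`` bounds the perpendicular bow of a centerline as a fraction
    of its length.  ``absorbance`` is the per-class Beer-Lambert optical
    density of one cell layer; ``noise_sd`` the grayscale noise sd on a
    [0, 1] intensity scale.
    """

    width_px: int = 2048
    height_px: int = 2048
    n_fibers: int = 12
    n_vessels: int = 4
    fiber_length_px: tuple[float, float] = (460.0, 120.0)
    fiber_width_px: tuple[float, float] = (35.0, 5.0)
    vessel_length_px: tuple[float, float] = (380.0, 80.0)
    vessel_width_px: tuple[float, float] = (78.0, 8.0)
    curvature: float = 0.15
    absorbance: dict = field(
        default_factory=lambda: {"fiber": 0.35, "vessel": 0.5}
    )
    noise_sd: float = 0.02
    seed: int = 0
    allow_border: bool = False  # disable in-frame rejection (border test cases)

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) < 256:
            raise ValueError("scene dimensions must be >= 256 px")
        if self.n_fibers < 0 or self.n_vessels < 0:
            raise ValueError("instance counts must be >= 0")
        if not 0 <= self.curvature <= 0.3:
            raise ValueError("curvature must be in [0, 0.3]")
        for name in ("fiber_length_px", "fiber_width_px",
                     "vessel_length_px", "vessel_width_px"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd <= 0:
                raise ValueError(f"{name} parameters must be positive")

    def to_config(self) -> str:
        """Flat key=value serialization."""
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, (tuple, list)):
                v = ",".join(str(x) for x in v)
            elif isinstance(v, dict):
                v = ",".join(f"{kk}:{vv}" for kk, vv in v.items())
            lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SceneSpec":
        kwargs: dict = {}
        valid = set(cls.__dataclass_fields__)
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"unknown scene config key {key!r}")
            if key in ("width_px", "height_px", "n_fibers", "n_vessels", "seed"):
                kwargs[key] = int(value)
            elif key in ("curvature", "noise_sd"):
                kwargs[key] = float(value)
            elif key == "allow_border":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key == "absorbance":
                kwargs[key] = {
                    kk: float(vv)
                    for kk, vv in (pair.split(":") for pair in value.split(","))
                }
            else:
                kwargs[key] = tuple(float(x) for x in value.split(","))
        return cls(**kwargs)


@dataclass
class GroundTruthInstance:
    """One synthetic cell with its exact ground truth."""

    instance_id: str
    class_label: str
    centerline: np.ndarray  # (N, 2) float (x, y)
    true_length_px: float
    true_width_px: float
    true_area_px2: float
    full_mask: InstanceMask
    outline: PolygonAnnotation


@dataclass
class SyntheticScene:
    """Rendered image plus per-instance ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    instances: list[GroundTruthInstance]
    spec: SceneSpec
    image_id: str = "synthetic"


# ---------------------------------------------------------------------------
# Centerline sampling
# ---------------------------------------------------------------------------


def polyline_arc_length(points: np.ndarray) -> float:
    """Arc length of a polyline given as an (N, 2) array."""
    d = np.diff(np.asarray(points, dtype=float), axis=0)
    return float(np.sqrt((d ** 2).sum(axis=1)).sum())


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2


def sample_centerline(
    rng: np.random.Generator,
    length_px: float,
    curvature: float,
    bounds: tuple[float, float, float, float],
    max_attempts: int = 100,
) -> np.ndarray:
    """Sample a quadratic-Bezier centerline of the requested arc length.

    The control point sits at the chord midpoint plus a perpendicular offset
    of at most ``curvature * length``; the chord is rescaled iteratively so
    the arc length matches ``length_px`` within 2%.  The polyline is
    discretized at steps of at most 0.5 px and must lie entirely inside
    ``bounds = (xmin, ymin, xmax, ymax)``; placement is re-attempted up to
    ``max_attempts`` times before failing.
    """
    if length_px < 10:
        raise ValueError("centerline length must be >= 10 px")
    xmin, ymin, xmax, ymax = bounds
    for _ in range(max_attempts):
        theta = rng.uniform(0, 2 * np.pi)
        offset = rng.uniform(-curvature, curvature) * length_px
        direction = np.array([np.cos(theta), np.sin(theta)])
        normal = np.array([-direction[1], direction[0]])
        chord = length_px
        pts = None
        for _ in range(6):  # fixed-point iteration on the chord length
            p0 = np.zeros(2)
            p2 = direction * chord
            p1 = (p0 + p2) / 2 + normal * offset
            n = max(int(np.ceil(1.1 * length_px / 0.4)), 8)
            pts = _bezier_points(p0, p1, p2, n)
            arc = polyline_arc_length(pts)
            if abs(arc - length_px) / length_px <= 0.005:
                break
            chord *= length_px / arc
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        span = hi - lo
        if span[0] > xmax - xmin or span[1] > ymax - ymin:
            continue
        origin = np.array([
            rng.uniform(xmin - lo[0], xmax - hi[0]),
            rng.uniform(ymin - lo[1], ymax - hi[1]),
        ])
        return pts + origin
    raise PlacementError("scene too crowded")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length steps."""
    points = np.asarray(points, dtype=float)
    seg = np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    x = np.interp(si, s, points[:, 0])
    y = np.interp(si, s, points[:, 1])
    return np.column_stack([x, y])


def render_instance(
    centerline: np.ndarray,
    width_px: float,
    frame_height_px: int | None = None,
    frame_width_px: int | None = None,
    class_label: str = "fiber",
    instance_id: str | None = None,
) -> tuple[InstanceMask, PolygonAnnotation]:
    """Rasterize the stadium sweep of a centerline at the given width.

    A pixel is foreground iff its center lies within ``width/2`` of the
    centerline polyline (exact point-to-segment distance, accumulated over
    a local window per segment).  Returns the full instance mask plus its
    traced boundary outline.  When frame dimensions are given the mask is
    clipped to the frame.
    """
    if width_px < 3:
        raise ValueError("width must be >= 3 px")
    centerline = np.atleast_2d(np.asarray(centerline, dtype=float))
    # 2-px resampling: with the gentle curvatures generated here the chord
    # deviates from the curve by well under 0.01 px
    pts = _resample_polyline(centerline, 2.0)
    half = width_px / 2.0
    lo = pts.min(axis=0) - half - 1
    hi = pts.max(axis=0) + half + 1
    c0, r0 = int(np.floor(lo[0])), int(np.floor(lo[1]))
    c1, r1 = int(np.ceil(hi[0])), int(np.ceil(hi[1]))
    if frame_width_px is not None:
        c0, c1 = max(c0, 0), min(c1, frame_width_px - 1)
    if frame_height_px is not None:
        r0, r1 = max(r0, 0), min(r1, frame_height_px - 1)
    nrows, ncols = r1 - r0 + 1, c1 - c0 + 1
    dmin = np.full((nrows, ncols), np.inf)
    pad = int(np.ceil(half)) + 1
    if len(pts) == 1:
        pts = np.vstack([pts, pts])
    # exact point-to-segment distance, accumulated over a local window
    # around each polyline segment
    for a, b in zip(pts[:-1], pts[1:]):
        wc0 = max(int(np.floor(min(a[0], b[0]))) - pad - c0, 0)
        wc1 = min(int(np.ceil(max(a[0], b[0]))) + pad - c0, ncols - 1)
        wr0 = max(int(np.floor(min(a[1], b[1]))) - pad - r0, 0)
        wr1 = min(int(np.ceil(max(a[1], b[1]))) + pad - r0, nrows - 1)
        if wc1 < wc0 or wr1 < wr0:
            continue
        px = np.arange(wc0 + c0, wc1 + c0 + 1, dtype=float)[None, :]
        py = np.arange(wr0 + r0, wr1 + r0 + 1, dtype=float)[:, None]
        ab = b - a
        seg2 = ab @ ab
        if seg2 == 0:
            d = np.hypot(px - a[0], py - a[1])
        else:
            t = np.clip(((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / seg2, 0, 1)
            d = np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))
        np.minimum(dmin[wr0:wr1 + 1, wc0:wc1 + 1], d,
                   out=dmin[wr0:wr1 + 1, wc0:wc1 + 1])
    grid = dmin <= half

    rr = np.flatnonzero(grid.any(axis=1))
    cc = np.flatnonzero(grid.any(axis=0))
    grid = grid[rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1]
    mask = InstanceMask(
        class_label=class_label,
        offset=(r0 + int(rr[0]), c0 + int(cc[0])),
        grid=grid,
        instance_id=instance_id,
    )

    # boundary outline traced on the padded grid, mapped to frame coords
    contours = skmeasure.find_contours(np.pad(grid, 1).astype(float), 0.5)
    contour = max(contours, key=len)
    verts = np.column_stack([
        contour[:, 1] - 1 + mask.offset[1],  # x = col
        contour[:, 0] - 1 + mask.offset[0],  # y = row
    ])
    # light decimation keeps outlines compact without visible geometry loss
    if len(verts) > 16:
        keep = np.arange(0, len(verts), 2)
        verts = verts[keep]
    outline = PolygonAnnotation(class_label=class_label, vertices=verts)
    return mask, outline


def stadium_area_px2(length_px: float, width_px: float) -> float:
    """Closed-form area of a stadium: L*w + pi*(w/2)^2."""
    return length_px * width_px + np.pi * (width_px / 2.0) ** 2


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lower:
            return float(v)
    return float(lower)


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw parameterized by the mean and sd of the variable."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


#: Per-class transmitted-light tint (relative channel absorbance weights),
#: loosely imitating safranin-stained material.
CLASS_TINT = {
    "fiber": np.array([0.5, 1.2, 1.0]),
    "vessel": np.array([0.6, 1.0, 1.2]),
}


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a full synthetic scene from its spec.

    Byte-identical output for identical ``(spec, seed)``.  Every instance's
    full mask is stored un-occluded even where instances overlap.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    instances: list[GroundTruthInstance] = []

    plan = [("fiber", spec.fiber_length_px, spec.fiber_width_px)] * spec.n_fibers
    plan += [("vessel", spec.vessel_length_px, spec.vessel_width_px)] * spec.n_vessels

    for i, (label, ldist, wdist) in enumerate(plan):
        length = max(_lognormal(rng, *ldist), 10.0)
        width = _truncated_normal(rng, *wdist, lower=3.0)
        margin = width / 2.0 + 1.0
        if spec.allow_border:
            bounds = (-margin, -margin, w - 1 + margin, h - 1 + margin)
        else:
            bounds = (margin, margin, w - 1 - margin, h - 1 - margin)
        centerline = sample_centerline(rng, length, spec.curvature, bounds)
        iid = f"{label}_{i:03d}"
        mask, outline = render_instance(
            centerline, width, frame_height_px=h, frame_width_px=w,
            class_label=label, instance_id=iid,
        )
        instances.append(
            GroundTruthInstance(
                instance_id=iid,
                class_label=label,
                centerline=centerline,
                true_length_px=polyline_arc_length(centerline),
                true_width_px=width,
                true_area_px2=stadium_area_px2(polyline_arc_length(centerline), width),
                full_mask=mask,
                outline=outline,
            )
        )

    # Beer-Lambert stacking: transmittance multiplies per covering instance
    absorbance = np.zeros((h, w, 3), dtype=float)
    for inst in instances:
        a = spec.absorbance.get(inst.class_label, 0.4)
        tint = CLASS_TINT.get(inst.class_label, np.ones(3))
        r0, c0, r1, c1 = inst.full_mask.bbox
        region = absorbance[r0:r1, c0:c1]
        region += inst.full_mask.grid[:, :, None] * (a * tint)[None, None, :]
    image = 0.92 * np.exp(-absorbance)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticScene(
        image=(image * 255).round().astype(np.uint8),
        instances=instances,
        spec=spec,
        image_id=f"synthetic_seed{spec.seed}",
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

GT_CSV_COLUMNS = ("instance_id", "class", "true_length_px", "true_width_px",
                  "true_area_px2")


def export_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write a scene bundle re-importable by the annotation reader.

    Files: the rendered image PNG, one full-frame mask PNG per instance
    (``{image_id}_{idx}_{class}.png``), a VGG-dialect JSON of the outlines,
    a ground-truth CSV and a centerlines JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = scene.spec
    paths: dict[str, Path] = {}

    img_path = out / f"{scene.image_id}.png"
    Image.fromarray(scene.image).save(str(img_path))
    paths["image"] = img_path

    for idx, inst in enumerate(scene.instances):
        mpath = out / f"{scene.image_id}_{idx}_{inst.class_label}.png"
        save_mask_png(inst.full_mask, spec.height_px, spec.width_px, mpath)

    aset = ImageAnnotationSet(
        image_id=scene.image_id,
        width_px=spec.width_px,
        height_px=spec.height_px,
        annotations=[inst.outline for inst in scene.instances],
    )
    json_path = out / f"{scene.image_id}_annotations.json"
    write_vgg_json([aset], json_path)
    paths["annotations"] = json_path

    csv_path = out / f"{scene.image_id}_ground_truth.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GT_CSV_COLUMNS)
        for inst in scene.instances:
            writer.writerow([
                inst.instance_id, inst.class_label,
                f"{inst.true_length_px:.4f}", f"{inst.true_width_px:.4f}",
                f"{inst.true_area_px2:.4f}",
            ])
    paths["ground_truth"] = csv_path

    cl_path = out / f"{scene.image_id}_centerlines.json"
    cl_path.write_text(json.dumps({
        inst.instance_id: [[float(x), float(y)] for x, y in inst.centerline]
        for inst in scene.instances
    }))
    paths["centerlines"] = cl_path

    cfg_path = out / f"{scene.image_id}_spec.cfg"
    cfg_path.write_text(spec.to_config())
    paths["spec"] = cfg_path
    return paths


def load_scene_masks(out_dir: str | Path, image_id: str) -> list[InstanceMask]:
    """Re-load the per-instance mask PNGs of an exported scene bundle."""
    from .annotation_io import load_mask_png

    out = Path(out_dir)
    found = []
    for path in out.glob(f"{image_id}_*_*.png"):
        parts = path.stem.rsplit("_", 2)
        if len(parts) != 3 or not parts[1].isdigit():
            continue
        found.append((int(parts[1]), path))
    return [load_mask_png(path) for _, path in sorted(found)]
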