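"""Pipeline orchestration: simulate -> segment -> measure -> evaluate -> compare.

Whole-slide macerate scans are far larger than what a segmentation backend
ingests at once, so large frames are tiled (default 1024 px tiles with 10%
overlap, mirroring common microscope tile acquisition), the backend runs
per tile, and per-tile detections are merged back into the global frame
with IoU-based de-duplication.  Border exclusion is always evaluated on the
GLOBAL frame: an instance touching an interior tile edge is not a border
instance.

The segmentation backend is an interface, not an implementation — anything
that emits per-instance masks or polygons with confidences plugs in.  For
testing, the synthetic generator's ground truth serves as an oracle
backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .annotation_io import Calibration, InstanceMask, mask_from_full_frame
from .detection_eval import mask_iou
from .morphometry import MorphometryRecord, measure_collection

logger = logging.getLogger("fibrometry")


@dataclass
class PipelineConfig:
    """Knobs shared across pipeline stages.

    ``iou_dedup_threshold``: same-class detections from overlapping tiles
    with mask IoU at or above this are duplicates of one instance (genuinely
    distinct overlapping cells rarely exceed 0.5 IoU; re-detections of the
    same cell exceed 0.9).  ``confidence_floor`` drops low-confidence
    backend output before any measurement.
    """

    um_per_px: float = 0.65
    tile_px: int = 1024
    tile_overlap: float = 0.1
    iou_dedup_threshold: float = 0.8
    confidence_floor: float = 0.25
    seed: int = 0
    length_mode: str = "pixel_count"
    width_bias_correction: bool = False
    border_margin: int = 0
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.tile_px < 256:
            raise ValueError("tile_px must be >= 256")
        for name in ("iou_dedup_threshold", "confidence_floor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def calibration(self) -> Calibration:
        return Calibration(um_per_px=self.um_per_px)

    def to_config(self) -> str:
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_config(cls, text: str) -> "PipelineConfig":
        kwargs: dict = {}
        fields_ = cls.__dataclass_fields__
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields_:
                raise ValueError(f"unknown config key {key!r}")
            typ = fields_[key].type
            if typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            elif typ == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Tiled detection merge
# ---------------------------------------------------------------------------


@dataclass
class TileDetections:
    """Backend output for one tile window, in tile-local coordinates."""

    window: tuple[int, int, int, int]  # (row0, col0, rows, cols)
    instances: list[InstanceMask] = field(default_factory=list)


def crop_instance_to_window(
    inst: InstanceMask, window: tuple[int, int, int, int]
) -> InstanceMask | None:
    """Clip a global-frame instance to one tile window (tile-local coords).

    Returns None when the instance has no foreground inside the window.
    Used by the oracle backend to emulate what a per-tile segmenter sees.
    """
    wr0, wc0, wrows, wcols = window
    r0, c0, r1, c1 = inst.bbox
    rr0, cc0 = max(r0, wr0), max(c0, wc0)
    rr1, cc1 = min(r1, wr0 + wrows), min(c1, wc0 + wcols)
    if rr1 <= rr0 or cc1 <= cc0:
        return None
    sub = inst.grid[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    if not sub.any():
        return None
    import numpy as np

    rows = np.flatnonzero(sub.any(axis=1))
    cols = np.flatnonzero(sub.any(axis=0))
    return InstanceMask(
        class_label=inst.class_label,
        offset=(rr0 - wr0 + int(rows[0]), cc0 - wc0 + int(cols[0])),
        grid=sub[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].copy(),
        confidence=inst.confidence,
        instance_id=inst.instance_id,
    )


def _touches_interior_edge(
    local: InstanceMask, window: tuple[int, int, int, int],
    frame_height_px: int, frame_width_px: int,
) -> bool:
    """True iff the tile-local instance touches a tile edge that is not
    also the global image border."""
    wr0, wc0, wrows, wcols = window
    r0, c0, r1, c1 = local.bbox
    if r0 == 0 and wr0 > 0:
        return True
    if c0 == 0 and wc0 > 0:
        return True
    if r1 == wrows and wr0 + wrows < frame_height_px:
        return True
    if c1 == wcols and wc0 + wcols < frame_width_px:
        return True
    return False


def _to_global(local: InstanceMask, window: tuple[int, int, int, int]) -> InstanceMask:
    wr0, wc0, _, _ = window
    return InstanceMask(
        class_label=local.class_label,
        offset=(local.offset[0] + wr0, local.offset[1] + wc0),
        grid=local.grid,
        confidence=local.confidence,
        instance_id=local.instance_id,
    )


def _intersection_over_smaller(a: InstanceMask, b: InstanceMask) -> float:
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r1 <= r0 or c1 <= c0:
        return 0.0
    inter = int((
        a.grid[r0 - ar0:r1 - ar0, c0 - ac0:c1 - ac0]
        & b.grid[r0 - br0:r1 - br0, c0 - bc0:c1 - bc0]
    ).sum())
    return inter / min(a.area_px, b.area_px)


def merge_tile_detections(
    tile_detections: list[TileDetections],
    frame_height_px: int,
    frame_width_px: int,
    iou_dedup_threshold: float = 0.8,
) -> tuple[list[InstanceMask], list[InstanceMask]]:
    """Merge per-tile detections into a deduplicated global instance list.

    Detections are shifted to global coordinates.  Detections that touch an
    interior tile edge (but not the global border) are fragments of a cell
    the tile cut off; a fragment is kept only when a complete copy of the
    same cell exists in some other tile — it is then absorbed into that
    copy — otherwise it is flagged and returned in the ``fragmented`` list,
    excluded from measurement.  Among complete detections, same-class pairs
    with mask IoU >= threshold collapse to the higher-confidence one.

    Returns ``(kept, fragmented)``, both in global coordinates.
    """
    complete: list[InstanceMask] = []
    fragments: list[InstanceMask] = []
    for td in tile_detections:
        wr0, wc0, wrows, wcols = td.window
        if wr0 < 0 or wc0 < 0:
            raise ValueError("inconsistent tile offsets")
        for local in td.instances:
            if (local.offset[0] + local.grid.shape[0] > wrows
                    or local.offset[1] + local.grid.shape[1] > wcols):
                raise ValueError("inconsistent tile offsets")
            target = (
                fragments
                if _touches_interior_edge(local, td.window,
                                          frame_height_px, frame_width_px)
                else complete
            )
            target.append(_to_global(local, td.window))

    # dedup complete detections, highest confidence first
    complete.sort(
        key=lambda m: (-(m.confidence if m.confidence is not None else 1.0),
                       m.instance_id or "")
    )
    kept: list[InstanceMask] = []
    n_dups = 0
    for cand in complete:
        dup = any(
            k.class_label == cand.class_label
            and mask_iou(k, cand) >= iou_dedup_threshold
            for k in kept
        )
        if dup:
            n_dups += 1
        else:
            kept.append(cand)

    # fragments: absorbed when a kept complete detection covers them
    fragmented: list[InstanceMask] = []
    n_absorbed = 0
    for frag in fragments:
        covered = any(
            k.class_label == frag.class_label
            and _intersection_over_smaller(k, frag) >= iou_dedup_threshold
            for k in kept
        )
        if covered:
            n_absorbed += 1
        else:
            fragmented.append(frag)
    logger.info(
        "tile merge: %d kept, %d duplicates collapsed, %d fragments absorbed, "
        "%d fragmented (excluded)",
        len(kept), n_dups, n_absorbed, len(fragmented),
    )
    return kept, fragmented


# ---------------------------------------------------------------------------
# Measurement orchestration
# ---------------------------------------------------------------------------


def measure_frame(
    instances: list[InstanceMask],
    frame_height_px: int,
    frame_width_px: int,
    config: PipelineConfig,
    image_id: str = "",
) -> list[MorphometryRecord]:
    """Measure a global-frame instance list under the pipeline config."""
    records = measure_collection(
        instances,
        config.calibration,
        frame_height_px,
        frame_width_px,
        exclude_border=config.exclude_border,
        length_mode=config.length_mode,
        width_bias_correction=config.width_bias_correction,
        border_margin=config.border_margin,
        image_id=image_id,
    )
    n_excl = sum(r.excluded for r in records)
    logger.info(
        "measured %d instance(s): %d in summaries, %d border-excluded",
        len(records), len(records) - n_excl, n_excl,
    )
    return records


def measure_tiled(
    instances: list[InstanceMask],
    frame_height_px: int,
    frame_width_px: int,
    config: PipelineConfig,
    image_id: str = "",
) -> tuple[list[MorphometryRecord], list[InstanceMask]]:
    """Tiled measurement path: tile, crop, merge, then measure globally.

    Emulates running a per-tile segmentation backend with the oracle
    (ground-truth) instances: every instance is cropped to each tile that
    sees it, the per-tile detections are merged with de-duplication, and the
    surviving global instances are measured.  For instances complete within
    at least one tile this is exactly equivalent to whole-frame measurement.
    """
    from .annotation_io import tile_image

    windows = tile_image(frame_width_px, frame_height_px,
                         config.tile_px, config.tile_overlap)
    tiles = []
    for win in windows:
        dets = []
        for inst in instances:
            local = crop_instance_to_window(inst, win)
            if local is not None:
                dets.append(local)
        tiles.append(TileDetections(window=win, instances=dets))
    kept, fragmented = merge_tile_detections(
        tiles, frame_height_px, frame_width_px,
        iou_dedup_threshold=config.iou_dedup_threshold,
    )
    records = measure_frame(kept, frame_height_px, frame_width_px, config,
                            image_id=image_id)
    return records, fragmented


def load_bundle_instances(bundle_dir: str | Path, image_id: str) -> list[InstanceMask]:
    """Load the per-instance masks of an exported scene bundle."""
    from .synthetic import load_scene_masks

    return load_scene_masks(bundle_dir, image_id)


def find_bundle_image_ids(bundle_dir: str | Path) -> list[str]:
    """Image ids present in a directory of exported scene bundles."""
    out = []
    for path in sorted(Path(bundle_dir).glob("*_ground_truth.csv")):
        out.append(path.name[: -len("_ground_truth.csv")])
    return out
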