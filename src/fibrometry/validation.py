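"""Self-validation experiments on synthetic scenes.

Each function runs one end-to-end experiment against the synthetic
generator's exact ground truth and returns plain numbers: how well the
measurement pipeline recovers known centerline lengths and widths, whether
tiled and whole-frame measurement agree, whether group means from disjoint
crops of the same cell population are statistically indistinguishable, and
whether the two-sample test is calibrated (type-I error, power on a planted
length difference of the size reported for GA20-oxidase overexpression
lines).

All randomness derives from the single ``seed`` argument, so every
experiment is reproducible.  Problem sizes (scene dimensions, instance
counts, repetition counts) are fixed here as the package's validation
conditions; the morphometry length mode used for recovery is
``weighted_path``, the orientation-unbiased estimator (``pixel_count``
undercounts oblique skeletons by construction and is provided for parity
with summation-based pipelines, not for physical recovery).
"""

from __future__ import annotations

import numpy as np

from .annotation_io import InstanceMask
from .detection_eval import APSummary, map_metrics
from .pipeline import PipelineConfig, measure_frame, measure_tiled
from .stats_report import t_test
from .synthetic import SceneSpec, _lognormal, render_scene


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 9973 + salt) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def length_width_recovery(
    seed: int, n_per_class: int = 200, per_scene: int = 25
) -> dict:
    """Measure synthetic cells and compare to realized ground truth.

    Renders enough default-parameter scenes to accumulate ``n_per_class``
    fibers and vessels, runs the full measurement pipeline
    (weighted-path length, distance-transform width), and reports the
    realized ground-truth means next to the measured means.
    """
    n_scenes = int(np.ceil(n_per_class / per_scene))
    cfg = PipelineConfig(length_mode="weighted_path")
    acc: dict = {
        cls: {"true_l": [], "meas_l": [], "true_w": [], "meas_w": []}
        for cls in ("fiber", "vessel")
    }
    for k in range(n_scenes):
        spec = SceneSpec(
            width_px=1600, height_px=1600,
            n_fibers=per_scene, n_vessels=per_scene,
            seed=_derived_seed(seed, k),
        )
        scene = render_scene(spec)
        records = measure_frame(
            [i.full_mask for i in scene.instances], 1600, 1600, cfg,
            image_id=scene.image_id,
        )
        by_id = {r.instance_id: r for r in records}
        for inst in scene.instances:
            rec = by_id[inst.instance_id]
            if rec.excluded:
                continue
            d = acc[inst.class_label]
            d["true_l"].append(inst.true_length_px)
            d["meas_l"].append(rec.length_px)
            d["true_w"].append(inst.true_width_px)
            d["meas_w"].append(rec.width_px)
    out = {}
    for cls, d in acc.items():
        true_l = float(np.mean(d["true_l"]))
        meas_l = float(np.mean(d["meas_l"]))
        true_w = float(np.mean(d["true_w"]))
        meas_w = float(np.mean(d["meas_w"]))
        out[cls] = {
            "n": len(d["true_l"]),
            "true_mean_length_px": true_l,
            "measured_mean_length_px": meas_l,
            "length_rel_error": (meas_l - true_l) / true_l,
            "true_mean_width_px": true_w,
            "measured_mean_width_px": meas_w,
            "width_abs_error_px": meas_w - true_w,
        }
    return out


# ---------------------------------------------------------------------------
# Scale invariance
# ---------------------------------------------------------------------------


def tiled_vs_whole(seed: int) -> dict:
    """Compare tiled-path and whole-frame measurement records.

    Default scene; 1280-px tiles at 50% overlap so most instances are
    complete within at least one tile.  Returns counts of compared and
    mismatching records (mismatch = any differing measurement field).
    """
    spec = SceneSpec(seed=_derived_seed(seed, 101))
    scene = render_scene(spec)
    cfg = PipelineConfig(tile_px=1280, tile_overlap=0.5,
                         length_mode="weighted_path")
    gts = [i.full_mask for i in scene.instances]
    for g in gts:
        g.confidence = 1.0
    whole = {r.instance_id: r for r in measure_frame(
        gts, spec.height_px, spec.width_px, cfg, image_id=scene.image_id)}
    tiled, fragmented = measure_tiled(
        gts, spec.height_px, spec.width_px, cfg, image_id=scene.image_id)
    mismatched = 0
    for r in tiled:
        w = whole[r.instance_id]
        if (r.length_px, r.width_px, r.area_px2, r.touches_border) != \
                (w.length_px, w.width_px, w.area_px2, w.touches_border):
            mismatched += 1
    return {
        "n_instances": len(gts),
        "n_compared": len(tiled),
        "n_mismatched": mismatched,
        "n_fragmented": len(fragmented),
    }


def disjoint_crop_pvalues(
    seed: int, reps: int = 20, n_per_group: int = 100
) -> list[float]:
    """Null comparison of fiber-length means across disjoint fields of view.

    Each repetition renders two independent scenes (disjoint fields of the
    same simulated slide population, ``n_per_group`` fibers each), measures
    them with the full pipeline, and runs the pooled two-sample t-test on
    the measured lengths.  Under scale invariance the p-values are uniform;
    the expected pass rate of p > 0.05 is 95%.
    """
    pvals = []
    for k in range(reps):
        samples = []
        for side in (0, 1):
            spec = SceneSpec(
                width_px=1280, height_px=1280,
                n_fibers=n_per_group, n_vessels=0,
                seed=_derived_seed(seed, 200 + 2 * k + side),
            )
            scene = render_scene(spec)
            cfg = PipelineConfig(length_mode="weighted_path")
            records = measure_frame(
                [i.full_mask for i in scene.instances], 1280, 1280, cfg)
            samples.append([r.length_um for r in records if not r.excluded])
        pvals.append(t_test(samples[0], samples[1]).p_value)
    return pvals


# ---------------------------------------------------------------------------
# Statistical calibration
# ---------------------------------------------------------------------------


def null_type_i_error(
    seed: int, reps: int = 2000, n: int = 50, alpha: float = 0.05
) -> float:
    """Fraction of null two-sample comparisons with p < alpha.

    Both samples are drawn from the fiber-length distribution of the
    synthetic generator's defaults, so this calibrates the test under the
    same skewed (log-normal) lengths the pipeline produces.
    """
    rng = np.random.default_rng(_derived_seed(seed, 301))
    mean, sd = SceneSpec().fiber_length_px
    hits = 0
    for _ in range(reps):
        a = [_lognormal(rng, mean, sd) for _ in range(n)]
        b = [_lognormal(rng, mean, sd) for _ in range(n)]
        if t_test(a, b).p_value < alpha:
            hits += 1
    return hits / reps


def planted_difference_pvalues(
    seed: int, reps: int = 20, n: int = 500, effect: float = 0.12
) -> list[float]:
    """Power check: a planted relative mean-length difference at n per group.

    Mirrors comparing a fiber-elongation overexpression line against its
    wildtype control: group two's length distribution is shifted by
    ``effect`` (default +12%).
    """
    rng = np.random.default_rng(_derived_seed(seed, 401))
    mean, sd = SceneSpec().fiber_length_px
    pvals = []
    for _ in range(reps):
        a = [_lognormal(rng, mean, sd) for _ in range(n)]
        b = [_lognormal(rng, mean * (1 + effect), sd) for _ in range(n)]
        pvals.append(t_test(a, b).p_value)
    return pvals


# ---------------------------------------------------------------------------
# Evaluation sanity
# ---------------------------------------------------------------------------


def perfect_prediction_map(seed: int) -> APSummary:
    """Evaluate ground truth against itself: every mAP must be exactly 1."""
    spec = SceneSpec(
        width_px=768, height_px=768, n_fibers=6, n_vessels=3,
        fiber_length_px=(220.0, 50.0), fiber_width_px=(12.0, 2.0),
        vessel_length_px=(180.0, 30.0), vessel_width_px=(26.0, 4.0),
        seed=_derived_seed(seed, 501),
    )
    scene = render_scene(spec)
    gts = [i.full_mask for i in scene.instances]
    preds = [
        InstanceMask(
            class_label=g.class_label, offset=g.offset, grid=g.grid,
            confidence=0.9, instance_id=f"pred_{k}",
        )
        for k, g in enumerate(gts)
    ]
    return map_metrics(preds, gts)
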