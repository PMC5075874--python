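"""Reproducible synthetic benchmarks exercising the full analysis path.

Each benchmark regenerates its inputs from a seed, runs the ordinary analysis
functions (never ground-truth shortcuts, except to score the output), and
returns summary statistics.  Problem sizes are chosen to finish in a few
minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ViabilityConfig
from .phenotyping import estimate_time_of_death
from .segmentation import extract_components, fit_area_model, mask_worms
from .separation import SeparationConfig, separate_component
from .survival import chip_survival
from .synthetic import ClusterSpec, PlacementError, SceneSpec, generate_assay_timelapse, render_scene

_CONTACTS = ("side_touch", "end_touch", "mixed")


@dataclass
class SeparationBenchmarkResult:
    recovered: int
    total: int
    n_clusters: int
    per_contact: dict

    @property
    def fraction(self) -> float:
        return self.recovered / self.total if self.total else float("nan")


def _iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    inter = int((mask_a & mask_b).sum())
    union = int((mask_a | mask_b).sum())
    return inter / union if union else 0.0


def separation_benchmark(
    n_clusters: int = 200,
    seed: int = 1,
    n_isolated: int = 5,
    iou_threshold: float = 0.7,
    config: SeparationConfig | None = None,
) -> SeparationBenchmarkResult:
    """Score the separation algorithm on random touching-worm clusters.

    Each scene holds one cluster of 2-5 worms (contact type drawn uniformly
    from side/end/mixed) plus ``n_isolated`` single worms that calibrate the
    area model, exactly as single worms dominate a real chamber.  A clustered
    worm counts as recovered when some separated instance matches its ground
    truth at IoU >= ``iou_threshold``.
    """
    meta_rng = np.random.default_rng(seed)
    scene_seeds = meta_rng.integers(0, 2**31 - 1, size=4 * n_clusters)
    recovered = total = done = 0
    per_contact = {c: [0, 0] for c in _CONTACTS}
    seed_idx = 0
    while done < n_clusters and seed_idx < len(scene_seeds):
        scene_seed = int(scene_seeds[seed_idx])
        seed_idx += 1
        rng = np.random.default_rng(scene_seed)
        k = int(rng.integers(2, 6))
        contact = _CONTACTS[int(rng.integers(0, 3))]
        spec = SceneSpec(
            image_height_px=384,
            image_width_px=384,
            n_worms=k + n_isolated,
            cluster_plan=(ClusterSpec(tuple(range(k)), contact),),
            seed=scene_seed,
        )
        try:
            bf, _, gt = render_scene(spec)
        except PlacementError:
            continue  # crowded draw; replace with the next seed
        mask = mask_worms(bf)
        comps = extract_components(mask, bf.darkness)
        if len(comps) < 5:
            continue
        model = fit_area_model(comps)

        # separate every component that holds part of the cluster (contacts
        # can be broken by segmentation itself, which is a valid separation)
        cluster_mask = np.zeros_like(gt.worm_mask)
        for worm_id in range(1, k + 1):
            cluster_mask |= gt.mask_of(worm_id)
        inst_masks = []
        for comp in comps:
            if comp.global_mask(cluster_mask.shape)[cluster_mask].any():
                result = separate_component(comp, model, config)
                inst_masks.extend(
                    inst.mask(cluster_mask.shape) for inst in result.instances
                )
        for worm_id in range(1, k + 1):
            truth = gt.mask_of(worm_id)
            best_iou = max((_iou(truth, m) for m in inst_masks), default=0.0)
            total += 1
            per_contact[contact][1] += 1
            if best_iou >= iou_threshold:
                recovered += 1
                per_contact[contact][0] += 1
        done += 1
    return SeparationBenchmarkResult(
        recovered, total, done,
        {c: {"recovered": v[0], "total": v[1]} for c, v in per_contact.items()},
    )


@dataclass
class TodRobustnessResult:
    n_worms: int
    n_within_2h: int
    errors_h: list

    @property
    def fraction_within_2h(self) -> float:
        return self.n_within_2h / self.n_worms if self.n_worms else float("nan")


def tod_robustness(
    n_worms: int = 50,
    seed: int = 2,
    worms_per_scene: int = 10,
    thresholds: tuple[float, ...] | None = None,
    n_frames: int = 30,
) -> TodRobustnessResult:
    """Time-of-death accuracy across the configured viability-threshold band.

    Simulates hourly-imaged assays with known integer death hours, classifies
    every worm in every frame at several fixed thresholds spanning the
    configured robustness range, and checks that the estimated time of death
    stays within 2 h of the truth at every threshold.
    """
    if thresholds is None:
        lo, hi = ViabilityConfig().threshold_range
        thresholds = tuple(np.round(np.linspace(lo, hi, 4), 3))
    meta_rng = np.random.default_rng(seed)
    n_scenes = math.ceil(n_worms / worms_per_scene)
    n_ok = 0
    errors: list[float] = []
    counted = 0
    for s in range(n_scenes):
        scene_seed = int(meta_rng.integers(0, 2**31 - 1))
        nw = min(worms_per_scene, n_worms - counted)
        spec = SceneSpec(
            image_height_px=288, image_width_px=288, n_worms=nw,
            seed=scene_seed,
        )
        death_times = [float(meta_rng.integers(4, n_frames - 5)) for _ in range(nw)]
        frames = generate_assay_timelapse(
            spec, death_times, frame_interval_h=1.0, n_frames=n_frames,
            speeds_px=[0.0] * nw, render_pairs=False,
        )
        # per-frame opacity per ground-truth worm via the measured components
        opacity: dict[int, list[float | None]] = {i: [] for i in range(nw)}
        times = []
        for af in frames:
            bf = af.brightfield[0]
            gt = af.truth[0]
            mask = mask_worms(bf)
            comps = extract_components(mask, bf.darkness)
            times.append(af.time_h)
            for i in range(nw):
                truth = gt.mask_of(i + 1)
                best, best_ov = None, 0
                for comp in comps:
                    ov = int(comp.global_mask(truth.shape)[truth].sum())
                    if ov > best_ov:
                        best, best_ov = comp, ov
                opacity[i].append(best.mean_darkness if best is not None else None)
        for i in range(nw):
            worst_err = 0.0
            for thr in thresholds:
                alive = [
                    (o is not None) and (o > thr) for o in opacity[i]
                ]
                tod = estimate_time_of_death(times, alive)
                err = abs(tod - death_times[i]) if math.isfinite(tod) else math.inf
                worst_err = max(worst_err, err)
            errors.append(worst_err)
            if worst_err <= 2.0:
                n_ok += 1
        counted += nw
    return TodRobustnessResult(counted, n_ok, errors)


def area_model_recovery(n_scenes: int = 20, seed: int = 3) -> list[float]:
    """Relative error of the single-worm area estimate on 30-worm scenes
    with ~20% of worms in clusters.  Returns one relative error per scene."""
    meta_rng = np.random.default_rng(seed)
    errors = []
    s = 0
    while len(errors) < n_scenes:
        scene_seed = int(meta_rng.integers(0, 2**31 - 1))
        s += 1
        if s > 3 * n_scenes:
            break
        spec = SceneSpec(
            image_height_px=820, image_width_px=820, n_worms=30,
            cluster_plan=(
                ClusterSpec((0, 1, 2), "side_touch"),
                ClusterSpec((3, 4, 5), "mixed"),
            ),
            seed=scene_seed,
        )
        try:
            bf, _, gt = render_scene(spec)
        except PlacementError:
            continue
        comps = extract_components(mask_worms(bf), bf.darkness)
        if len(comps) < 5:
            continue
        model = fit_area_model(comps)
        truth = float(np.mean([w.area_px for w in gt.worms]))
        errors.append(abs(model.single_worm_area_px - truth) / truth)
    return errors


def exponential_death_recovery(
    n_seeds: int = 50, seed: int = 4, n_worms: int = 30,
    rate_per_h: float = 1 / 24, horizon_h: int = 80,
) -> float:
    """Fraction of survival-grid points where the chip estimator falls within
    the 95% binomial band around the exponential closed form e^(-rate*t)."""
    meta_rng = np.random.default_rng(seed)
    inside = total = 0
    grid = np.arange(0, horizon_h + 1, 4.0)
    for _ in range(n_seeds):
        rng = np.random.default_rng(int(meta_rng.integers(0, 2**31 - 1)))
        deaths = rng.exponential(1.0 / rate_per_h, size=n_worms)
        counts = [(deaths > t).sum() for t in grid]
        curve = chip_survival(counts, grid, n_worms)
        S_true = np.exp(-rate_per_h * grid)
        band = 1.96 * np.sqrt(S_true * (1 - S_true) / n_worms)
        inside += int(np.sum(np.abs(curve.survival - S_true) <= band + 1e-12))
        total += len(grid)
    return inside / total
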