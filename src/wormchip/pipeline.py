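"""End-to-end orchestration: frames in, measurement tables and survival out.

Per chamber the pipeline makes two passes.  The first masks every primary
(pair-0) bright-field frame and pools the component areas to fit the area
model.  The second separates each frame's components into worm instances and
measures opacity, viability, fluorescence and motility per instance.  The
survival curve is then the per-frame count of instances classified alive
divided by the initial worm count — exact on a chip, where no worm can leave.

Worm identities are NOT tracked across frames (future work in the original
workflow); motility pairs each pair-1 instance with the overlapping pair-0
instance within the same ~1 s frame pair, which is unambiguous at that
time scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import Frame, MEASUREMENT_COLUMNS, load_series, write_results
from .phenotyping import classify_viability, measure_fluorescence, measure_motility
from .segmentation import annotate_components, extract_components, fit_area_model, mask_worms
from .separation import SeparationResult, separate_component
from .survival import chip_survival

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _mask_frame(frame: Frame, cfg: RunConfig, min_area: float | None = None):
    m = cfg.masking
    return mask_worms(
        frame,
        method=m.method,
        k_sigma=m.k_sigma,
        bg_window_px=m.bg_window_px,
        min_contrast=m.min_contrast,
        min_object_area_px=min_area,
        min_object_area_frac=m.min_object_area_frac,
    )


def analyze_chamber(frames: list[Frame], cfg: RunConfig):
    """Analyze all frames of one chamber.

    Returns ``(measurements, label_masks, area_model, survival_df)``.
    """
    by_key = {(f.channel, f.time_h, f.pair_index): f for f in frames}
    primary = sorted(
        (f for f in frames if f.channel == "brightfield" and f.pair_index == 0),
        key=lambda f: f.time_h,
    )
    if not primary:
        raise PipelineError("chamber has no pair-0 bright-field frames")
    chamber = primary[0].chamber_id

    # pass 1: masks and pooled component areas for the area model
    masks = {f.time_h: _mask_frame(f, cfg) for f in primary}
    all_components = {
        t: extract_components(masks[t], by_key[("brightfield", t, 0)].darkness)
        for t in masks
    }
    pooled = [c for comps in all_components.values() for c in comps]
    area_model = fit_area_model(pooled, min_object_area_frac=cfg.masking.min_object_area_frac)

    rows: list[dict] = []
    label_masks: dict[str, np.ndarray] = {}
    alive_counts: list[int] = []
    times: list[float] = []
    initial_n: int | None = cfg.initial_n

    for f in primary:
        t = f.time_h
        comps = all_components[t]
        annotate_components(comps, area_model)
        worm_mask = masks[t].mask
        darkness = f.darkness
        instances = []
        for comp in comps:
            res: SeparationResult = separate_component(comp, area_model, cfg.separation)
            instances.extend(res.instances)

        # motility: separate the pair-1 frame and match instances by overlap
        motility_by_instance: dict[int, float] = {}
        later = by_key.get(("brightfield", t, 1))
        if later is not None:
            later_mask = _mask_frame(later, cfg)
            later_instances = []
            for comp in extract_components(later_mask, later.darkness):
                annotate_components([comp], area_model)
                later_instances.extend(
                    separate_component(comp, area_model, cfg.separation).instances
                )
            earlier_global = worm_mask
            taken: set[int] = set()
            for linst in later_instances:
                mot = measure_motility(linst, earlier_global)
                lmask = linst.mask(darkness.shape)
                best, best_ov = None, 0
                for i, inst in enumerate(instances):
                    if i in taken:
                        continue
                    ov = int((lmask[inst.rows, inst.cols]).sum())
                    if ov > best_ov:
                        best, best_ov = i, ov
                if best is not None:
                    motility_by_instance[best] = mot
                    taken.add(best)

        fl = by_key.get(("fluorescence", t, 0))
        label = np.zeros(darkness.shape, dtype=np.int32)
        n_alive = 0
        for i, inst in enumerate(instances):
            label[inst.rows, inst.cols] = i + 1
            call = classify_viability(
                inst, darkness, worm_mask,
                mode=cfg.viability.mode,
                fixed_threshold=cfg.viability.fixed_threshold,
                neighborhood_width_px=cfg.viability.neighborhood_width_px,
            )
            if call.viability == "alive":
                n_alive += 1
            fluor = (
                measure_fluorescence(inst, fl.pixels, worm_mask)
                if fl is not None else float("nan")
            )
            rows.append(
                {
                    "chamber_id": chamber,
                    "time_h": t,
                    "worm_id": i + 1,
                    "area_px": inst.area_px,
                    "fluorescence_total": fluor,
                    "opacity": call.opacity,
                    "motility": motility_by_instance.get(i, float("nan")),
                    "viability": call.viability,
                    "confidence": inst.confidence,
                }
            )
        label_masks[f"{chamber}_t{t:g}"] = label
        alive_counts.append(n_alive)
        times.append(t)
        if initial_n is None:
            initial_n = len(instances)

    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    curve = chip_survival(alive_counts, times, max(initial_n or 1, 1))
    survival_df = curve.to_frame()
    survival_df.insert(0, "chamber_id", chamber)
    return measurements, label_masks, area_model, survival_df


def run_pipeline(cfg: RunConfig, frames: list[Frame] | None = None) -> dict:
    """Run every stage and write results to ``cfg.out_dir``.

    Returns the run manifest.  Raises :class:`PipelineError` with a
    stage-scoped message on failure; outputs of completed chambers are kept.
    """
    if frames is None:
        frames = load_series(cfg.input_dir, cfg.pattern)
    if not frames:
        raise PipelineError(f"no input frames found in {cfg.input_dir}")
    chambers: dict[str, list[Frame]] = {}
    for f in frames:
        chambers.setdefault(f.chamber_id, []).append(f)

    tables: dict[str, pd.DataFrame] = {}
    masks: dict[str, np.ndarray] = {}
    all_measurements, all_survival = [], []
    for chamber in sorted(chambers):
        log.info("analyzing chamber %s (%d frames)", chamber, len(chambers[chamber]))
        try:
            meas, lab, _, surv = analyze_chamber(chambers[chamber], cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage scope
            raise PipelineError(f"analysis failed for chamber {chamber}: {exc}") from exc
        all_measurements.append(meas)
        all_survival.append(surv)
        masks.update(lab)
    tables["measurements"] = pd.concat(all_measurements, ignore_index=True)
    tables["survival"] = pd.concat(all_survival, ignore_index=True)
    return write_results(tables, masks, cfg.out_dir, config=cfg.to_dict(), seed=cfg.seed)
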