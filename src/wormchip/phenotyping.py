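"""Per-worm viability classification and quantitative phenotypes.

A worm is scored dead when its opacity (mean darkness of its pixels in the
bright-field image) falls to or below a threshold.  The default threshold is
adaptive: the mean darkness of a ring-shaped neighborhood around the worm
(excluding all worm pixels) plus the standard deviation of the darkness of
the whole image.  Because a cadaver's contrast collapses within hours, the
classification is insensitive to the precise threshold; a fixed-scalar mode
is available behind a config switch.

Motility follows the frame-pair definition: the fraction of pixels covered by
a worm in the later of two ~1-second-spaced images that were not worm pixels
in the earlier image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import ks_2samp

from .separation import WormInstance


@dataclass
class ViabilityCall:
    viability: str  # "alive" | "dead"
    opacity: float
    threshold: float
    neighborhood_fallback: bool = False  # ring fully occupied by other worms


def classify_viability(
    instance: WormInstance | np.ndarray,
    darkness: np.ndarray,
    worm_mask: np.ndarray,
    mode: str = "adaptive",
    fixed_threshold: float = 0.30,
    neighborhood_width_px: int = 10,
    threshold_offset: float = 0.0,
) -> ViabilityCall:
    """Classify one worm as alive or dead from its bright-field opacity.

    ``worm_mask`` marks every worm pixel in the frame (used to exclude worms
    from the neighborhood ring).  Boundary convention: ``opacity <= threshold``
    means dead, so the dead set is closed and ties are deterministic.
    """
    inst_mask = instance.mask(darkness.shape) if isinstance(instance, WormInstance) \
        else np.asarray(instance, dtype=bool)
    opacity = float(darkness[inst_mask].mean())
    fallback = False
    if mode == "adaptive":
        ring = ndimage.binary_dilation(
            inst_mask, np.ones((3, 3), bool), iterations=neighborhood_width_px
        ) & ~worm_mask
        if ring.any():
            neighborhood_mean = float(darkness[ring].mean())
        else:
            bg = ~worm_mask
            neighborhood_mean = float(darkness[bg].mean()) if bg.any() else 0.0
            fallback = True
        threshold = neighborhood_mean + float(darkness.std())
    elif mode == "fixed":
        threshold = fixed_threshold
    else:
        raise ValueError(f"unknown viability mode {mode!r}")
    threshold += threshold_offset
    viability = "alive" if opacity > threshold else "dead"
    return ViabilityCall(viability, opacity, threshold, fallback)


def estimate_time_of_death(times_h, statuses) -> float:
    """First time from which the worm is dead at every later observation.

    ``statuses`` holds "alive"/"dead" (or booleans, True = alive) aligned with
    ``times_h``.  Returns ``math.inf`` if the worm is alive at the end.  A
    dead observation followed by alive (segmentation flicker) is treated as an
    anomaly: the time of the *last* alive-to-dead transition is used.
    """
    times = list(times_h)
    alive = [s if isinstance(s, (bool, np.bool_)) else s == "alive" for s in statuses]
    if len(times) != len(alive):
        raise ValueError("times and statuses must have equal length")
    if not times:
        return math.inf
    order = np.argsort(times, kind="stable")
    times = [times[i] for i in order]
    alive = [alive[i] for i in order]
    if alive[-1]:
        return math.inf
    # walk back to the start of the terminal dead run
    k = len(alive) - 1
    while k > 0 and not alive[k - 1]:
        k -= 1
    return float(times[k])


def measure_fluorescence(
    instance: WormInstance | np.ndarray,
    fluorescence: np.ndarray,
    worm_mask: np.ndarray | None = None,
    background_mode: str = "median_nonworm",
) -> float:
    """Total background-subtracted fluorescence over the worm's pixels.

    Background is the median of non-worm pixels (or zero); per-pixel values
    are clamped at zero before summing, so a dark worm on a dark background
    reports 0.
    """
    inst_mask = instance.mask(fluorescence.shape) if isinstance(instance, WormInstance) \
        else np.asarray(instance, dtype=bool)
    if background_mode == "median_nonworm":
        bg_mask = ~worm_mask if worm_mask is not None else ~inst_mask
        background = float(np.median(fluorescence[bg_mask])) if bg_mask.any() else 0.0
    elif background_mode == "none":
        background = 0.0
    else:
        raise ValueError(f"unknown background mode {background_mode!r}")
    values = fluorescence[inst_mask] - background
    return float(np.clip(values, 0, None).sum())


def measure_motility(
    instance: WormInstance | np.ndarray,
    earlier_mask: np.ndarray,
) -> float:
    """Fraction of the worm's pixels (later frame) not covered in the earlier frame."""
    inst_mask = instance.mask(earlier_mask.shape) if isinstance(instance, WormInstance) \
        else np.asarray(instance, dtype=bool)
    n = int(inst_mask.sum())
    if n == 0:
        raise ValueError("instance has no pixels")
    new = int((inst_mask & ~np.asarray(earlier_mask, dtype=bool)).sum())
    return new / n


@dataclass
class PopulationSummary:
    quantity: str
    time_h: float
    values: np.ndarray  # sorted sample (the empirical CDF support)
    mean: float
    sd: float
    low_n: bool


def population_summaries(
    table: pd.DataFrame,
    quantities: tuple[str, ...] = ("fluorescence_total", "opacity", "motility"),
    groupby: str = "time_h",
    min_n: int = 3,
) -> tuple[list[PopulationSummary], pd.DataFrame]:
    """Per-time empirical CDFs, means/SDs, and pairwise two-sample KS tests.

    Returns ``(summaries, ks_table)`` where ``ks_table`` has one row per
    (quantity, time_a, time_b) pair with the KS statistic and p-value.
    """
    if table.empty:
        raise ValueError("measurement table is empty")
    summaries: list[PopulationSummary] = []
    ks_rows = []
    for q in quantities:
        groups = []
        for t, sub in table.groupby(groupby, sort=True):
            vals = sub[q].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            vals = np.sort(vals)
            summaries.append(
                PopulationSummary(q, float(t), vals, float(vals.mean()),
                                  float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                                  low_n=len(vals) < min_n)
            )
            groups.append((float(t), vals))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ta, va = groups[i]
                tb, vb = groups[j]
                if len(va) and len(vb):
                    res = ks_2samp(va, vb, method="asymp")
                    ks_rows.append(
                        {"quantity": q, "time_a": ta, "time_b": tb,
                         "ks_stat": float(res.statistic), "p_value": float(res.pvalue)}
                    )
    return summaries, pd.DataFrame(ks_rows)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF evaluated at the sorted sample points."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y
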