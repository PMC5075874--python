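"""Worm masking, connected components, and the single-worm area model.

Worms are much darker than the background in bright-field (and brighter in
fluorescence), so masking is a thresholding problem.  The default method
estimates a local background with a large-window low-percentile rank filter —
wide enough (~10x a worm width) and low enough in rank that even a dense worm
cluster cannot drag it up — and keeps pixels whose darkness exceeds the
background by ``k_sigma`` robust standard deviations.

Each connected component of the mask is one worm or several touching worms.
Because single-worm components dominate a 30-35 worm chamber, the single-worm
area is estimated as the dominant mode of the component-area distribution and
then used to count worms per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import rank
from skimage.util import img_as_ubyte

from ._contour import trace_boundary
from .io import Frame


@dataclass
class WormMask:
    """Binary worm-pixel mask aligned to a source frame."""

    mask: np.ndarray
    threshold: float  # contrast threshold actually applied
    method: str

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class WormComponent:
    """A connected set of worm pixels: one worm or several touching worms."""

    component_id: int
    slices: tuple[slice, slice]  # bounding box in the source frame
    mask: np.ndarray  # local boolean mask within the bounding box
    area_px: int
    boundary: np.ndarray  # (n, 2) ordered closed pixel path, global coords
    mean_darkness: float = float("nan")
    estimated_worm_count: int | None = None
    low_confidence: bool = False

    @property
    def offset(self) -> tuple[int, int]:
        return (self.slices[0].start, self.slices[1].start)

    def global_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices] = self.mask
        return out

    def pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = np.nonzero(self.mask)
        return r + self.slices[0].start, c + self.slices[1].start


@dataclass
class AreaModel:
    """Single-worm size calibration estimated from component areas."""

    single_worm_area_px: float
    single_worm_length_px: float | None = None
    min_object_area_px: float = 0.0
    single_worm_half_width_px: float | None = None  # median medial EDT of singles

    def __post_init__(self) -> None:
        if self.single_worm_area_px <= 0:
            raise ValueError("single_worm_area_px must be positive")
        if self.min_object_area_px >= self.single_worm_area_px:
            raise ValueError("min_object_area_px must be below single_worm_area_px")


# --------------------------------------------------------------------------
# Masking
# --------------------------------------------------------------------------

def _local_background(signal: np.ndarray, window_px: int) -> np.ndarray:
    # low-percentile rank filter on uint8: fast, and robust even where worm
    # clusters cover most of the window (a median would track the worms)
    u8 = img_as_ubyte(np.clip(signal, 0, 1))
    bg = rank.percentile(
        u8, footprint=np.ones((window_px, window_px), dtype=bool), p0=0.25
    )
    return bg.astype(float) / 255.0


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def mask_worms(
    frame: Frame,
    method: str = "local_median",
    k_sigma: float = 3.0,
    bg_window_px: int = 101,
    min_contrast: float = 0.04,
    min_object_area_px: float | None = None,
    min_object_area_frac: float = 0.2,
    fill_holes: bool = True,
) -> WormMask:
    """Mask worm pixels in a frame.

    Bright-field frames are thresholded on darkness, fluorescence frames on
    brightness.  ``min_object_area_px=None`` bootstraps the debris cutoff as
    ``min_object_area_frac`` x the median provisional component area.
    """
    signal = frame.darkness if frame.channel == "brightfield" else frame.pixels
    if method == "local_median":
        bg = _local_background(signal, bg_window_px)
        residual = signal - bg
        thr = max(k_sigma * _robust_sd(residual), min_contrast)
        mask = residual > thr
    elif method == "global_otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(signal))
        mask = signal > thr
    else:
        raise ValueError(f"unknown masking method {method!r}")

    mask = _filter_small(mask, 16.0)  # unconditional speck floor (noise pixels)
    if min_object_area_px is None:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n:
            areas = np.bincount(labels.ravel())[1:]
            areas = np.sort(areas[areas > 0])
            # mass-weighted median: the component area at half the foreground
            # pixel mass — debris blobs are numerous but carry little mass
            cum = np.cumsum(areas)
            typical = float(areas[np.searchsorted(cum, 0.5 * cum[-1])])
            min_object_area_px = min_object_area_frac * typical
        else:
            min_object_area_px = 0.0
    mask = _filter_small(mask, float(min_object_area_px))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return WormMask(mask=mask, threshold=float(thr), method=method)


def _filter_small(mask: np.ndarray, min_area: float) -> np.ndarray:
    if min_area <= 1:
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


# --------------------------------------------------------------------------
# Components
# --------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=bool)


def extract_components(
    mask: WormMask | np.ndarray,
    darkness: np.ndarray | None = None,
) -> list[WormComponent]:
    """8-connected components of a worm mask, with ordered boundary contours.

    ``darkness`` (the source bright-field darkness image) fills in each
    component's mean darkness when provided.
    """
    arr = mask.mask if isinstance(mask, WormMask) else np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(arr, structure=_EIGHT)
    components: list[WormComponent] = []
    for cid, slc in enumerate(ndimage.find_objects(labels), start=1):
        local = labels[slc] == cid
        offset = np.array([slc[0].start, slc[1].start])
        boundary = trace_boundary(local) + offset
        mean_dark = float("nan")
        if darkness is not None:
            mean_dark = float(darkness[slc][local].mean())
        components.append(
            WormComponent(
                component_id=cid,
                slices=slc,
                mask=local,
                area_px=int(local.sum()),
                boundary=boundary,
                mean_darkness=mean_dark,
            )
        )
    return components


# --------------------------------------------------------------------------
# Area model
# --------------------------------------------------------------------------

def skeleton_length(mask: np.ndarray) -> float:
    """Arclength of the morphological skeleton (axial steps 1, diagonal sqrt 2)."""
    skel = morphology.skeletonize(mask)
    if not skel.any():
        return 0.0
    r, c = np.nonzero(skel)
    pts = set(zip(r.tolist(), c.tolist()))
    axial = diag = 0
    for (i, j) in pts:
        if (i, j + 1) in pts:
            axial += 1
        if (i + 1, j) in pts:
            axial += 1
        if (i + 1, j + 1) in pts:
            diag += 1
        if (i + 1, j - 1) in pts:
            diag += 1
    return axial + math.sqrt(2) * diag


def fit_area_model(
    components,
    min_components: int = 5,
    min_object_area_frac: float = 0.2,
) -> AreaModel:
    """Estimate the single-worm area (and length) from component statistics.

    ``components`` is either a sequence of :class:`WormComponent` or a plain
    array of component areas.  Because single-worm components are the most
    abundant, the single-worm area is a robust center of the dominant
    (low-area) mode: the median of areas below 1.6x the overall median, which
    excludes multi-worm components without being dragged by their tail.  The
    single-worm length is the mean skeleton length of components whose area
    is within +-30% of the estimate (requires WormComponent inputs).
    """
    comp_list = list(components)
    if comp_list and isinstance(comp_list[0], WormComponent):
        areas = np.array([c.area_px for c in comp_list], dtype=float)
    else:
        areas = np.asarray(comp_list, dtype=float)
        comp_list = []
    if len(areas) < min_components:
        raise ValueError(
            f"need at least {min_components} components to fit the area model "
            f"(got {len(areas)}); analyze more frames"
        )
    med = float(np.median(areas))
    cand = areas[areas < 1.6 * med]
    estimate = float(np.median(cand)) if len(cand) else med

    length = None
    half_width = None
    if comp_list:
        singles = [
            c for c in comp_list if abs(c.area_px - estimate) <= 0.3 * estimate
        ]
        if singles:
            length = float(np.mean([skeleton_length(c.mask) for c in singles]))
            half_width = float(np.median(np.concatenate(
                [_medial_half_widths(c.mask) for c in singles]
            )))
    return AreaModel(
        single_worm_area_px=estimate,
        single_worm_length_px=length,
        min_object_area_px=min_object_area_frac * estimate,
        single_worm_half_width_px=half_width,
    )


def _medial_half_widths(mask: np.ndarray) -> np.ndarray:
    """Distance-transform values along the skeleton (local half-widths)."""
    skel = morphology.skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)
    vals = edt[skel]
    return vals if len(vals) else np.array([0.5])


def count_worms(component: WormComponent | float, area_model: AreaModel) -> int:
    """Estimated number of worms in a component: round(area / single-worm area),
    clamped to >= 1 (sub-threshold debris that survived filtering counts as one
    low-confidence worm)."""
    area = component.area_px if isinstance(component, WormComponent) else float(component)
    n = max(1, int(math.floor(area / area_model.single_worm_area_px + 0.5)))
    if isinstance(component, WormComponent):
        component.estimated_worm_count = n
        component.low_confidence = area < area_model.min_object_area_px
    return n


def annotate_components(components, area_model: AreaModel) -> None:
    for c in components:
        count_worms(c, area_model)
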