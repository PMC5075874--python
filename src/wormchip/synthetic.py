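"""Ground-truthed synthetic chamber scenes.

Emulates the statistical and geometric structure of bright-field / fluorescence
time-lapse images of *C. elegans* confined in a micro-pillar chamber: dark
elongated worms on a light background, clusters of side- and end-touching
worms (worms never overlap — the shallow chamber forbids crossing), rapid
post-mortem opacity decay, and per-worm fluorescent reporter signal.

Darkness is defined as ``1 - normalized intensity`` throughout, so "darker"
always means a larger value.  Coordinates are row-major and 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import Frame


class PlacementError(RuntimeError):
    """Raised when a cluster cannot be placed without overlap."""


# --------------------------------------------------------------------------
# Spec dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PillarSpec:
    """Hexagonal micro-pillar lattice rendered as slightly dark disks."""

    pitch_px: float = 55.0
    radius_px: float = 6.0
    darkness: float = 0.11


@dataclass(frozen=True)
class ClusterSpec:
    """A group of worms placed in mutual contact.

    ``contact_type`` is one of ``none``, ``side_touch``, ``end_touch``,
    ``mixed`` (per-worm random choice of side/end).
    """

    worm_indices: tuple[int, ...]
    contact_type: str = "side_touch"

    def __post_init__(self) -> None:
        if self.contact_type not in ("none", "side_touch", "end_touch", "mixed"):
            raise ValueError(f"unknown contact type {self.contact_type!r}")


@dataclass(frozen=True)
class DeadDarknessCurve:
    """Cadaver darkness as a function of hours since death.

    Exponential decay of the alive-vs-background contrast with a configurable
    half-life.  The default 1 h half-life leaves ~6% of the contrast after
    4 h, i.e. a cadaver is nearly indistinguishable from background within
    about 4 hours.
    """

    half_life_h: float = 1.0

    def __call__(self, hours_since_death: float, alive_darkness: float,
                 background_level: float) -> float:
        if hours_since_death <= 0:
            return alive_darkness
        decay = 0.5 ** (hours_since_death / self.half_life_h)
        return background_level + (alive_darkness - background_level) * decay


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic chamber scene."""

    image_height_px: int = 384
    image_width_px: int = 384
    n_worms: int = 8
    worm_length_px: tuple[float, float] = (100.0, 15.0)  # mean, sd
    worm_width_px: tuple[float, float] = (10.0, 2.0)
    cluster_plan: tuple[ClusterSpec, ...] = ()
    alive_darkness: float = 0.65
    alive_darkness_sd: float = 0.04
    dead_darkness_curve: DeadDarknessCurve = DeadDarknessCurve()
    background_level: float = 0.08
    pillar_spec: PillarSpec | None = PillarSpec()
    noise_sd: float = 0.02
    fluor_per_worm: tuple[float, ...] | None = None
    fluor_background: float = 0.02
    n_debris: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.worm_width_px[0] >= self.worm_length_px[0] / 5:
            raise ValueError("worms must be elongated: mean width < mean length / 5")
        if self.alive_darkness <= self.background_level:
            raise ValueError("alive_darkness must exceed background_level")
        for cl in self.cluster_plan:
            for i in cl.worm_indices:
                if not (0 <= i < self.n_worms):
                    raise ValueError(f"cluster worm index {i} out of range")


@dataclass
class WormTruth:
    worm_id: int  # 1-based, matches label image
    midline: np.ndarray  # (n, 2) float, global (row, col)
    length_px: float
    area_px: int
    alive: bool
    fluorescence_total: float
    cluster_id: int | None


@dataclass
class GroundTruth:
    label_image: np.ndarray  # int, 0 = background, k = worm k
    worms: list[WormTruth]

    def mask_of(self, worm_id: int) -> np.ndarray:
        return self.label_image == worm_id

    @property
    def worm_mask(self) -> np.ndarray:
        return self.label_image > 0


# --------------------------------------------------------------------------
# Single-worm geometry
# --------------------------------------------------------------------------

def _midline_points(length_px: float, curvature_amplitude: float,
                    frequency: float, phase: float, base_angle: float) -> np.ndarray:
    """Integrate a damped-sinusoid heading into a unit-step midline polyline."""
    n = max(int(round(length_px)), 5)
    s = np.arange(n, dtype=float)
    damp = 1.0 - 0.4 * s / n  # amplitude decays toward the tail
    theta = base_angle + curvature_amplitude * damp * np.sin(
        2 * math.pi * frequency * s / n + phase
    )
    rows = np.concatenate([[0.0], np.cumsum(np.sin(theta[:-1]))])
    cols = np.concatenate([[0.0], np.cumsum(np.cos(theta[:-1]))])
    return np.column_stack([rows, cols])


def _radius_profile(s: np.ndarray, length: float, width: float) -> np.ndarray:
    """Half-width along the body: constant mid-section, elliptic taper at ends."""
    taper = max(width, 0.12 * length)
    r = np.full_like(s, width / 2.0)
    head = s < taper
    tail = s > length - taper
    r[head] = (width / 2.0) * np.sqrt(np.clip(1 - ((taper - s[head]) / taper) ** 2, 0, 1))
    r[tail] = (width / 2.0) * np.sqrt(
        np.clip(1 - ((s[tail] - (length - taper)) / taper) ** 2, 0, 1)
    )
    return np.maximum(r, 0.8)  # keep tips at least ~1.6 px wide so the body stays connected


def expected_shape_area(length_px: float, width_px: float) -> float:
    """Closed-form area of the swept tube (rectangle + elliptic caps)."""
    taper = max(width_px, 0.12 * length_px)
    return width_px * (length_px - 2 * taper * (1 - math.pi / 4))


def _self_intersects(midline: np.ndarray, width: float) -> bool:
    step = max(2, int(width // 2))
    pts = midline[::step]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    n = len(pts)
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    far_in_arclength = idx * step > 2.5 * width
    return bool(np.any(d2[far_in_arclength] < (0.9 * width) ** 2))


def generate_worm_shape(
    length_px: float,
    width_px: float,
    curvature_amplitude: float,
    seed: int | np.random.Generator = 0,
    base_angle: float | None = None,
    max_attempts: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one worm body as a local boolean mask plus its midline.

    The body is swept from a smooth damped-sinusoid midline with tapered ends.
    Returns ``(mask, midline)`` where ``midline`` is in the mask's local
    coordinates.  Raises :class:`PlacementError` if every attempt produces a
    self-intersecting body.
    """
    if length_px < 5 * width_px:
        raise ValueError("length_px must be at least 5 x width_px")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        phase = rng.uniform(0, 2 * math.pi)
        freq = rng.uniform(0.8, 1.5)
        angle = rng.uniform(0, 2 * math.pi) if base_angle is None else base_angle
        midline = _midline_points(length_px, curvature_amplitude, freq, phase, angle)
        if curvature_amplitude > 0 and _self_intersects(midline, width_px):
            continue
        mask, local_midline = _render_tube(midline, length_px, width_px)
        return mask, local_midline
    raise PlacementError(
        f"could not draw a non-self-intersecting worm (length={length_px}, "
        f"amplitude={curvature_amplitude})"
    )


def _render_tube(midline: np.ndarray, length: float, width: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    margin = int(math.ceil(width)) + 2
    lo = midline.min(axis=0) - margin
    shifted = midline - lo
    shape = tuple(int(math.ceil(v)) + margin for v in shifted.max(axis=0))
    mask = np.zeros(shape, dtype=bool)
    s = np.arange(len(shifted), dtype=float)
    radii = _radius_profile(s, length, width)
    for (r, c), rad in zip(shifted, radii):
        r0, r1 = int(math.floor(r - rad)), int(math.ceil(r + rad)) + 1
        c0, c1 = int(math.floor(c - rad)), int(math.ceil(c + rad)) + 1
        rr, cc = np.mgrid[r0:r1, c0:c1]
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        mask[r0:r1, c0:c1] |= disk
    return mask, shifted


# --------------------------------------------------------------------------
# Scene placement
# --------------------------------------------------------------------------

@dataclass
class _Placed:
    rows: np.ndarray  # global pixel rows
    cols: np.ndarray
    midline: np.ndarray  # global float coords
    cluster_id: int | None


def _mask_to_indices(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(mask)
    return rows, cols


_DIL = ndimage.generate_binary_structure(2, 2)


def _place_cluster_member(
    shape_rows, shape_cols, midline, H, W, offset, occupancy, adjacency_target
) -> bool:
    """Check a candidate placement: inside bounds, overlap-free, and (if an
    adjacency target is given) 8-adjacent to it."""
    r = shape_rows + offset[0]
    c = shape_cols + offset[1]
    if r.min() < 1 or c.min() < 1 or r.max() >= H - 1 or c.max() >= W - 1:
        return False
    if occupancy[r, c].any():
        return False
    if adjacency_target is not None and not adjacency_target[r, c].any():
        return False
    return True


class _ScenePlacer:
    """Places all worms of a scene without overlap, honoring the cluster plan."""

    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.H = spec.image_height_px
        self.W = spec.image_width_px
        self.occupancy = np.zeros((self.H, self.W), dtype=bool)
        # spacing mask keeps non-cluster worms >= 2 px apart (8-disconnected)
        self.spaced = np.zeros((self.H, self.W), dtype=bool)
        self.placed: dict[int, _Placed] = {}

    def _draw_shape(self, base_angle=None):
        L = max(30.0, self.rng.normal(*self.spec.worm_length_px))
        w = float(np.clip(self.rng.normal(*self.spec.worm_width_px), 4.0, 0.999 * L / 5.0))
        amp = self.rng.uniform(0.1, 0.5)
        mask, midline = generate_worm_shape(L, w, amp, self.rng, base_angle=base_angle)
        rows, cols = _mask_to_indices(mask)
        return rows, cols, midline, L, w

    def _commit(self, idx, rows, cols, offset, midline, cluster_id):
        r, c = rows + offset[0], cols + offset[1]
        self.occupancy[r, c] = True
        dil = np.zeros((self.H, self.W), dtype=bool)
        dil[r, c] = True
        self.spaced |= ndimage.binary_dilation(dil, _DIL, iterations=2)
        self.placed[idx] = _Placed(r, c, midline + offset, cluster_id)

    def place_isolated(self, idx: int, cluster_id=None, max_attempts: int = 120) -> None:
        for _ in range(max_attempts):
            rows, cols, midline, L, w = self._draw_shape()
            h, wd = rows.max() + 1, cols.max() + 1
            if h >= self.H - 2 or wd >= self.W - 2:
                continue
            offset = (
                self.rng.integers(1, self.H - h - 1),
                self.rng.integers(1, self.W - wd - 1),
            )
            r, c = rows + offset[0], cols + offset[1]
            if self.spaced[r, c].any():
                continue
            self._commit(idx, rows, cols, offset, midline, cluster_id)
            return
        raise PlacementError(f"could not place isolated worm {idx}")

    def place_touching(self, idx: int, anchor_idx: int, contact: str,
                       cluster_id: int, max_attempts: int = 80) -> None:
        """Place worm ``idx`` in side or end contact with an already-placed anchor."""
        anchor = self.placed[anchor_idx]
        anchor_mask = np.zeros((self.H, self.W), dtype=bool)
        anchor_mask[anchor.rows, anchor.cols] = True
        anchor_adj = ndimage.binary_dilation(anchor_mask, _DIL)
        # other worms (not in this cluster) must stay 2 px away
        cluster_members = {
            i for i, p in self.placed.items() if p.cluster_id == cluster_id
        }
        outside = np.zeros((self.H, self.W), dtype=bool)
        for i, p in self.placed.items():
            if i not in cluster_members:
                outside[p.rows, p.cols] = True
        outside_spaced = ndimage.binary_dilation(outside, _DIL, iterations=2)

        m = anchor.midline
        tangents = np.gradient(m, axis=0)
        for _ in range(max_attempts):
            if contact == "side_touch":
                j = self.rng.integers(int(0.25 * len(m)), int(0.75 * len(m)))
                t = tangents[j] / (np.linalg.norm(tangents[j]) + 1e-9)
                normal = np.array([-t[1], t[0]])
                if self.rng.random() < 0.5:
                    normal = -normal
                angle = math.atan2(t[0], t[1]) + self.rng.uniform(-0.5, 0.5)
                if self.rng.random() < 0.5:
                    angle += math.pi
                start = m[j] + normal * 40.0
                approach = -normal
                anchor_point, attach_frac = start, 0.5
            else:  # end_touch
                head = self.rng.random() < 0.5
                j = -1 if head else 0
                t = tangents[j] / (np.linalg.norm(tangents[j]) + 1e-9)
                if not head:
                    t = -t
                angle = math.atan2(t[0], t[1]) + self.rng.uniform(-0.6, 0.6)
                start = m[j] + t * 40.0
                approach = -t
                anchor_point, attach_frac = start, 0.0

            rows, cols, midline, L, w = self._draw_shape(base_angle=angle)
            # position the new worm so its attach point starts at `start`
            attach = midline[int(attach_frac * (len(midline) - 1))]
            base = np.round(anchor_point - attach).astype(int)
            placed_ok = False
            for step in range(90):
                offset = base + np.round(step * approach).astype(int)
                r = rows + offset[0]
                c = cols + offset[1]
                if r.min() < 1 or c.min() < 1 or r.max() >= self.H - 1 or c.max() >= self.W - 1:
                    continue
                if self.occupancy[r, c].any() or outside_spaced[r, c].any():
                    break  # stepped into a body: this approach line failed
                if anchor_adj[r, c].any():
                    self._commit(idx, rows, cols, tuple(offset), midline, cluster_id)
                    placed_ok = True
                    break
            if placed_ok:
                return
        raise PlacementError(
            f"could not place worm {idx} in {contact} contact with worm {anchor_idx} "
            f"(cluster {cluster_id})"
        )


def _place_all(spec: SceneSpec, rng: np.random.Generator) -> dict[int, _Placed]:
    placer = _ScenePlacer(spec, rng)
    clustered: dict[int, tuple[int, str]] = {}
    for cid, cl in enumerate(spec.cluster_plan):
        if cl.contact_type == "none":
            continue
        for k, widx in enumerate(cl.worm_indices):
            contact = cl.contact_type
            if contact == "mixed":
                contact = "side_touch" if (k % 2 == 1) ^ (rng.random() < 0.3) else "end_touch"
            clustered[widx] = (cid, contact)
        members = list(cl.worm_indices)
        placer.place_isolated(members[0], cluster_id=cid)
        for widx in members[1:]:
            anchor = int(rng.choice([m for m in members if m in placer.placed]))
            _, contact = clustered[widx]
            placer.place_touching(widx, anchor, contact, cid)
    for idx in range(spec.n_worms):
        if idx not in placer.placed:
            placer.place_isolated(idx)
    return placer.placed


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _pillar_mask(spec: SceneSpec) -> np.ndarray:
    p = spec.pillar_spec
    mask = np.zeros((spec.image_height_px, spec.image_width_px), dtype=bool)
    if p is None:
        return mask
    dy = p.pitch_px * math.sqrt(3) / 2
    rr, cc = np.mgrid[0: spec.image_height_px, 0: spec.image_width_px]
    row_idx = 0
    y = p.pitch_px / 2
    while y < spec.image_height_px:
        x0 = p.pitch_px / 2 + (p.pitch_px / 2 if row_idx % 2 else 0)
        x = x0
        while x < spec.image_width_px:
            mask |= (rr - y) ** 2 + (cc - x) ** 2 <= p.radius_px**2
            x += p.pitch_px
        y += dy
        row_idx += 1
    return mask


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def render_scene(
    spec: SceneSpec,
    hours_since_death: Sequence[float | None] | None = None,
    time_h: float = 0.0,
    pair_index: int = 0,
    chamber_id: str = "sim0",
    _placed: dict[int, _Placed] | None = None,
    _rng: np.random.Generator | None = None,
) -> tuple[Frame, Frame, GroundTruth]:
    """Render one scene: (brightfield Frame, fluorescence Frame, GroundTruth).

    ``hours_since_death[i]`` is ``None`` for a live worm, otherwise the time
    since worm *i* died (its darkness follows the dead-darkness curve).
    """
    rng = _rng if _rng is not None else np.random.default_rng(spec.seed)
    placed = _placed if _placed is not None else _place_all(spec, rng)
    H, W = spec.image_height_px, spec.image_width_px

    darkness = np.full((H, W), spec.background_level)
    darkness[_pillar_mask(spec)] = spec.pillar_spec.darkness if spec.pillar_spec else 0.0

    label = np.zeros((H, W), dtype=np.int32)
    worms: list[WormTruth] = []
    fluors = spec.fluor_per_worm or tuple(0.0 for _ in range(spec.n_worms))
    # per-worm darkness drawn once per scene from the rng stream (fixed order)
    alive_dark = spec.alive_darkness + spec.alive_darkness_sd * rng.standard_normal(spec.n_worms)
    alive_dark = np.clip(alive_dark, spec.background_level + 0.2, 0.95)

    for idx in range(spec.n_worms):
        p = placed[idx]
        hsd = None if hours_since_death is None else hours_since_death[idx]
        if hsd is None:
            dark = alive_dark[idx]
            alive = True
        else:
            dark = spec.dead_darkness_curve(hsd, alive_dark[idx], spec.background_level)
            alive = False
        darkness[p.rows, p.cols] = dark
        label[p.rows, p.cols] = idx + 1
        worms.append(
            WormTruth(
                worm_id=idx + 1,
                midline=p.midline,
                length_px=_polyline_length(p.midline),
                area_px=len(p.rows),
                alive=alive,
                fluorescence_total=float(fluors[idx]),
                cluster_id=p.cluster_id,
            )
        )

    # debris blobs (progeny/eggs): small ellipses, never part of the ground truth
    for _ in range(spec.n_debris):
        a = rng.uniform(4, 8)
        b = rng.uniform(3, 5)
        for _attempt in range(40):
            cy = rng.uniform(10, H - 10)
            cx = rng.uniform(10, W - 10)
            rr, cc = np.mgrid[int(cy - a): int(cy + a) + 1, int(cx - a): int(cx + a) + 1]
            blob = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1
            rr, cc = rr[blob], cc[blob]
            inside = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            rr, cc = rr[inside], cc[inside]
            if len(rr) and not (label[rr, cc] > 0).any():
                darkness[rr, cc] = spec.alive_darkness
                break

    bf_intensity = 1.0 - darkness
    if spec.noise_sd > 0:
        bf_intensity = bf_intensity + rng.normal(0, spec.noise_sd, size=(H, W))
    bf = Frame(np.clip(bf_intensity, 0, 1), "brightfield", chamber_id, time_h, pair_index)

    fl_intensity = np.full((H, W), spec.fluor_background)
    for idx in range(spec.n_worms):
        p = placed[idx]
        if fluors[idx] > 0:
            fl_intensity[p.rows, p.cols] += fluors[idx] / len(p.rows)
    if spec.noise_sd > 0:
        fl_intensity = fl_intensity + rng.normal(0, spec.noise_sd / 2, size=(H, W))
    fl = Frame(np.clip(fl_intensity, 0, 1), "fluorescence", chamber_id, time_h, pair_index)

    return bf, fl, GroundTruth(label, worms)


# --------------------------------------------------------------------------
# Time-lapse assay
# --------------------------------------------------------------------------

@dataclass
class AssayFrame:
    """One imaging time point: a ~1 s bright-field pair plus fluorescence."""

    time_h: float
    brightfield: tuple[Frame, Frame]
    fluorescence: Frame
    truth: tuple[GroundTruth, GroundTruth]  # per pair member


def generate_assay_timelapse(
    spec: SceneSpec,
    death_times: Sequence[float],
    frame_interval_h: float = 1.0,
    n_frames: int | None = None,
    pair_offset_s: float = 1.3,
    speeds_px: Sequence[float] | None = None,
    chamber_id: str = "sim0",
    render_pairs: bool = True,
) -> list[AssayFrame]:
    """Simulate an hourly-imaged killing assay with motility frame pairs.

    ``death_times[i]`` is the hour at which worm *i* dies (``math.inf`` for a
    worm that never dies).  Between the two members of each frame pair, live
    worms translate by their per-worm speed (pixels per pair interval); after
    death a worm stops moving and fades along the dead-darkness curve.
    """
    if frame_interval_h <= 0:
        raise ValueError("frame_interval_h must be positive")
    death_times = list(death_times)
    if len(death_times) != spec.n_worms:
        raise ValueError("death_times must have one entry per worm")
    if any(dt < 0 for dt in death_times):
        raise ValueError("death_times must be >= 0 (use math.inf for never)")
    rng = np.random.default_rng(spec.seed)
    placed = _place_all(spec, rng)
    if speeds_px is None:
        speeds_px = [float(rng.uniform(2.0, 5.0)) for _ in range(spec.n_worms)]
    if n_frames is None:
        finite = [t for t in death_times if math.isfinite(t)]
        horizon = (max(finite) + 5.0) if finite else 12.0
        n_frames = int(horizon / frame_interval_h) + 1

    H, W = spec.image_height_px, spec.image_width_px
    frames: list[AssayFrame] = []
    for k in range(n_frames):
        t = k * frame_interval_h
        hsd = [None if t <= death_times[i] else t - death_times[i]
               for i in range(spec.n_worms)]
        frame_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, k])
        )
        bf0, fl0, gt0 = render_scene(
            spec, hsd, time_h=t, pair_index=0, chamber_id=chamber_id,
            _placed=placed, _rng=frame_rng,
        )
        if render_pairs:
            shifted = _shift_alive(placed, hsd, speeds_px, frame_rng, H, W)
            bf1, _, gt1 = render_scene(
                spec, hsd, time_h=t, pair_index=1, chamber_id=chamber_id,
                _placed=shifted, _rng=frame_rng,
            )
        else:
            bf1, gt1 = bf0, gt0
        frames.append(AssayFrame(t, (bf0, bf1), fl0, (gt0, gt1)))
    return frames


def _shift_alive(placed, hours_since_death, speeds, rng, H, W):
    """Translate live worms by their per-worm speed, skipping moves that collide."""
    occupancy = np.zeros((H, W), dtype=bool)
    for p in placed.values():
        occupancy[p.rows, p.cols] = True
    out: dict[int, _Placed] = {}
    for idx, p in placed.items():
        speed = speeds[idx]
        if hours_since_death[idx] is not None or speed < 0.5:
            out[idx] = p
            continue
        angle = rng.uniform(0, 2 * math.pi)
        moved = p
        for scale in (1.0, 0.5):
            dr = int(round(speed * scale * math.sin(angle)))
            dc = int(round(speed * scale * math.cos(angle)))
            if dr == 0 and dc == 0:
                continue
            r, c = p.rows + dr, p.cols + dc
            if r.min() < 1 or c.min() < 1 or r.max() >= H - 1 or c.max() >= W - 1:
                continue
            others = occupancy.copy()
            others[p.rows, p.cols] = False
            if others[r, c].any():
                continue
            moved = _Placed(r, c, p.midline + np.array([dr, dc]), p.cluster_id)
            break
        out[idx] = moved
    return out


def write_scene(bf: Frame, fl: Frame, truth: GroundTruth, out_dir) -> None:
    """Write a rendered scene: frames as TIFF, ground truth as TIFF + JSON."""
    import json
    from pathlib import Path

    import tifffile

    from .io import write_frames

    out_dir = Path(out_dir)
    write_frames([bf, fl], out_dir)
    tifffile.imwrite(out_dir / "truth_labels.tif", truth.label_image.astype(np.uint16))
    records = [
        {
            "worm_id": w.worm_id,
            "length_px": w.length_px,
            "area_px": w.area_px,
            "alive": w.alive,
            "fluorescence_total": w.fluorescence_total,
            "cluster_id": w.cluster_id,
            "midline": np.asarray(w.midline).round(2).tolist(),
        }
        for w in truth.worms
    ]
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(records, fh)
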