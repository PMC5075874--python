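"""Splitting multi-worm components into individual worms.

The shallow chamber forbids worms from crossing on top of each other, so a
multi-worm component is a planar arrangement of touching bodies.  The
algorithm exploits two facts:

* regions whose local width matches a single worm body must belong to exactly
  one worm ("body parts"); thicker regions are worm-worm junctions;
* a worm silhouette bends smoothly, so a sharp turn of the component boundary
  marks a contact point between two worms.  Connections across a junction
  whose flanking boundary arc contains such a turn are prohibited.

Parts are assembled across junctions by a maximum-compatibility matching of
part endpoints (tangent continuity among non-prohibited pairings), producing
medial chains.  Chains longer than one worm — end-to-end contacts that turn
angles cannot resolve — are cut into individuals using the average length of
isolated worms as a ruler.  Component pixels are finally assigned to the
nearest chain in geodesic (within-mask) distance.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.draw import line as draw_line

from .segmentation import AreaModel, WormComponent, count_worms

_EIGHT = np.ones((3, 3), dtype=bool)
# fixed neighbor scan order for deterministic traversals
_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class SeparationConfig:
    width_factor: float = 1.3  # x single-worm half-width narrowness cutoff
    turn_window_px: int = 5
    sharp_turn_deg: float = 70.0
    min_part_px: int = 4
    min_continuation_score: float = 0.2
    smooth_gap_bonus: float = 1.0
    attach_radius_px: int = 2
    max_junction_endpoints: int = 10


@dataclass
class TurnAngleProfile:
    """Signed turn angle (degrees) at every boundary pixel of a closed contour."""

    angles_deg: np.ndarray
    sharp: np.ndarray  # |angle| > threshold
    window_px: int
    sharp_turn_deg: float


@dataclass
class Endpoint:
    part_id: int
    end: int  # 0 = path start, 1 = path end
    pixel: tuple[int, int]
    tangent: np.ndarray  # unit vector pointing out of the part (into the junction)
    width_px: float = 0.0  # local body width at the part end
    contour_index: int | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.part_id, self.end)


@dataclass
class BodyPart:
    """A narrow skeleton segment that belongs to exactly one worm."""

    part_id: int
    path: np.ndarray  # (n, 2) ordered medial pixels, component-local coords
    width_profile: np.ndarray  # local full width (2 x EDT) along the path
    endpoints: list[Endpoint] = field(default_factory=list)

    @property
    def length_px(self) -> float:
        return _path_arclength(self.path)


@dataclass
class Junction:
    """A thick region where several worms are in contact."""

    junction_id: int
    pixels: np.ndarray  # (n, 2) skeleton pixels of the thick/branch region
    endpoints: list[Endpoint] = field(default_factory=list)
    prohibited: set[frozenset] = field(default_factory=set)
    #: part-id pairs whose connecting boundary gap is smooth — strong evidence
    #: that the two parts are the same silhouette continuing past the junction
    smooth_pairs: set[frozenset] = field(default_factory=set)
    matched: list[tuple[tuple, tuple, float]] = field(default_factory=list)
    unresolved: bool = False

    def is_prohibited(self, a: Endpoint | tuple, b: Endpoint | tuple) -> bool:
        ka = a.key if isinstance(a, Endpoint) else a
        kb = b.key if isinstance(b, Endpoint) else b
        return frozenset((ka, kb)) in self.prohibited


@dataclass
class WormInstance:
    """One individual worm's pixel set within a frame."""

    worm_id: int
    rows: np.ndarray  # global pixel coordinates
    cols: np.ndarray
    length_px: float
    confidence: str  # isolated | resolved | chain_split | unresolved

    @property
    def area_px(self) -> int:
        return len(self.rows)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.rows, self.cols] = True
        return out


@dataclass
class SeparationResult:
    instances: list[WormInstance]
    expected_count: int
    success: bool
    unresolved_junctions: int = 0


# --------------------------------------------------------------------------
# Turn angles
# --------------------------------------------------------------------------

def compute_turn_angles(
    contour: np.ndarray,
    window_px: int = 5,
    sharp_turn_deg: float = 70.0,
) -> TurnAngleProfile:
    """Signed turn angle at each contour pixel over a smoothing window.

    The angle at pixel *i* is the signed angle between the chords
    ``(i - window) -> i`` and ``i -> (i + window)``, indices modulo the
    contour length.  Positive = clockwise in image coordinates.
    """
    contour = np.asarray(contour, dtype=float)
    n = len(contour)
    if n < 3 * window_px:
        raise ValueError(
            f"contour of length {n} is too short for window {window_px}"
        )
    prev = contour[(np.arange(n) - window_px) % n]
    nxt = contour[(np.arange(n) + window_px) % n]
    v1 = contour - prev
    v2 = nxt - contour
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.sum(v1 * v2, axis=1)
    angles = np.degrees(np.arctan2(cross, dot))
    return TurnAngleProfile(
        angles_deg=angles,
        sharp=np.abs(angles) > sharp_turn_deg,
        window_px=window_px,
        sharp_turn_deg=sharp_turn_deg,
    )


# --------------------------------------------------------------------------
# Body parts and junctions
# --------------------------------------------------------------------------

def _path_arclength(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    return float(np.sum(np.where(steps.sum(axis=1) == 2, math.sqrt(2), 1.0)))


def _trace_path(pixels: set[tuple[int, int]]) -> np.ndarray:
    """Order a thin 8-connected pixel set into a simple path (greedy walk)."""
    if not pixels:
        return np.empty((0, 2), dtype=int)
    neigh = {}
    for p in pixels:
        neigh[p] = [
            (p[0] + dr, p[1] + dc)
            for dr, dc in _NEIGHBORS
            if (p[0] + dr, p[1] + dc) in pixels
        ]
    ends = sorted(p for p, nb in neigh.items() if len(nb) <= 1)
    start = ends[0] if ends else min(pixels)
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        candidates = [q for q in neigh[cur] if q not in visited]
        if not candidates:
            break
        # prefer axial moves so the walk hugs the skeleton
        candidates.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        nxt = candidates[0]
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    return np.array(path, dtype=int)


def _end_tangent(path: np.ndarray, end: int, k: int = 5) -> np.ndarray:
    """Unit tangent at a path end, pointing outward (away from the part body)."""
    if len(path) < 2:
        return np.zeros(2)
    if end == 1:
        v = path[-1] - path[max(0, len(path) - 1 - k)]
    else:
        v = path[0] - path[min(len(path) - 1, k)]
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.zeros(2)


def single_worm_half_width(area_model: AreaModel, component: WormComponent | None = None
                           ) -> float:
    """Half-width of a single worm implied by the area model."""
    if area_model.single_worm_half_width_px:
        return area_model.single_worm_half_width_px
    if area_model.single_worm_length_px:
        return 0.5 * area_model.single_worm_area_px / area_model.single_worm_length_px
    if component is not None:  # fallback: typical medial half-width of this component
        skel = morphology.skeletonize(component.mask)
        edt = ndimage.distance_transform_edt(component.mask)
        vals = edt[skel]
        if len(vals):
            return float(np.median(vals))
    # last resort: treat the worm as a ~10:1 rod
    return 0.5 * math.sqrt(area_model.single_worm_area_px / 10.0)


def extract_body_parts(
    component: WormComponent,
    area_model: AreaModel,
    width_factor: float = 1.3,
    config: SeparationConfig | None = None,
) -> tuple[list[BodyPart], list[Junction]]:
    """Decompose a component skeleton into narrow body parts and thick junctions.

    Skeleton pixels whose medial half-width (distance transform) stays within
    ``width_factor`` x the single-worm half-width and that are not branch
    points form body parts; the remaining skeleton pixels form junctions.
    Part endpoints lying within the attach radius of a junction are attached
    to it.
    """
    cfg = config or SeparationConfig(width_factor=width_factor)
    mask = component.mask
    skel = morphology.skeletonize(mask)
    if not skel.any():  # degenerate: thinner than 2 px everywhere
        r, c = np.nonzero(mask)
        path = np.column_stack([r, c])
        return [BodyPart(0, path, np.ones(len(path)))], []
    edt = ndimage.distance_transform_edt(mask)
    half = single_worm_half_width(area_model, component)
    narrow = skel & (edt <= cfg.width_factor * half)
    nbr_count = ndimage.convolve(skel.astype(np.int8), _EIGHT.astype(np.int8),
                                 mode="constant") - skel
    branch = skel & (nbr_count >= 3)
    part_mask = narrow & ~branch

    part_labels, n_parts = ndimage.label(part_mask, structure=_EIGHT)
    parts: list[BodyPart] = []
    junction_extra = np.zeros_like(part_mask)
    pid = 0
    for lab in range(1, n_parts + 1):
        px = part_labels == lab
        if int(px.sum()) < cfg.min_part_px:
            junction_extra |= px  # tiny fragments belong to the junction zone
            continue
        path = _trace_path(set(zip(*map(lambda a: a.tolist(), np.nonzero(px)))))
        widths = 2.0 * edt[path[:, 0], path[:, 1]]
        part = BodyPart(pid, path, widths)
        for end in (0, 1):
            pix = tuple(path[-1] if end else path[0])
            k = min(3, len(widths))
            w_end = float(np.mean(widths[-k:] if end else widths[:k]))
            part.endpoints.append(
                Endpoint(pid, end, pix, _end_tangent(path, end), width_px=w_end)
            )
        parts.append(part)
        pid += 1

    junction_px = (skel & ~part_mask) | junction_extra
    # dilate for labeling only, so junction fragments within 2 px merge
    jl_src = ndimage.binary_dilation(junction_px, _EIGHT)
    jlabels, n_j = ndimage.label(jl_src, structure=_EIGHT)
    jlabels[~junction_px] = 0

    junctions: dict[int, Junction] = {}
    rad = cfg.attach_radius_px
    H, W = mask.shape
    for part in parts:
        for ep in part.endpoints:
            r, c = ep.pixel
            patch = jlabels[max(0, r - rad): r + rad + 1, max(0, c - rad): c + rad + 1]
            labs = np.unique(patch[patch > 0])
            if len(labs) == 0:
                continue
            if len(labs) > 1:  # pick the nearest junction label
                best, bestd = None, None
                rr, cc = np.nonzero(patch)
                for i in range(len(rr)):
                    lab = patch[rr[i], cc[i]]
                    d = max(abs(rr[i] - min(r, rad)), abs(cc[i] - min(c, rad)))
                    if bestd is None or d < bestd:
                        best, bestd = lab, d
                labs = [best]
            lab = int(labs[0])
            if lab not in junctions:
                jr, jc = np.nonzero(jlabels == lab)
                junctions[lab] = Junction(lab, np.column_stack([jr, jc]))
            junctions[lab].endpoints.append(ep)
    # junctions with < 2 attached endpoints impose no constraints; keep only real ones
    real = [j for j in junctions.values() if len(j.endpoints) >= 2]
    for k, j in enumerate(real):
        j.junction_id = k
    return parts, real


# --------------------------------------------------------------------------
# Prohibition by boundary turn angles
# --------------------------------------------------------------------------

def label_contour_by_parts(
    contour: np.ndarray,
    parts: list[BodyPart],
    max_dist_px: float,
) -> np.ndarray:
    """Label each contour pixel with the id of its nearest body part.

    Pixels farther than ``max_dist_px`` from every part's medial path stay
    unlabeled (-1); those are the junction stretches of the boundary.
    """
    n = len(contour)
    labels = np.full(n, -1, dtype=int)
    dmin = np.full(n, np.inf)
    cpts = contour.astype(float)
    for part in parts:
        path = part.path.astype(float)
        d = np.sqrt(
            ((cpts[:, None, :] - path[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        sel = (d < dmin) & (d <= max_dist_px)
        labels[sel] = part.part_id
        dmin[sel] = d[sel]
    return labels


def _contour_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal circular runs of identical labels: (label, start, stop_exclusive).

    ``stop`` may exceed ``len(labels)`` for the run wrapping the origin.
    """
    n = len(labels)
    if n == 0:
        return []
    # rotate so position 0 starts a run
    breaks = np.nonzero(labels != np.roll(labels, 1))[0]
    if len(breaks) == 0:
        return [(int(labels[0]), 0, n)]
    runs = []
    starts = list(breaks)
    for i, s in enumerate(starts):
        e = starts[(i + 1) % len(starts)]
        stop = e if e > s else e + n
        runs.append((int(labels[s]), int(s), int(stop)))
    return runs


def prohibit_pairings(
    junction: Junction,
    profile: TurnAngleProfile,
    contour: np.ndarray,
    parts: list[BodyPart] | None = None,
    part_labels: np.ndarray | None = None,
    half_width_px: float = 5.0,
    locality_px: float | None = None,
) -> Junction:
    """Prohibit endpoint pairings whose connecting boundary gap turns sharply.

    The contour is partitioned into runs owned by the nearest body part, with
    unlabeled gaps where the boundary crosses a junction.  Two parts are
    boundary-adjacent at this junction when a run of one is followed (up to a
    gap) by a run of the other near the junction pixels.  The pairing of
    their endpoints is prohibited when every such connecting gap contains a
    sharp turn — the contact notch between two different worms.  Pairs of
    parts that are not boundary-adjacent (e.g. opposite arms of a crossing)
    are unconstrained.  Prohibition is symmetric by construction.
    """
    if part_labels is None:
        if parts is None:
            raise ValueError("need either parts or part_labels")
        part_labels = label_contour_by_parts(contour, parts, 1.6 * half_width_px + 1.0)
    n = len(contour)
    runs = _contour_runs(part_labels)
    loc = locality_px if locality_px is not None else 3.0 * half_width_px + 2.0
    jpix = junction.pixels.astype(float)

    def near_junction(indices: np.ndarray) -> bool:
        pts = contour[indices % n].astype(float)
        d = np.sqrt(((pts[:, None, :] - jpix[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        return bool((d <= loc).any())

    labeled = [r for r in runs if r[0] >= 0]
    gap_info: dict[frozenset, list[bool]] = {}
    m = len(labeled)
    for t in range(m):
        la, (sa, ea) = labeled[t][0], labeled[t][1:]
        lb, (sb, eb) = labeled[(t + 1) % m][0], labeled[(t + 1) % m][1:]
        if la == lb:
            continue
        gap = np.arange(ea, sb if sb >= ea else sb + n)  # may be empty
        ext = max(2, profile.window_px)  # notch flags can bleed into the runs
        probe = np.concatenate([np.arange(ea - ext, ea), gap, np.arange(sb, sb + ext)])
        if not near_junction(probe):
            continue
        sharp = bool(profile.sharp[probe % n].any())
        gap_info.setdefault(frozenset((la, lb)), []).append(sharp)

    for a, b in combinations(junction.endpoints, 2):
        if a.part_id == b.part_id:
            junction.prohibited.add(frozenset((a.key, b.key)))  # no self-loops
            continue
        gaps = gap_info.get(frozenset((a.part_id, b.part_id)))
        if gaps and all(gaps):
            junction.prohibited.add(frozenset((a.key, b.key)))
        elif gaps and not all(gaps):
            junction.smooth_pairs.add(frozenset((a.part_id, b.part_id)))
    return junction


# --------------------------------------------------------------------------
# Junction resolution
# --------------------------------------------------------------------------

def _pair_score(a: Endpoint, b: Endpoint) -> float:
    """Continuation compatibility: 1 for a straight-through, equal-width join.

    Combines tangent continuity, alignment of the displacement with the
    tangents, and body-width continuity — a worm's width varies slowly along
    its body, so joining a tapered tip to a mid-body part is penalized.
    """
    cont = -float(np.dot(a.tangent, b.tangent))
    d = np.array(b.pixel, dtype=float) - np.array(a.pixel, dtype=float)
    norm = np.linalg.norm(d)
    if norm > 0:
        dhat = d / norm
        align = 0.5 * (float(np.dot(a.tangent, dhat)) + float(np.dot(b.tangent, -dhat)))
    else:
        align = 0.0
    wmax = max(a.width_px, b.width_px, 1.0)
    width_penalty = 0.6 * abs(a.width_px - b.width_px) / wmax
    return 0.5 * cont + 0.5 * align - width_penalty


def _best_matching(
    endpoints: list[Endpoint],
    allowed: dict[frozenset, float],
) -> list[tuple[tuple, tuple, float]]:
    """Enumerate all partial matchings; maximize total score, then pair count."""
    keys = [ep.key for ep in endpoints]
    best: tuple[float, int, list] = (-1e18, 0, [])

    def recurse(remaining: tuple, current: list, total: float) -> None:
        nonlocal best
        if not remaining:
            cand = (total, len(current), current)
            if (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
            return
        head, rest = remaining[0], remaining[1:]
        # leave head unmatched
        recurse(rest, current, total)
        for i, other in enumerate(rest):
            pair = frozenset((head, other))
            if pair in allowed:
                recurse(
                    rest[:i] + rest[i + 1:],
                    current + [(head, other, allowed[pair])],
                    total + allowed[pair],
                )

    recurse(tuple(keys), [], 0.0)
    return best[2]


def resolve_junctions(
    parts: list[BodyPart],
    junctions: list[Junction],
    config: SeparationConfig | None = None,
) -> list[np.ndarray]:
    """Pair part endpoints at each junction and assemble medial chains.

    Returns the list of assembled chain paths (ordered pixel polylines, with
    straight bridges across junction gaps).  Junctions whose endpoints cannot
    be paired at all despite multiple attached parts are flagged
    ``unresolved``.
    """
    cfg = config or SeparationConfig()
    for j in junctions:
        if len(j.endpoints) > cfg.max_junction_endpoints:
            j.unresolved = True
            j.matched = []
            continue
        allowed: dict[frozenset, float] = {}
        two_ended = (
            len(j.endpoints) == 2
            and j.endpoints[0].part_id != j.endpoints[1].part_id
        )
        for a, b in combinations(j.endpoints, 2):
            s = _pair_score(a, b)
            if two_ended and s >= 0.3:
                # a junction with exactly two attached parts cannot be
                # resolved by turn angles (end-to-end contact): connect the
                # parts into one long segment and let the length ruler decide
                allowed[frozenset((a.key, b.key))] = s
                continue
            if j.is_prohibited(a, b):
                continue
            smooth = frozenset((a.part_id, b.part_id)) in j.smooth_pairs
            if smooth:
                # a smooth boundary gap marks one silhouette continuing past
                # the junction: admit even sharply bent continuations
                allowed[frozenset((a.key, b.key))] = s + cfg.smooth_gap_bonus
            elif s >= cfg.min_continuation_score:
                allowed[frozenset((a.key, b.key))] = s
        j.matched = _best_matching(j.endpoints, allowed)
        j.unresolved = len(j.endpoints) >= 3 and not j.matched
    chains, _ = _assemble_chains(parts, junctions)
    return chains


def _assemble_chains(parts, junctions):
    """Walk part/bridge edges into chains; cycles are broken at the weakest bridge."""
    bridge: dict[tuple, tuple] = {}
    scores: dict[frozenset, float] = {}
    for j in junctions:
        for ka, kb, s in j.matched:
            bridge[ka] = kb
            bridge[kb] = ka
            scores[frozenset((ka, kb))] = s
    part_by_id = {p.part_id: p for p in parts}

    def endpoint_pixel(key):
        p = part_by_id[key[0]]
        return p.path[-1] if key[1] == 1 else p.path[0]

    chains: list[np.ndarray] = []
    chain_parts: list[list[int]] = []
    visited: set[int] = set()

    def walk(start_key) -> tuple[np.ndarray, list[int]]:
        segments = []
        members = []
        key = start_key
        while True:
            pid, end = key
            visited.add(pid)
            members.append(pid)
            path = part_by_id[pid].path
            segments.append(path if end == 0 else path[::-1])
            other = (pid, 1 - end)
            nxt = bridge.get(other)
            if nxt is None or nxt[0] in visited:
                break
            # straight bridge across the junction gap
            p0 = endpoint_pixel(other)
            p1 = endpoint_pixel(nxt)
            rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
            if len(rr) > 2:
                segments.append(np.column_stack([rr[1:-1], cc[1:-1]]))
            key = nxt
        return np.concatenate(segments), members

    # open chains first (free ends), then leftover cycles
    for p in sorted(parts, key=lambda q: q.part_id):
        if p.part_id in visited:
            continue
        for end in (0, 1):
            if (p.part_id, end) not in bridge:
                path, members = walk((p.part_id, end))
                chains.append(path)
                chain_parts.append(members)
                break
        else:
            continue
    for p in sorted(parts, key=lambda q: q.part_id):
        if p.part_id in visited:
            continue
        # cycle: drop this part's weakest bridge and walk from the cut
        k0, k1 = (p.part_id, 0), (p.part_id, 1)
        weakest = min(
            (k for k in (k0, k1)),
            key=lambda k: scores.get(frozenset((k, bridge[k])), 0.0),
        )
        partner = bridge.pop(weakest)
        bridge.pop(partner, None)
        path, members = walk(weakest)
        chains.append(path)
        chain_parts.append(members)
    return chains, chain_parts


# --------------------------------------------------------------------------
# Chain splitting and pixel assignment
# --------------------------------------------------------------------------

def split_chains(path: np.ndarray, area_model: AreaModel,
                 ruler_px: float | None = None,
                 n_override: int | None = None,
                 widths: np.ndarray | None = None) -> list[np.ndarray]:
    """Cut an assembled medial chain into individual worms by the length ruler.

    ``n = round(length / ruler)`` clamped to >= 1; the chain is cut into *n*
    contiguous pieces of equal medial arclength.  ``n_override`` forces the
    piece count (used when the component's area-based worm count supplies
    stronger evidence than the chain length alone).  When a local width
    profile is given, each cut snaps to the narrowest point within a small
    window around the equal-length position — worm-worm contact points are
    width constrictions, so this recovers the true boundary of end-to-end
    chains of unequal worms.
    """
    ruler = ruler_px or area_model.single_worm_length_px
    if not ruler and n_override is None:
        return [path]
    total = _path_arclength(path)
    if n_override is not None:
        n = max(1, int(n_override))
    else:
        n = max(1, int(math.floor(total / ruler + 0.5)))
    if n == 1 or len(path) < 2 * n:
        return [path]
    steps = np.abs(np.diff(path, axis=0))
    w = np.where(steps.sum(axis=1) == 2, math.sqrt(2), 1.0)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    cut_idx = [0]
    for k in range(1, n):
        target = k * total / n
        nominal = int(np.argmin(np.abs(cum - target)))
        if widths is not None:
            window = max(6.0, 0.15 * total / n)
            cand = np.nonzero(np.abs(cum - target) <= window)[0]
            cand = cand[(cand > cut_idx[-1] + 1) & (cand < len(path) - 1)]
            if len(cand):
                wvals = np.asarray(widths, dtype=float)[cand]
                best = np.lexsort((np.abs(cum[cand] - target), wvals))[0]
                nominal = int(cand[best])
        cut_idx.append(max(nominal, cut_idx[-1] + 1))
    cut_idx.append(len(path))
    pieces = []
    for k in range(n):
        piece = path[cut_idx[k]: cut_idx[k + 1]]
        if len(piece) == 0:
            piece = path[[min(cut_idx[k], len(path) - 1)]]
        pieces.append(piece)
    return pieces


def _cumlength(path: np.ndarray) -> np.ndarray:
    if len(path) < 2:
        return np.zeros(len(path))
    steps = np.abs(np.diff(path, axis=0))
    w = np.where(steps.sum(axis=1) == 2, math.sqrt(2), 1.0)
    return np.concatenate([[0.0], np.cumsum(w)])


def find_constriction_cuts(
    widths: np.ndarray,
    cum: np.ndarray,
    ruler_px: float,
    single_width_px: float,
    depth_factor: float = 0.65,
    min_piece_frac: float = 0.45,
) -> list[int]:
    """Indices of deep interior width minima along a chain — contact points.

    Two worms joined end to end leave a pronounced constriction where the
    tapered tips meet; unlike the length ruler this evidence is insensitive
    to worm-size variation.  Candidate cuts are interior points whose local
    width falls below ``depth_factor`` x the single-worm width, accepted
    narrowest-first while staying ``min_piece_frac`` x ruler away from the
    chain ends and from each other.
    """
    total = cum[-1] if len(cum) else 0.0
    margin = min_piece_frac * ruler_px
    interior = (cum > margin) & (cum < total - margin)
    if not interior.any():
        return []
    # relative to the chain's own body width: thin worms must not self-trigger
    body_width = min(float(np.median(widths[interior])), single_width_px)
    threshold = depth_factor * body_width
    cand = np.nonzero(interior & (widths < threshold))[0]
    if len(cand) == 0:
        return []
    order = cand[np.argsort(widths[cand], kind="stable")]
    cuts: list[int] = []
    for idx in order:
        if all(abs(cum[idx] - cum[c]) >= min_piece_frac * ruler_px for c in cuts):
            cuts.append(int(idx))
    return sorted(cuts)


def _split_sideways(territory: np.ndarray, chain: np.ndarray):
    """Split a territory across the chain: pixels left vs right of the midline.

    For two worms lying side by side the merged medial line runs along the
    contact, between the bodies — so the true boundary is the midline itself,
    not a perpendicular cut.  Returns (left_mask, right_mask) or None when
    the split is degenerate (one side nearly empty).
    """
    rr, cc = np.nonzero(territory)
    if len(rr) == 0 or len(chain) < 3:
        return None
    pts = np.column_stack([rr, cc]).astype(float)
    ch = chain.astype(float)
    # smoothed tangents along the chain
    tang = np.gradient(ch, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang /= norms[:, None]
    d2 = ((pts[:, None, :] - ch[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    rel = pts - ch[nearest]
    t = tang[nearest]
    side = t[:, 0] * rel[:, 1] - t[:, 1] * rel[:, 0]  # signed cross product
    left = side >= 0
    n_left = int(left.sum())
    if min(n_left, len(pts) - n_left) < 0.2 * len(pts):
        return None
    left_mask = np.zeros_like(territory)
    right_mask = np.zeros_like(territory)
    left_mask[rr[left], cc[left]] = True
    right_mask[rr[~left], cc[~left]] = True
    return left_mask, right_mask


def _assign_pixels(mask: np.ndarray, seeds: list[np.ndarray]) -> np.ndarray:
    """Multi-source BFS: label every mask pixel by its geodesically nearest seed."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    q: deque = deque()
    for lab, seed in enumerate(seeds, start=1):
        for r, c in seed:
            if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c] \
                    and labels[r, c] == 0:
                labels[r, c] = lab
                q.append((int(r), int(c)))
    while q:
        r, c = q.popleft()
        lab = labels[r, c]
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] \
                    and mask[rr, cc] and labels[rr, cc] == 0:
                labels[rr, cc] = lab
                q.append((rr, cc))
    return labels


# --------------------------------------------------------------------------
# Full cascade
# --------------------------------------------------------------------------

def separate_component(
    component: WormComponent,
    area_model: AreaModel,
    config: SeparationConfig | None = None,
) -> SeparationResult:
    """Separate a connected component into individual worm instances.

    Single-worm components short-circuit to one ``isolated`` instance with the
    component's exact pixel set.  Failures are reported as flags, never
    exceptions.
    """
    cfg = config or SeparationConfig()
    expected = count_worms(component, area_model)
    off_r, off_c = component.offset
    if expected == 1 and not _looks_multiworm(component, area_model, cfg):
        r, c = np.nonzero(component.mask)
        inst = WormInstance(1, r + off_r, c + off_c,
                            _estimate_length(component), "isolated")
        return SeparationResult([inst], 1, True)

    parts, junctions = extract_body_parts(component, area_model, config=cfg)
    if not parts:
        r, c = np.nonzero(component.mask)
        inst = WormInstance(1, r + off_r, c + off_c,
                            _estimate_length(component), "unresolved")
        return SeparationResult([inst], expected, False, len(junctions))

    contour = component.boundary - np.array([off_r, off_c])
    try:
        profile = compute_turn_angles(contour, cfg.turn_window_px, cfg.sharp_turn_deg)
    except ValueError:
        profile = TurnAngleProfile(
            np.zeros(len(contour)), np.zeros(len(contour), dtype=bool),
            cfg.turn_window_px, cfg.sharp_turn_deg,
        )
    half = single_worm_half_width(area_model, component)
    part_labels = label_contour_by_parts(contour, parts, 1.6 * half + 1.0)
    for j in junctions:
        prohibit_pairings(j, profile, contour, part_labels=part_labels,
                          half_width_px=half)
    chains = resolve_junctions(parts, junctions, cfg)
    n_unresolved = sum(j.unresolved for j in junctions)
    # fragments far shorter than any worm are junction debris, not seeds
    ruler = area_model.single_worm_length_px
    if ruler:
        kept = [c for c in chains if _path_arclength(c) >= 0.35 * ruler]
        if kept:
            chains = kept

    # stage 1: assign every component pixel to its geodesically nearest chain
    chain_labels = _assign_pixels(component.mask, chains)
    chain_labels = _fill_unreached(chain_labels, component.mask)
    chain_areas = np.bincount(chain_labels.ravel(), minlength=len(chains) + 1)[1:]
    edt = ndimage.distance_transform_edt(component.mask)
    single_width = 2.0 * half
    widths_list = [2.0 * edt[c[:, 0], c[:, 1]] for c in chains]
    # a chain substantially wider than one body over a sustained stretch is a
    # side-by-side contact regardless of what the noisy area count says
    fat_flags = [
        bool(len(w)) and float(np.mean(w > 1.5 * single_width)) > 0.2
        for w in widths_list
    ]
    counts = _chain_worm_counts(chains, chain_areas, area_model, fat_flags)

    base_conf = "unresolved" if n_unresolved else "resolved"
    instances: list[WormInstance] = []
    wid = 0
    for i, (chain, n_pieces) in enumerate(zip(chains, counts)):
        territory = chain_labels == i + 1
        widths = widths_list[i]
        cum = _cumlength(chain)
        total = cum[-1] if len(cum) else 0.0
        is_fat = fat_flags[i]
        pieces = None
        if ruler and not is_fat and total > 1.2 * ruler:
            cuts = find_constriction_cuts(widths, cum, ruler, single_width)
            if cuts:
                bounds = [0] + cuts + [len(chain)]
                pieces = [chain[bounds[k]: bounds[k + 1]] for k in range(len(bounds) - 1)]
        if pieces is None and is_fat and n_pieces == 2:
            halves = _split_sideways(territory, chain)
            if halves is not None:
                conf = "unresolved" if n_unresolved else "chain_split"
                for hm in halves:
                    r, c = np.nonzero(hm)
                    wid += 1
                    instances.append(WormInstance(
                        wid, r + off_r, c + off_c, _path_arclength(chain), conf))
                continue
        if pieces is None:
            pieces = split_chains(chain, area_model, n_override=n_pieces,
                                  widths=widths)
        conf = "unresolved" if n_unresolved else (
            "chain_split" if len(pieces) > 1 else base_conf
        )
        if len(pieces) == 1:
            r, c = np.nonzero(territory)
            if len(r):
                wid += 1
                instances.append(WormInstance(
                    wid, r + off_r, c + off_c, _path_arclength(chain), conf))
            continue
        # stage 2: split the chain's own territory among its pieces
        piece_labels = _assign_pixels(territory, pieces)
        piece_labels = _fill_unreached(piece_labels, territory)
        for k, piece in enumerate(pieces):
            r, c = np.nonzero(piece_labels == k + 1)
            if len(r) == 0:
                continue
            wid += 1
            instances.append(WormInstance(
                wid, r + off_r, c + off_c, _path_arclength(piece), conf))
    success = (len(instances) == expected) and n_unresolved == 0
    return SeparationResult(instances, expected, success, n_unresolved)


def _looks_multiworm(component: WormComponent, area_model: AreaModel,
                     cfg: SeparationConfig) -> bool:
    """Secondary screen for components the area count calls single.

    Two small touching worms can have the area of one average worm; their
    skeleton is however much longer than the ruler, or locally much wider
    than one body.  Such components go through the full cascade.
    """
    ruler = area_model.single_worm_length_px
    if not ruler:
        return False
    skel = morphology.skeletonize(component.mask)
    if not skel.any():
        return False
    edt = ndimage.distance_transform_edt(component.mask)
    vals = edt[skel]
    n_ax = int(skel.sum())  # pixel count: cheap lower bound on arclength
    half = single_worm_half_width(area_model, component)
    wide_frac = float(np.mean(vals > 1.5 * half))
    return n_ax > 1.35 * ruler or wide_frac > 0.2


def _fill_unreached(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Assign any unlabeled mask pixel to its nearest labeled pixel."""
    if ((labels == 0) & mask).any():
        _, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
        labels = np.where(mask & (labels == 0), labels[ir, ic], labels)
    return labels


def _chain_worm_counts(chains, chain_areas, area_model: AreaModel,
                       fat_flags=None) -> list[int]:
    """Worms per chain, from length and area evidence combined.

    Per chain the worm count is the stronger of two signals: medial length /
    ruler (robust for end-to-end chains of small worms) and pixel area /
    single-worm area (robust for side-by-side contacts, whose merged skeleton
    is shorter than the sum of the midlines).  Rounding is biased slightly
    downward because junction-zone pixels inflate the area of single-worm
    chains, while genuine multi-worm chains sit well above the boundary.
    A chain flagged fat (sustained double width) holds at least two worms
    whenever either signal gives it more than ~1.2 worm-equivalents.
    """
    ruler = area_model.single_worm_length_px
    if not ruler or ruler <= 0:
        return [1] * len(chains)
    single_area = area_model.single_worm_area_px
    counts = []
    for k, (chain, area) in enumerate(zip(chains, chain_areas)):
        ideal = max(_path_arclength(chain) / ruler, area / single_area)
        n = max(1, int(math.floor(ideal + 0.4)))
        if fat_flags is not None and k < len(fat_flags) and fat_flags[k]                 and n == 1 and ideal >= 1.2:
            n = 2
        counts.append(n)
    return counts


def _estimate_length(component: WormComponent) -> float:
    from .segmentation import skeleton_length

    return skeleton_length(component.mask)


def render_debug_overlay(
    component: WormComponent,
    area_model: AreaModel,
    config: SeparationConfig | None = None,
) -> np.ndarray:
    """RGB overlay of the separation machinery for one component.

    Gray: component pixels; white: body-part medial paths; red: junction
    skeleton pixels; green: boundary pixels flagged as sharp turns; blue:
    the remaining (smooth) boundary.  Useful for eyeballing why a particular
    cluster did or did not resolve.
    """
    cfg = config or SeparationConfig()
    h, w = component.mask.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[component.mask] = (90, 90, 90)
    parts, junctions = extract_body_parts(component, area_model, config=cfg)
    contour = component.boundary - np.array(component.offset)
    try:
        profile = compute_turn_angles(contour, cfg.turn_window_px,
                                      cfg.sharp_turn_deg)
        sharp = profile.sharp
    except ValueError:
        sharp = np.zeros(len(contour), dtype=bool)
    img[contour[:, 0], contour[:, 1]] = (60, 60, 200)
    img[contour[sharp, 0], contour[sharp, 1]] = (0, 200, 0)
    for part in parts:
        img[part.path[:, 0], part.path[:, 1]] = (255, 255, 255)
    for j in junctions:
        img[j.pixels[:, 0], j.pixels[:, 1]] = (220, 40, 40)
    return img
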