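"""Moore-neighbor boundary tracing for binary components."""

from __future__ import annotations

import numpy as np

# Moore neighborhood in clockwise order starting from "west", as
# (drow, dcol).  Image coordinates: row grows downward.
_CLOCKWISE = [
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
]
_OFFSET_TO_IDX = {off: i for i, off in enumerate(_CLOCKWISE)}


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary of the (single) 8-connected component in ``mask``.

    Moore-neighbor tracing, clockwise, starting from the topmost-leftmost
    foreground pixel (ties broken row first, then column).  Terminates when
    the walk re-enters the start pixel with the same outgoing move as the
    first step (Jacob's criterion).  Returns an (n, 2) int array of
    (row, col); the path is closed implicitly (last adjacent to first).
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return np.empty((0, 2), dtype=int)
    start = (int(rows[0]) + 1, int(cols[0]) + 1)  # row-major: topmost-leftmost
    padded = np.pad(mask, 1)

    path = [start]
    cur = start
    backtrack_idx = 0  # start's west neighbor is background by construction
    first_move: tuple | None = None
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        for k in range(1, 9):
            idx = (backtrack_idx + k) % 8
            dr, dc = _CLOCKWISE[idx]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                break
        else:
            return np.array(path) - 1  # isolated pixel
        if first_move is None:
            first_move = (cur, idx)
        elif (cur, idx) == first_move:
            # about to repeat the initial move from the start pixel: done.
            # the walk has already re-appended `start`; drop that duplicate.
            return np.array(path[:-1]) - 1
        path.append(cand)
        backtrack_idx = _OFFSET_TO_IDX[(cur[0] - cand[0], cur[1] - cand[1])]
        cur = cand
    return np.array(path) - 1
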