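"""Reading time-lapse image series and writing result tables and label masks.

The on-disk layout is deliberately plain: grayscale TIFF frames named
``<chamber>_<channel>_t<hours>_p<pairindex>.tif``, CSV tables, 16-bit TIFF
label masks, and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

CHANNEL_CODES = {"bf": "brightfield", "fl": "fluorescence"}
CHANNEL_TO_CODE = {v: k for k, v in CHANNEL_CODES.items()}

#: Named-group regex matched against frame filenames by :func:`load_series`.
DEFAULT_PATTERN = (
    r"(?P<chamber>[A-Za-z0-9-]+)_(?P<channel>bf|fl)"
    r"_t(?P<time>[0-9]+(?:\.[0-9]+)?)_p(?P<pair>[01])\.(tif|tiff|png)$"
)

#: Column order of the per-worm measurement table.
MEASUREMENT_COLUMNS = [
    "chamber_id",
    "time_h",
    "worm_id",
    "area_px",
    "fluorescence_total",
    "opacity",
    "motility",
    "viability",
    "confidence",
]


@dataclass
class Frame:
    """One grayscale image plus its acquisition metadata.

    ``pixels`` are intensities normalized to [0, 1]; darkness (used throughout
    the analysis) is defined as ``1 - pixels``.  ``pair_index`` distinguishes
    the two members of a ~1 s motility pair taken at the same nominal hour.
    """

    pixels: np.ndarray
    channel: str  # "brightfield" | "fluorescence"
    chamber_id: str
    time_h: float
    pair_index: int = 0
    path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Frame pixels must be a nonempty 2-D array")
        if self.channel not in ("brightfield", "fluorescence"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")

    @property
    def darkness(self) -> np.ndarray:
        """1 - intensity, so that darker pixels have larger values."""
        return 1.0 - self.pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def sort_key(self) -> tuple:
        return (self.chamber_id, self.time_h, self.pair_index, self.channel)


def _normalize(raw: np.ndarray, mode: str) -> np.ndarray:
    raw = np.asarray(raw)
    if raw.ndim == 3:  # collapse trivial color axes
        raw = raw[..., 0]
    if mode == "bit_depth":
        if raw.dtype == np.uint8:
            return raw.astype(float) / 255.0
        if raw.dtype == np.uint16:
            return raw.astype(float) / 65535.0
        arr = raw.astype(float)
        if arr.max() > 1.0:
            arr = arr / arr.max()
        return np.clip(arr, 0.0, 1.0)
    if mode == "minmax":
        arr = raw.astype(float)
        lo, hi = arr.min(), arr.max()
        return np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    if mode == "none":
        return np.clip(raw.astype(float), 0.0, 1.0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def load_series(
    root: str | Path,
    pattern: str = DEFAULT_PATTERN,
    normalization: str = "bit_depth",
) -> list[Frame]:
    """Load every frame under ``root`` whose name matches ``pattern``.

    The regex must expose named groups ``chamber``, ``channel`` (``bf``/``fl``),
    ``time`` (hours) and ``pair`` (0/1).  Frames are returned sorted by
    (chamber, time, pair, channel).  Files that look like images but do not
    match the pattern raise; unrelated files are ignored.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory does not exist: {root}")
    rx = re.compile(pattern)
    frames: list[Frame] = []
    shapes: dict[str, tuple[int, int]] = {}
    for path in sorted(root.iterdir()):
        if path.suffix.lower() not in (".tif", ".tiff", ".png"):
            continue
        m = rx.search(path.name)
        if m is None:
            raise ValueError(f"filename does not match pattern: {path.name}")
        raw = tifffile.imread(path) if path.suffix.lower() != ".png" else _read_png(path)
        frame = Frame(
            pixels=_normalize(raw, normalization),
            channel=CHANNEL_CODES[m.group("channel")],
            chamber_id=m.group("chamber"),
            time_h=float(m.group("time")),
            pair_index=int(m.group("pair")),
            path=str(path),
        )
        prev = shapes.setdefault(frame.chamber_id, frame.shape)
        if prev != frame.shape:
            raise ValueError(
                f"mixed image sizes within chamber {frame.chamber_id}: "
                f"{prev} vs {frame.shape} ({path.name})"
            )
        frames.append(frame)
    if not frames:
        log.warning("no frames found under %s", root)
    keys = [(f.chamber_id, f.channel, f.time_h, f.pair_index) for f in frames]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (chamber, channel, time, pair) keys in series")
    frames.sort(key=Frame.sort_key)
    return frames


def _read_png(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(path)


def frame_filename(frame: Frame) -> str:
    t = frame.time_h
    t_str = f"{t:g}" if t == int(t) else f"{t:.3f}".rstrip("0")
    return f"{frame.chamber_id}_{CHANNEL_TO_CODE[frame.channel]}_t{t_str}_p{frame.pair_index}.tif"


def write_frames(frames: Iterable[Frame], out_dir: str | Path, bit_depth: int = 16) -> list[Path]:
    """Write frames as grayscale TIFFs using the canonical filename scheme."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in frames:
        if bit_depth == 16:
            data = np.round(np.clip(frame.pixels, 0, 1) * 65535).astype(np.uint16)
        elif bit_depth == 8:
            data = np.round(np.clip(frame.pixels, 0, 1) * 255).astype(np.uint8)
        else:
            raise ValueError("bit_depth must be 8 or 16")
        path = out_dir / frame_filename(frame)
        tifffile.imwrite(path, data)
        paths.append(path)
    return paths


def empty_measurement_table() -> pd.DataFrame:
    return pd.DataFrame(columns=MEASUREMENT_COLUMNS)


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    masks: Mapping[str, np.ndarray] | None,
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write CSV tables, 16-bit label-mask TIFFs and a JSON run manifest.

    Returns the manifest (also written to ``manifest.json``).  The CSV round
    trip is lossless: ``read_table(path)`` reproduces the rows exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tables": {},
        "masks": {},
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest["tables"][name] = path.name
    for name, mask in (masks or {}).items():
        if mask.max() > 65535:
            raise ValueError("label mask exceeds 16-bit range")
        path = out_dir / f"{name}_labels.tif"
        tifffile.imwrite(path, mask.astype(np.uint16))
        manifest["masks"][name] = path.name
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)
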