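"""Movie, table and configuration I/O.

Movies are multi-page TIFF, 16-bit unsigned, one page per frame, with the
frame interval and pre-trigger frame count stored in the image description so
a write/read round trip is lossless.  Tables (spots, events, comparisons) go
through pandas CSV; run configuration is YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .spotdetect import SpotRecord
from .synthgen import Movie

logger = logging.getLogger("vesiclekit")

__all__ = ["read_movie", "write_movie", "RunConfig", "spots_to_dataframe",
           "events_to_dataframe", "write_report"]


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-page 16-bit unsigned TIFF (values clipped/rounded)."""
    frames = np.clip(np.rint(np.asarray(movie.frames, dtype=float)), 0, 65535).astype(np.uint16)
    meta = json.dumps({"frame_interval_s": movie.frame_interval_s,
                       "n_pre_frames": movie.n_pre_frames,
                       "n_frames": movie.n_frames})
    tifffile.imwrite(path, frames, photometric="minisblack", description=meta)


def read_movie(path) -> Movie:
    """Read a multi-page 16-bit unsigned TIFF as a Movie; lossless round trip."""
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:
        raise ValueError(f"unreadable TIFF file {path}: {exc}") from exc
    with tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path} contains zero pages")
        frames = []
        for i, page in enumerate(tif.pages):
            try:
                arr = page.asarray()
            except Exception as exc:
                raise ValueError(f"failed to read page {i} of {path}: {exc}") from exc
            if arr.dtype != np.uint16:
                raise ValueError(f"page {i} of {path} is {arr.dtype}, expected uint16")
            frames.append(arr)
        desc = tif.pages[0].description or ""
    interval, n_pre = 1.0, 0
    try:
        meta = json.loads(desc)
        interval = float(meta.get("frame_interval_s", 1.0))
        n_pre = int(meta.get("n_pre_frames", 0))
        n_expected = meta.get("n_frames")
        if n_expected is not None and len(frames) < int(n_expected):
            raise ValueError(f"{path} is truncated: failed to read page "
                             f"{len(frames)} of {int(n_expected)}")
    except (json.JSONDecodeError, AttributeError, TypeError):
        logger.debug("read_movie: no embedded metadata in %s; assuming 1-s frames", path)
    return Movie(np.stack(frames), frame_interval_s=interval, n_pre_frames=n_pre)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; embedded in every report."""

    experiment: str                       # "fusion" | "clustering"
    presets: list[str]
    n_locations: int = 10
    seed: int = 42
    outdir: str | None = None
    exact_counts: bool = True             # fusion fixtures plant exact docked/event totals
    preset_overrides: dict = field(default_factory=dict)  # make_preset field overrides
    detection: dict = field(default_factory=dict)   # detect_spots overrides
    kinetics: dict = field(default_factory=dict)    # detect_step overrides
    classifier: dict = field(default_factory=dict)  # ClassifierParams overrides
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.experiment not in ("fusion", "clustering"):
            raise ValueError("experiment must be 'fusion' or 'clustering'")
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if not self.presets:
            raise ValueError("at least one preset is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def spots_to_dataframe(spots: Sequence[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in spots],
                        columns=["fov_id", "frame", "x", "y", "intensity_raw",
                                 "area_px", "intensity_au"])


def events_to_dataframe(events) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in events],
                        columns=["spot_id", "fov_id", "t_event_s", "t_sync_s", "step_ratio"])


def write_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=_default)
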