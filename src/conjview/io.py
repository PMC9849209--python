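"""Reading and writing of movies, masks and tidy tables.

Movies travel as one multi-page TIFF per channel plus a YAML sidecar with
pixel size and frame interval; ground truth and measurements are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .render import CHANNELS, MovieStack

__all__ = ["write_movie", "read_movie", "write_labels", "read_labels"]


def write_movie(movie: MovieStack, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ch, stack in movie.channels.items():
        tifffile.imwrite(out / f"{ch}.tif", stack.astype(np.float32))
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_min": movie.frame_interval_min,
        "channels": list(movie.channels),
    }
    with open(out / "movie.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return out


def read_movie(in_dir: str | Path) -> MovieStack:
    d = Path(in_dir)
    with open(d / "movie.yaml") as fh:
        meta = yaml.safe_load(fh)
    channels = {ch: tifffile.imread(d / f"{ch}.tif") for ch in meta.get("channels", CHANNELS)}
    return MovieStack(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_min=float(meta["frame_interval_min"]),
    )


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.int32))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
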