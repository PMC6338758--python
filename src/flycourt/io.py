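"""File I/O for recordings, landmark tables and configuration.

Frame stacks travel as zero-padded numbered PNG sequences or multi-page TIFFs,
always with a JSON sidecar holding the arena geometry and frame interval.
Landmark tables are CSV in image pixel coordinates (y increases downward).
Simulation/run configuration is TOML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .angle import LandmarkSet
from .detect import AssayRecording

__all__ = [
    "write_recording",
    "read_recording",
    "read_landmark_csv",
    "write_landmark_csv",
    "load_toml",
]

_SIDECAR = "meta.json"


def write_recording(rec: AssayRecording, path: str | Path, fmt: str = "tiff") -> Path:
    """Write a recording as PNG sequence (``fmt='png'``, to a directory) or
    multi-page TIFF (``fmt='tiff'``), plus a JSON sidecar with arena metadata.

    Returns the path of the frame data (directory or .tif file).
    """
    path = Path(path)
    meta = {
        "assay_id": rec.assay_id,
        "timestamps_s": rec.timestamps_s.tolist(),
        "arena": rec.arena,
    }
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(rec.frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
        sidecar = path / _SIDECAR
    elif fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix not in (".tif", ".tiff"):
            path = path.with_suffix(".tif")
        tifffile.imwrite(str(path), rec.frames, photometric="minisblack")
        sidecar = path.with_suffix(".json")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh)
        fh.write("\n")
    return path


def read_recording(path: str | Path) -> AssayRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(
                f"no frame_NNNNNN.png files in {path}; expected a PNG sequence "
                f"plus a {_SIDECAR} sidecar"
            )
        frames = np.stack([iio.imread(f) for f in files])
        sidecar = path / _SIDECAR
    else:
        frames = tifffile.imread(str(path))
        sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        ts = np.asarray(meta.get("timestamps_s", np.arange(len(frames))), dtype=float)
        arena = meta.get("arena", {})
        assay_id = meta.get("assay_id", path.stem)
    else:
        ts = np.arange(len(frames), dtype=float)
        arena = {}
        assay_id = path.stem
    return AssayRecording(frames=frames, timestamps_s=ts, arena=arena, assay_id=assay_id)


_LANDMARK_COLS = [
    "male_id", "anus_x", "anus_y", "penis_x", "penis_y",
    "mid_a_x", "mid_a_y", "mid_b_x", "mid_b_y",
]


def write_landmark_csv(sets: dict[str, LandmarkSet], path: str | Path) -> None:
    """Write labelled landmark sets to CSV (image pixel coordinates)."""
    rows = [
        {
            "male_id": male_id,
            "anus_x": lm.anus[0], "anus_y": lm.anus[1],
            "penis_x": lm.penis[0], "penis_y": lm.penis[1],
            "mid_a_x": lm.midline_a[0], "mid_a_y": lm.midline_a[1],
            "mid_b_x": lm.midline_b[0], "mid_b_y": lm.midline_b[1],
        }
        for male_id, lm in sets.items()
    ]
    pd.DataFrame(rows, columns=_LANDMARK_COLS).to_csv(path, index=False)


def read_landmark_csv(path: str | Path) -> dict[str, LandmarkSet]:
    """Read landmark sets from CSV; returns {male_id: LandmarkSet}."""
    df = pd.read_csv(path)
    missing = set(_LANDMARK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    return {
        str(r.male_id): LandmarkSet(
            anus=(r.anus_x, r.anus_y),
            penis=(r.penis_x, r.penis_y),
            midline_a=(r.mid_a_x, r.mid_a_y),
            midline_b=(r.mid_b_x, r.mid_b_y),
        )
        for r in df.itertuples()
    }


def load_toml(path: str | Path) -> dict:
    """Load a TOML configuration file."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
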