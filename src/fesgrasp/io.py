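"""File formats: 16-bit PNG depth (mm), 8-bit RGB PNG, JSON sidecars, and
run-length encoded masks for JSONL tracking logs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .camera_geometry import ColorFrame, DepthFrame
from .plane_detect import BackgroundImage, PlaneModel


def save_depth_png(depth: DepthFrame, path) -> None:
    iio.imwrite(path, np.round(depth.depth).clip(0, 65535).astype(np.uint16))


def load_depth_png(path) -> DepthFrame:
    return DepthFrame(iio.imread(path).astype(np.float64))


def save_color_png(rgb: ColorFrame, path) -> None:
    iio.imwrite(path, rgb.rgb)


def load_color_png(path) -> ColorFrame:
    return ColorFrame(iio.imread(path)[..., :3].astype(np.uint8))


def save_background(bg: BackgroundImage, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_depth_png(DepthFrame(bg.bcg), d / "bcg.png")
    (d / "bcg.json").write_text(
        json.dumps(
            {
                "n_frames_averaged": bg.n_frames_averaged,
                "plane_normal": bg.table_plane.normal.tolist(),
                "plane_offset": bg.table_plane.offset,
            },
            indent=1,
        )
    )


def load_background(directory) -> BackgroundImage:
    d = Path(directory)
    meta = json.loads((d / "bcg.json").read_text())
    return BackgroundImage(
        bcg=load_depth_png(d / "bcg.png").depth,
        n_frames_averaged=meta["n_frames_averaged"],
        table_plane=PlaneModel(np.array(meta["plane_normal"]), meta["plane_offset"]),
    )


def mask_to_rle(mask: np.ndarray) -> dict:
    """Flat run-length encoding (C order): alternating run lengths starting
    with a zero-run."""
    flat = mask.reshape(-1).astype(np.int8)
    edges = np.flatnonzero(np.diff(flat))
    bounds = np.concatenate(([0], edges + 1, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def rle_to_mask(rle: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(rle["shape"])), dtype=bool)
    pos, val = 0, False
    for run in rle["runs"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(rle["shape"])
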