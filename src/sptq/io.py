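"""File round-trips for movies, tables and masks.

Movies travel as multi-page TIFF with a JSON sidecar acquisition descriptor
(frame interval, pixel size, activation-frame indices); tables as headered
CSV; masks as 8-bit TIFF/PNG images where nonzero means inside.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread, imwrite

from .simulate import ImageStack
from .spatial import RegionMasks


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a movie as multi-page TIFF plus a .json descriptor sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    path.with_suffix(".json").write_text(json.dumps(stack.descriptor(), indent=2))


def read_stack(path: str | Path, descriptor_path: str | Path | None = None) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    dpath = Path(descriptor_path) if descriptor_path else path.with_suffix(".json")
    desc = json.loads(dpath.read_text())
    if desc["n_frames"] != len(frames):
        raise ValueError(
            f"descriptor frame count {desc['n_frames']} != stack frames {len(frames)}"
        )
    is_act = np.zeros(len(frames), dtype=bool)
    is_act[desc.get("activation_frames", [])] = True
    return ImageStack(
        frames=frames,
        pixel_size=desc["pixel_size"],
        frame_interval=desc["frame_interval"],
        is_activation=is_act,
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def trajectories_to_table(trajs) -> pd.DataFrame:
    rows = [
        pd.DataFrame(
            {"traj_id": t.traj_id, "frame": t.frames, "x_um": t.xy[:, 0], "y_um": t.xy[:, 1]}
        )
        for t in trajs
    ]
    cols = ["traj_id", "frame", "x_um", "y_um"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def table_to_trajectories(table: pd.DataFrame):
    from .tracking import Trajectory

    return [
        Trajectory(
            traj_id=int(tid),
            frames=g["frame"].to_numpy(),
            xy=g[["x_um", "y_um"]].to_numpy(),
        )
        for tid, g in table.sort_values(["traj_id", "frame"]).groupby("traj_id")
    ]


def read_mask(path: str | Path) -> np.ndarray:
    img = imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_region_masks(masks: RegionMasks, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("cell", "nucleoid", "membrane", "cytoplasm"):
        write_mask(getattr(masks, name), directory / f"{name}.png")
    (directory / "pixel_size.json").write_text(
        json.dumps({"pixel_size_um": masks.pixel_size})
    )


def read_region_masks(directory: str | Path) -> RegionMasks:
    directory = Path(directory)
    px = json.loads((directory / "pixel_size.json").read_text())["pixel_size_um"]
    return RegionMasks(
        cell=read_mask(directory / "cell.png"),
        nucleoid=read_mask(directory / "nucleoid.png"),
        membrane=read_mask(directory / "membrane.png"),
        cytoplasm=read_mask(directory / "cytoplasm.png"),
        pixel_size=px,
    )
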