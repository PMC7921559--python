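"""Reading and writing the pipeline's file formats.

Images go through tifffile (multichannel stacks as ZCYX, 16-bit; label masks
as single-channel TIFF or PNG); tables are plain CSV with fixed headers so
reruns are byte-comparable.  Track tables default to the columns
``track_id, frame, time_s, x_um, y_um`` but a column map adapts common
tracker exports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .detection import ImageStack
from .motion import Track, TrackSet

__all__ = [
    "write_image_stack",
    "read_image_stack",
    "write_mask",
    "read_mask",
    "write_table",
    "read_tracks_csv",
    "write_tracks_csv",
]

FLOAT_FORMAT = "%.6f"
TRACK_COLUMNS = ("track_id", "frame", "time_s", "x_um", "y_um")


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multichannel stack as ZCYX uint16 TIFF (CYX for 2D)."""
    names = sorted(stack.channels)
    arrs = [stack.channels[n] for n in names]
    data = np.stack(arrs, axis=-3 if arrs[0].ndim == 3 else 0)
    data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "channel_names": names,
            "voxel_size_nm": list(stack.voxel_size),
        },
    )


def read_image_stack(
    path: str | Path,
    channel_names: list[str] | None = None,
    voxel_size: tuple[float, ...] | None = None,
) -> ImageStack:
    """Read a ZCYX (or CYX) TIFF back into an ImageStack.

    Channel names and voxel size are recovered from the TIFF metadata when
    present, otherwise they must be supplied.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = channel_names or meta.get("channel_names")
    vs = voxel_size or meta.get("voxel_size_nm")
    if names is None or vs is None:
        raise ValueError(f"{path}: channel names / voxel size not in metadata")
    axis = -3 if data.ndim == 4 else 0
    channels = {n: np.take(data, i, axis=axis).astype(np.float64)
                for i, n in enumerate(names)}
    return ImageStack(channels=channels, voxel_size=tuple(vs))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.int32))


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from imageio.v3 import imread

        return np.asarray(imread(path)).astype(np.int32)
    return tifffile.imread(path).astype(np.int32)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Deterministic CSV output (fixed float format, no index)."""
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_tracks_csv(path: str | Path, trackset: TrackSet) -> None:
    write_table(path, trackset.to_frame())


def read_tracks_csv(
    path: str | Path,
    dt: float,
    column_map: Mapping[str, str] | None = None,
) -> TrackSet:
    """Load a track table; ``column_map`` translates foreign headers to the
    canonical ``track_id, frame, time_s, x_um, y_um`` (time_s optional — it is
    rebuilt from frame * dt when absent)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = {"track_id", "frame", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    if "time_s" not in df.columns:
        df["time_s"] = df["frame"] * dt
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                times=grp["time_s"].to_numpy(),
                positions=grp[["x_um", "y_um"]].to_numpy(),
            )
        )
    return TrackSet(tracks=tracks, dt=dt, meta={"source": str(path)})
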