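"""Reading and writing of image stacks, spot tables and label volumes.

Stacks go through OME-TIFF so voxel sizes travel with the pixels; loading a
plain TIFF without calibration requires an explicit ``voxel_size`` override —
there is no silent 1-µm default.  Spot tables are plain CSV with a fixed
header so results diff cleanly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import ImageStack, LabelVolume

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "SPOT_COLUMNS",
    "CATEGORIES",
    "new_spot_table",
    "validate_spot_table",
    "write_spot_table",
    "read_spot_table",
]

#: Fixed spot-table schema.  Coordinates are physical (µm); ``z_um`` is NaN
#: for spots detected on 2D projections.
SPOT_COLUMNS = [
    "spot_id",
    "channel",
    "z_um",
    "y_um",
    "x_um",
    "peak_intensity",
    "integrated_intensity",
    "category",
    "membrane_distance_um",
    "source_image",
]

CATEGORIES = ("unassigned", "nuclear_pore", "plasma_membrane", "cytosol")


# ---------------------------------------------------------------------------
# stacks

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an OME-TIFF carrying the voxel calibration."""
    path = Path(path)
    meta: dict = {"axes": stack.axes}
    names = [a for a in stack.axes if a in "ZYX"]
    for name, size in zip(names, stack.voxel_size):
        meta[f"PhysicalSize{name}"] = size
        meta[f"PhysicalSize{name}Unit"] = "µm"
    if stack.frame_interval is not None:
        meta["TimeIncrement"] = stack.frame_interval
        meta["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, stack.data, ome=True, metadata=meta)


def _ome_voxel_size(ome_xml: str, axes: str) -> tuple[float, ...] | None:
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None
    out = []
    for a in axes:
        if a not in "ZYX":
            continue
        v = pixels.get(f"PhysicalSize{a}")
        if v is None:
            return None
        out.append(float(v))
    return tuple(out)


def read_stack(
    path: str | Path, voxel_size: tuple[float, ...] | None = None
) -> ImageStack:
    """Load a TIFF/OME-TIFF into canonical axis order.

    ``voxel_size`` overrides (or supplies, for plain TIFF) the µm spacing.
    A plain TIFF without calibration and without an override is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "Z")
        if not tf.ome_metadata:
            # plain TIFF: a 3D page stack is a z-stack, not channels
            if data.ndim == 3:
                axes = "ZYX"
            elif data.ndim == 2:
                axes = "YX"
        frame_interval = None
        file_voxel = None
        if tf.ome_metadata:
            file_voxel = _ome_voxel_size(tf.ome_metadata, axes)
            root = ET.fromstring(tf.ome_metadata)
            ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
            pix = root.find(f".//{ns}Pixels")
            if pix is not None and pix.get("TimeIncrement"):
                frame_interval = float(pix.get("TimeIncrement"))

    # canonicalize axis order to a subsequence of TCZYX
    order = [axes.index(a) for a in "TCZYX" if a in axes]
    if sorted(order) != order:
        data = np.moveaxis(data, order, range(len(order)))
        axes = "".join(a for a in "TCZYX" if a in axes)
    if voxel_size is not None:
        vs = tuple(float(v) for v in voxel_size)
    elif file_voxel is not None:
        vs = file_voxel
    else:
        raise ValueError(
            f"{path}: no voxel calibration in file; pass voxel_size= "
            "explicitly (µm per spatial axis)"
        )
    n_spatial = sum(1 for a in axes if a in "ZYX")
    if len(vs) != n_spatial:
        raise ValueError(
            f"{path}: voxel_size needs {n_spatial} entries for axes {axes}"
        )
    return ImageStack(data, vs, frame_interval=frame_interval, axes=axes)


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    write_stack(
        ImageStack(labels.labels.astype(np.int32), labels.voxel_size), path
    )


def read_labels(
    path: str | Path, voxel_size: tuple[float, ...] | None = None
) -> LabelVolume:
    st = read_stack(path, voxel_size=voxel_size)
    return LabelVolume(st.data.astype(np.int64), st.voxel_size)


# ---------------------------------------------------------------------------
# spot tables

def new_spot_table(
    centers_um: np.ndarray | None = None,
    *,
    channel: int = 0,
    peak_intensity=None,
    integrated_intensity=None,
    source_image: str = "",
) -> pd.DataFrame:
    """Build a schema-conforming spot table from per-spot arrays."""
    if centers_um is None or len(centers_um) == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    centers = np.atleast_2d(np.asarray(centers_um, dtype=float))
    n = len(centers)
    if centers.shape[1] == 2:  # (y, x) from a projection
        z = np.full(n, np.nan)
        y, x = centers[:, 0], centers[:, 1]
    else:
        z, y, x = centers[:, 0], centers[:, 1], centers[:, 2]
    df = pd.DataFrame(
        {
            "spot_id": np.arange(n),
            "channel": channel,
            "z_um": z,
            "y_um": y,
            "x_um": x,
            "peak_intensity": (
                np.zeros(n) if peak_intensity is None else peak_intensity
            ),
            "integrated_intensity": (
                np.zeros(n)
                if integrated_intensity is None
                else integrated_intensity
            ),
            "category": "unassigned",
            "membrane_distance_um": np.nan,
            "source_image": source_image,
        }
    )
    return df[SPOT_COLUMNS]


def validate_spot_table(spots: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    if len(spots) == 0:
        return
    if spots["spot_id"].duplicated().any():
        raise ValueError("spot ids must be unique within a table")
    if (spots["integrated_intensity"] < 0).any():
        raise ValueError("integrated_intensity must be nonnegative")
    bad = ~spots["category"].isin(CATEGORIES)
    if bad.any() or spots["category"].isna().any():
        raise ValueError(
            f"invalid spot categories: {spots.loc[bad, 'category'].unique()}"
        )


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    validate_spot_table(spots)
    spots[SPOT_COLUMNS].to_csv(path, index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"category": str, "source_image": str}, keep_default_na=True
    )
    if list(df.columns) != SPOT_COLUMNS:
        raise ValueError(
            f"{path}: header does not match spot-table schema {SPOT_COLUMNS}"
        )
    if len(df):
        df["source_image"] = df["source_image"].fillna("")
    validate_spot_table(df)
    return df
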