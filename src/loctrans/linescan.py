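"""Line-scan intensity profiles and apical/cytoplasmic enrichment ratios.

A line scan samples the image along a line perpendicular to a membrane,
averaged across a configurable width in pixels; its peak is the apical
intensity readout.  Enrichment ratios are (apical - background) /
(cytoplasm - background) from three scans / regions each, which makes the
ratio invariant to the detector gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .stack import ImageStack

__all__ = [
    "LineScan",
    "RatioResult",
    "line_scan",
    "region_mean",
    "enrichment_ratio",
    "per_cell_ratio_report",
]


@dataclass
class LineScan:
    anchor_um: tuple[float, float]
    direction: tuple[float, float]
    length_um: float
    width_px: int
    positions_um: np.ndarray
    profile: np.ndarray

    @property
    def peak_value(self) -> float:
        return float(self.profile.max())


def line_scan(
    image: ImageStack,
    anchor_um: tuple[float, float],
    direction: tuple[float, float],
    length_um: float,
    width_px: int = 1,
) -> LineScan:
    """Width-averaged intensity profile along a line.

    The profile is sampled every (smallest) pixel with linear interpolation
    and averaged over ``width_px`` parallel offsets perpendicular to the
    line.  The scan must lie fully inside the image.
    """
    if image.data.ndim != 2:
        raise ValueError("line_scan expects a 2D image")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    vs = np.asarray(image.voxel_size, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    d = d / norm
    perp = np.array([-d[1], d[0]])
    step = float(vs.min())
    n = int(np.ceil(length_um / step)) + 1
    pos = np.arange(n) * step
    anchor = np.asarray(anchor_um, dtype=float)
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * step
    # (n, width, 2) physical sample points
    pts = (
        anchor[None, None, :]
        + pos[:, None, None] * d[None, None, :]
        + offsets[None, :, None] * perp[None, None, :]
    )
    coords = (pts / vs).reshape(-1, 2).T
    shape = np.asarray(image.data.shape)
    if (coords.min(axis=1) < 0).any() or (coords.max(axis=1) > shape - 1).any():
        raise ValueError("line scan exits the image")
    samples = map_coordinates(
        image.data.astype(float), coords, order=1
    ).reshape(n, width_px)
    profile = samples.mean(axis=1)
    return LineScan(
        anchor_um=tuple(anchor),
        direction=tuple(d),
        length_um=float(length_um),
        width_px=width_px,
        positions_um=pos,
        profile=profile,
    )


def region_mean(image: ImageStack, box_px: tuple[slice, slice]) -> float:
    """Mean intensity over a rectangular region (pixel slices)."""
    return float(image.data[box_px].mean())


@dataclass
class RatioResult:
    apical_mean: float
    cyto_mean: float
    background_mean: float
    ratio: float
    valid: bool = True


def enrichment_ratio(
    apical_peaks: list[float],
    cyto_means: list[float],
    background_means: list[float] | None = None,
) -> RatioResult:
    """(mean apical - mean background) / (mean cyto - mean background).

    Background defaults to zero when no outside regions are given.  A
    nonpositive denominator flags the ratio as undefined rather than
    producing a misleading number.
    """
    apical = float(np.mean(apical_peaks))
    cyto = float(np.mean(cyto_means))
    bg = float(np.mean(background_means)) if background_means else 0.0
    denom = cyto - bg
    if denom <= 0:
        return RatioResult(apical, cyto, bg, np.nan, valid=False)
    return RatioResult(apical, cyto, bg, (apical - bg) / denom)


def per_cell_ratio_report(
    cells: dict[str, dict | None],
) -> pd.DataFrame:
    """One enrichment ratio per named cell plus the per-animal mean.

    ``cells`` maps a cell name (e.g. ``"2R"``) to
    ``{"apical": [...], "cyto": [...], "background": [...] | None}``;
    a ``None`` entry means the ROI was missing and is reported as such,
    never imputed.
    """
    rows = []
    for name, grp in cells.items():
        if grp is None:
            rows.append(
                {"cell": name, "ratio": np.nan, "status": "missing"}
            )
            continue
        res = enrichment_ratio(
            grp["apical"], grp["cyto"], grp.get("background")
        )
        rows.append(
            {
                "cell": name,
                "apical_mean": res.apical_mean,
                "cyto_mean": res.cyto_mean,
                "background_mean": res.background_mean,
                "ratio": res.ratio,
                "status": "ok" if res.valid else "undefined",
            }
        )
    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"]
    mean_row = {
        "cell": "animal_mean",
        "ratio": ok["ratio"].mean() if len(ok) else np.nan,
        "status": "summary",
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
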