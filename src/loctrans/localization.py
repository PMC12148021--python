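"""Membrane-proximity statistics, the z-flip randomized null, and spot
categorization for re-localization efficiency.

The proximity statistic is the fraction of translation spots whose 3D
distance to the nearest membrane lies within a closed band (default
0-0.35 µm).  Its null control reverses only the spot channel along the
optical axis and re-runs the identical detection + distance pipeline, which
destroys spot-membrane registration while keeping the spot distribution's
envelope inside the embryo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import DistanceMap, ImageStack

__all__ = [
    "ProximityResult",
    "spot_membrane_distances",
    "proximity_fraction",
    "zflip_null",
    "categorize_spots",
    "relocalization_report",
]


@dataclass
class ProximityResult:
    n_spots: int
    n_within: int
    fraction_within: float
    cutoff_um: float
    condition: str = "observed"

    def __post_init__(self) -> None:
        if not 0 <= self.n_within <= self.n_spots:
            raise ValueError("n_within must be in [0, n_spots]")


def spot_membrane_distances(
    spots: pd.DataFrame, dmap: DistanceMap
) -> pd.DataFrame:
    """Fill ``membrane_distance_um`` by sampling the distance map
    (trilinear) at each spot centre.  Spots outside the map raise."""
    out = spots.copy()
    if len(out) == 0:
        return out
    cols = ["z_um", "y_um", "x_um"] if dmap.distances.ndim == 3 else ["y_um", "x_um"]
    pts = out[cols].to_numpy(dtype=float)
    if np.isnan(pts).any():
        raise ValueError("spot centres contain NaN for the map's axes")
    out["membrane_distance_um"] = dmap.sample(pts)
    return out


def proximity_fraction(
    spots: pd.DataFrame, cutoff_um: float = 0.35, condition: str = "observed"
) -> ProximityResult:
    """Fraction of spots within the closed band [0, cutoff] of the membrane."""
    if len(spots) == 0:
        raise ValueError("no spots: proximity fraction undefined")
    d = spots["membrane_distance_um"].to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("membrane distances missing; run spot_membrane_distances")
    n_within = int((d <= cutoff_um).sum())
    return ProximityResult(
        n_spots=len(d),
        n_within=n_within,
        fraction_within=n_within / len(d),
        cutoff_um=float(cutoff_um),
        condition=condition,
    )


def zflip_null(spot_channel: ImageStack) -> ImageStack:
    """Reverse the spot channel along z (membrane channel stays fixed).

    An involution that preserves total intensity; the caller re-runs the
    exact same detection + distance pipeline on the flipped channel.
    """
    if not spot_channel.is_3d or spot_channel.data.ndim != 3:
        raise ValueError("zflip_null expects a single-channel 3D stack")
    return spot_channel.with_data(spot_channel.data[::-1].copy())


def categorize_spots(
    spots: pd.DataFrame,
    dmap_membrane: DistanceMap,
    dmap_nuclear: DistanceMap | None,
    cutoff_um: float = 0.35,
    exclusion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign nuclear_pore / plasma_membrane / cytosol by distance rule.

    A spot within ``cutoff_um`` of the nuclear surface is ``nuclear_pore``;
    otherwise within the cutoff of the membrane it is ``plasma_membrane``;
    otherwise ``cytosol``.  Without a nuclear map only the membrane/cytosol
    split is made.  Spots inside an exclusion mask (e.g. mitotic cells) are
    dropped.
    """
    out = spots.copy()
    if len(out) == 0:
        return out
    cols = ["z_um", "y_um", "x_um"] if dmap_membrane.distances.ndim == 3 else ["y_um", "x_um"]
    pts = out[cols].to_numpy(dtype=float)
    if exclusion is not None and exclusion.any():
        vox = np.round(
            pts / np.asarray(dmap_membrane.voxel_size)
        ).astype(int)
        vox = np.clip(vox, 0, np.asarray(exclusion.shape) - 1)
        drop = exclusion[tuple(vox.T)]
        out = out[~drop].reset_index(drop=True)
        pts = pts[~drop]
        if len(out) == 0:
            return out
    d_mem = dmap_membrane.sample(pts)
    if dmap_nuclear is not None:
        d_nuc = dmap_nuclear.sample(pts)
        cat = np.where(
            d_nuc <= cutoff_um,
            "nuclear_pore",
            np.where(d_mem <= cutoff_um, "plasma_membrane", "cytosol"),
        )
    else:
        cat = np.where(d_mem <= cutoff_um, "plasma_membrane", "cytosol")
    out["category"] = cat
    out["membrane_distance_um"] = d_mem
    return out


def relocalization_report(
    per_embryo: dict[str, pd.DataFrame], min_spots: int = 7
) -> pd.DataFrame:
    """Per-embryo category percentages plus a mean +/- s.d. summary row.

    Embryos with ``min_spots`` or fewer categorized spots fail the strict
    inclusion rule; they are listed with ``included=False`` and left out of
    the summary statistics.
    """
    cats = ["nuclear_pore", "plasma_membrane", "cytosol"]
    rows = []
    for name, spots in per_embryo.items():
        n = len(spots)
        counts = spots["category"].value_counts() if n else {}
        row = {"embryo": name, "n_spots": n, "included": n > min_spots}
        for c in cats:
            row[f"pct_{c}"] = 100.0 * counts.get(c, 0) / n if n else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    inc = df[df["included"]]
    summary = {"embryo": "mean±sd", "n_spots": int(inc["n_spots"].sum()),
               "included": True}
    for c in cats:
        summary[f"pct_{c}"] = inc[f"pct_{c}"].mean() if len(inc) else np.nan
        summary[f"sd_{c}"] = inc[f"pct_{c}"].std(ddof=1) if len(inc) > 1 else np.nan
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
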