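"""Object-based two-channel colocalization.

Spots are matched across channels by mutual nearest neighbours within a
physical radius, conflicts resolved greedily by ascending offset with a
deterministic (offset, idA, idB) tie-break.  The overlap fraction is
asymmetric, as in the assay it implements: matched translation spots over
all translation spots.  The same matcher estimates per-channel probe
detection efficiency from dual-probe labellings of the same mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "MatchResult",
    "match_spots",
    "translation_overlap",
    "probe_efficiency",
]

_COORDS = ["z_um", "y_um", "x_um"]


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: id_a, id_b, offset_um
    n_a: int
    n_b: int
    match_radius_um: float

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def overlap_fraction_a(self) -> float:
        return self.n_matched / self.n_a if self.n_a else np.nan

    @property
    def overlap_fraction_b(self) -> float:
        return self.n_matched / self.n_b if self.n_b else np.nan


def _points(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in _COORDS if c in table.columns]
    pts = table[cols].to_numpy(dtype=float)
    keep = ~np.isnan(pts).all(axis=0)
    return pts[:, keep] if pts.size else pts


def match_spots(
    table_a: pd.DataFrame, table_b: pd.DataFrame, radius_um: float
) -> MatchResult:
    """One-to-one mutual-nearest-neighbour matching within ``radius_um``."""
    if radius_um < 0:
        raise ValueError("match radius must be >= 0")
    n_a, n_b = len(table_a), len(table_b)
    if n_a == 0 or n_b == 0:
        return MatchResult(
            pd.DataFrame(columns=["id_a", "id_b", "offset_um"]),
            n_a, n_b, radius_um,
        )
    pa, pb = _points(table_a), _points(table_b)
    if pa.shape[1] != pb.shape[1]:
        raise ValueError("tables are not in the same coordinate frame")
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab, j_ab = tb.query(pa)           # nearest b for each a
    d_ba, j_ba = ta.query(pb)           # nearest a for each b
    ids_a = table_a["spot_id"].to_numpy()
    ids_b = table_b["spot_id"].to_numpy()
    cand = [
        (float(d_ab[i]), ids_a[i], ids_b[j_ab[i]], i, int(j_ab[i]))
        for i in range(n_a)
        if d_ab[i] <= radius_um and j_ba[j_ab[i]] == i
    ]
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for off, ida, idb, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append({"id_a": ida, "id_b": idb, "offset_um": off})
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "offset_um"])
    return MatchResult(pairs, n_a, n_b, radius_um)


def translation_overlap(
    translation: pd.DataFrame,
    mrna: pd.DataFrame,
    radius_um: float,
    min_translation_spots: int = 3,
) -> dict:
    """Fraction of translation spots that coincide with an mRNA spot.

    The translation table must already be intensity-gated.  Embryos with
    ``min_translation_spots`` or fewer translation spots are excluded
    (reported, not computed).
    """
    n_t = len(translation)
    if n_t <= min_translation_spots:
        return {
            "included": False,
            "n_translation": n_t,
            "rule": f"n > {min_translation_spots}",
            "overlap_fraction": np.nan,
        }
    if len(mrna) == 0:
        return {
            "included": True,
            "n_translation": n_t,
            "n_matched": 0,
            "overlap_fraction": 0.0,
        }
    m = match_spots(translation, mrna, radius_um)
    return {
        "included": True,
        "n_translation": n_t,
        "n_matched": m.n_matched,
        "overlap_fraction": m.overlap_fraction_a,
    }


def probe_efficiency(
    table_p1: pd.DataFrame, table_p2: pd.DataFrame, radius_um: float
) -> dict:
    """Per-channel probe-binding efficiency from a dual-probe labelling.

    Both tables must already be gated as mRNA spots.  The efficiency of a
    channel is the number of cross-channel matches divided by that
    channel's spot count; an empty channel gives an undefined (NaN)
    efficiency and is flagged.
    """
    m = match_spots(table_p1, table_p2, radius_um)
    return {
        "n_channel1": m.n_a,
        "n_channel2": m.n_b,
        "n_matched": m.n_matched,
        "efficiency_channel1": m.overlap_fraction_a,
        "efficiency_channel2": m.overlap_fraction_b,
        "valid": m.n_a > 0 and m.n_b > 0,
    }
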