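"""Core in-memory containers shared by every pipeline stage.

All physical coordinates are micrometres (µm).  Voxel index ``i`` along an
axis with spacing ``s`` maps to the physical position ``i * s`` at the voxel
centre (0-based indices).  Distances reported anywhere in the package are
therefore centre-to-centre distances in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ImageStack", "LabelVolume", "DistanceMap"]


@dataclass
class ImageStack:
    """An n-D intensity grid with physical calibration.

    Parameters
    ----------
    data
        Intensity array.  Spatial axes are the trailing axes in canonical
        (z, y, x) order; 2D images are (y, x).  A leading time axis is
        allowed for time series (axes ``"TYX"`` etc.).
    voxel_size
        µm per spatial axis, same order and length as the spatial axes of
        ``data``.  Strictly positive.
    frame_interval
        Seconds between frames when a time axis is present.
    axes
        Axis labels, e.g. ``"ZYX"``, ``"YX"``, ``"TYX"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...]
    frame_interval: float | None = None
    axes: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if not self.axes:
            self.axes = {2: "YX", 3: "ZYX", 4: "TZYX"}.get(self.data.ndim, "")
        n_spatial = sum(1 for a in self.axes if a in "ZYX")
        if n_spatial == 0:
            raise ValueError("ImageStack requires at least one spatial axis")
        if len(self.voxel_size) != n_spatial:
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for "
                f"{n_spatial} spatial axes"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if len(self.axes) != self.data.ndim:
            raise ValueError(
                f"axes {self.axes!r} does not match data ndim {self.data.ndim}"
            )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        spatial = [i for i, a in enumerate(self.axes) if a in "ZYX"]
        return tuple(self.data.shape[i] for i in spatial)

    @property
    def is_3d(self) -> bool:
        return "Z" in self.axes

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Same calibration, new intensities (shape must be unchanged)."""
        if data.shape != self.data.shape:
            raise ValueError("with_data requires an identically shaped array")
        return replace(self, data=data)

    def physical_extent(self) -> tuple[float, ...]:
        return tuple(
            s * n for s, n in zip(self.voxel_size, self.spatial_shape)
        )


@dataclass
class LabelVolume:
    """Integer cell segmentation on an :class:`ImageStack` grid.

    Label 0 means outside the embryo; labels >= 1 are cells.  The membrane
    ("boundary set") is the set of voxels inside a nonzero label that touch
    a voxel with a different label (including 0).
    """

    labels: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.labels.ndim:
            raise ValueError("voxel_size must have one entry per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def boundary_mask(self) -> np.ndarray:
        """Voxels inside a nonzero label adjacent (face-connected) to a
        different label or to the outside."""
        from skimage.segmentation import find_boundaries

        inner = find_boundaries(self.labels, mode="inner", connectivity=1)
        return inner & (self.labels > 0)

    def relabel_contiguous(self) -> "LabelVolume":
        vals = np.unique(self.labels)
        lut = np.zeros(vals.max() + 1, dtype=self.labels.dtype)
        nz = vals[vals > 0]
        lut[nz] = np.arange(1, len(nz) + 1)
        return LabelVolume(lut[self.labels], self.voxel_size)


@dataclass
class DistanceMap:
    """Per-voxel Euclidean distance (µm) to the nearest membrane voxel,
    respecting anisotropic voxel sizes.  Zero exactly on boundary voxels."""

    distances: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if (self.distances < 0).any():
            raise ValueError("distances must be nonnegative")

    def sample(self, centers_um: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the map at physical positions.

        Parameters
        ----------
        centers_um
            (n, ndim) array of points in µm, canonical axis order.
        """
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(centers_um, dtype=float))
        if pts.shape[1] != self.distances.ndim:
            raise ValueError("points dimensionality does not match map")
        coords = (pts / np.asarray(self.voxel_size)).T
        shape = np.asarray(self.distances.shape)
        if (coords.min(axis=1) < -0.5).any() or (
            coords.max(axis=1) > shape - 0.5
        ).any():
            raise ValueError("point outside the distance map")
        return map_coordinates(self.distances, coords, order=1, mode="nearest")
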