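"""Synthetic embryo scenes with ground truth.

The generator emulates the statistical structure the analysis assumes: a
membrane-marker channel outlining tightly packed cells inside an ellipsoidal
embryo, a spot channel with bright translation spots and dim mature-protein
spots, dual-channel mRNA scenes with controllable detection efficiency and
true overlap, line-scan fixtures with known enrichment ratios, and
photobleaching-recovery traces with known kinetics.  Every scene records
full ground truth (exact centres, classes, membrane distances, pairings,
kinetic parameters) so each pipeline stage can be tested as a
parameter-recovery problem.

Intensities are arbitrary detector units (ADU); the camera noise model is
Poisson-Gaussian and off by default so that closed-form checks are exact.
Determinism: identical seeds give voxel-identical images and identical
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .frap import FrapTrace
from .stack import ImageStack, LabelVolume

__all__ = [
    "NoiseParams",
    "EmbryoGeometry",
    "SpotPlacementParams",
    "ColocParams",
    "FrapSimParams",
    "GroundTruth",
    "generate_embryo",
    "place_and_render_spots",
    "generate_coloc_pair",
    "simulate_frap",
    "generate_linescan_image",
    "render_gaussian_spots",
]


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseParams(_Params):
    """Poisson-Gaussian camera model: shot noise at ``gain`` photons/ADU
    plus additive Gaussian read noise."""

    gain: float = Field(1.0, gt=0)
    read_sd: float = Field(0.0, ge=0)

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = rng.poisson(np.clip(img, 0, None) * self.gain) / self.gain
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, img.shape)
        return out


class EmbryoGeometry(_Params):
    """Scene geometry for one embryo.

    The embryo is an ellipsoid (centre and semi-axes in µm) containing
    ``n_cells`` cells produced by a seeded Voronoi tessellation.  With
    ``z_symmetric`` the cell seeds are mirrored about the stack's z
    mid-plane, giving a label volume invariant under a z-flip — the
    geometry used to validate the randomized control.
    """

    volume_shape: tuple[int, int, int] = (32, 96, 96)
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1)
    center_um: Optional[tuple[float, float, float]] = None
    semi_axes_um: Optional[tuple[float, float, float]] = None
    n_cells: int = Field(16, ge=1)
    membrane_intensity: float = Field(600.0, gt=0)
    background_level: float = Field(100.0, ge=0)
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.13, 0.13)
    noise: Optional[NoiseParams] = None
    z_symmetric: bool = False
    seed: int = 0

    def resolved_ellipsoid(self):
        extent = np.asarray(self.volume_shape) * np.asarray(self.voxel_size)
        if self.center_um is not None:
            center = np.asarray(self.center_um, dtype=float)
        else:
            center = extent / 2.0
            if self.z_symmetric:
                # a z-flip of the voxel grid reflects about (N-1)/2 voxels
                center[0] = (self.volume_shape[0] - 1) / 2.0 * self.voxel_size[0]
        semi = (
            np.asarray(self.semi_axes_um)
            if self.semi_axes_um is not None
            else extent * 0.42
        )
        if (semi <= 0).any():
            raise ValueError("ellipsoid semi-axes must be > 0")
        return center, semi


class SpotPlacementParams(_Params):
    """Placement and rendering of translation / mature-protein spots.

    ``p_membrane`` is the probability that a spot is drawn uniformly from
    the membrane-proximal band (distance <= ``band_width_um`` of the
    nearest membrane voxel); the rest are drawn uniformly from the interior
    beyond the band.  ``p_membrane=None`` places spots uniformly over the
    whole cell interior regardless of the band.  Amplitudes are lognormal,
    bright ("translation") with probability ``frac_bright``, else dim
    ("mature").
    """

    n_spots: int = Field(200, ge=0)
    p_membrane: Optional[float] = Field(0.5, ge=0, le=1)
    band_width_um: float = Field(0.35, gt=0)
    frac_bright: float = Field(1.0, ge=0, le=1)
    amplitude_bright: float = Field(400.0, gt=0)  # lognormal median, ADU
    amplitude_dim: float = Field(40.0, gt=0)
    amplitude_sigma: float = Field(0.3, ge=0)     # lognormal sigma (log-space)
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.13, 0.13)
    background_level: float = Field(100.0, ge=0)
    noise: Optional[NoiseParams] = None
    seed: int = 0


class ColocParams(_Params):
    """Two-channel mRNA / partner-spot scene.

    Each of ``n_mrna`` molecules appears in channel 1 with probability
    ``detection_efficiency[0]``; with probability ``true_overlap_fraction``
    it carries a partner spot, offset by at most ``max_pairing_offset_um``,
    which appears in channel 2 with probability ``detection_efficiency[1]``.
    """

    n_mrna: int = Field(500, ge=0)
    true_overlap_fraction: float = Field(1.0, ge=0, le=1)
    detection_efficiency: tuple[float, float] = (1.0, 1.0)
    max_pairing_offset_um: float = Field(0.1, ge=0)
    amplitude: float = Field(400.0, gt=0)
    amplitude_sigma: float = Field(0.3, ge=0)
    psf_sigma_um: tuple[float, float, float] = (0.35, 0.13, 0.13)
    background_level: float = Field(100.0, ge=0)
    noise: Optional[NoiseParams] = None
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if not all(0 <= e <= 1 for e in self.detection_efficiency):
            raise ValueError("detection efficiencies must be in [0, 1]")


class FrapSimParams(_Params):
    """Single-exponential recovery with acquisition bleaching and background.

    The bleached-region signal drops by ``bleach_depth`` at t=0 and recovers
    as ``mobile_fraction * (1 - exp(-t ln2 / half_time))`` of the bleached
    amount.  Every frame of both regions decays by
    ``acquisition_bleach_rate`` per frame; a constant background is added.
    """

    mobile_fraction: float = Field(0.6, ge=0, le=1)
    half_time_s: float = Field(120.0, gt=0)
    bleach_depth: float = Field(0.8, gt=0, le=1)
    acquisition_bleach_rate: float = Field(1.0, gt=0, le=1)
    background_level: float = Field(50.0, ge=0)
    prebleach_intensity: float = Field(1000.0, gt=0)
    reference_intensity: float = Field(1000.0, gt=0)
    frame_interval_s: float = Field(20.0, gt=0)
    n_prebleach_frames: int = Field(5, ge=1)
    duration_s: float = Field(1200.0, gt=0)
    noise_sd: float = Field(0.0, ge=0)
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if self.duration_s < self.frame_interval_s:
            raise ValueError("duration must cover at least one frame")


@dataclass
class GroundTruth:
    """What the generator actually put into a scene.

    ``spots`` has one row per *rendered* spot: id, channel, class
    (translation | mature | mrna), exact centre (µm), amplitude, true
    membrane distance (µm, centre to nearest membrane-voxel centre) and
    ``pair_id`` linking cross-channel partners (-1 if unpaired).
    """

    spots: pd.DataFrame
    kinetic_params: dict = field(default_factory=dict)
    time_s: np.ndarray | None = None
    recovery_fraction: np.ndarray | None = None      # of the bleached amount
    normalized_prebleach: np.ndarray | None = None   # of the pre-bleach level

    def pairings(self) -> list[tuple[int, int]]:
        """(channel-1 id, channel-2 id) for pairs rendered in both channels."""
        if len(self.spots) == 0:
            return []
        ch1 = self.spots[(self.spots.channel == 1) & (self.spots.pair_id >= 0)]
        ch2 = self.spots[(self.spots.channel == 2) & (self.spots.pair_id >= 0)]
        common = np.intersect1d(ch1.pair_id.values, ch2.pair_id.values)
        id1 = ch1.set_index("pair_id").spot_id
        id2 = ch2.set_index("pair_id").spot_id
        return [(int(id1[p]), int(id2[p])) for p in common]

    def to_csv(self, path) -> None:
        self.spots.to_csv(path, index=False)


_SPOT_GT_COLS = [
    "spot_id", "channel", "class", "z_um", "y_um", "x_um",
    "amplitude", "membrane_distance_um", "pair_id",
]


def _gt_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=_SPOT_GT_COLS)
    return pd.DataFrame(rows)[_SPOT_GT_COLS]


# ---------------------------------------------------------------------------
# embryo + labels

def _voxel_centers_um(shape, voxel_size):
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(shape, voxel_size)], indexing="ij"
    )
    return grids


def generate_embryo(
    geometry: EmbryoGeometry,
) -> tuple[ImageStack, LabelVolume, np.ndarray]:
    """Render a membrane channel, cell labels and the embryo mask.

    Cells are the Voronoi regions of ``n_cells`` seed points drawn uniformly
    inside the embryo ellipsoid (physical metric, so anisotropic voxels are
    respected).  The membrane channel is bright on the inter-cell /
    embryo-surface boundary voxels, blurred by the PSF and optionally
    corrupted by the camera noise model.
    """
    rng = np.random.default_rng(geometry.seed)
    shape = tuple(geometry.volume_shape)
    vs = np.asarray(geometry.voxel_size)
    center, semi = geometry.resolved_ellipsoid()

    grids = _voxel_centers_um(shape, geometry.voxel_size)
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    mask = r2 <= 1.0
    n_in = int(mask.sum())
    if n_in < geometry.n_cells * 32:
        raise ValueError(
            f"volume too small: {n_in} embryo voxels cannot hold "
            f"{geometry.n_cells} cells"
        )

    # seed points uniform in the ellipsoid (mirrored in z if requested)
    def _draw(n):
        pts = []
        while len(pts) < n:
            u = rng.uniform(-1, 1, size=(max(8, 2 * n), 3))
            keep = (u**2).sum(axis=1) <= 1.0
            pts.extend((u[keep] * semi + center).tolist())
        return np.asarray(pts[:n])

    z_extent = shape[0] * vs[0]
    if geometry.z_symmetric:
        half = _draw((geometry.n_cells + 1) // 2)
        mirrored = half.copy()
        mirrored[:, 0] = z_extent - vs[0] - mirrored[:, 0]
        seeds = np.vstack([half, mirrored])[: geometry.n_cells]
        if geometry.n_cells % 2 == 1:
            seeds[-1, 0] = (z_extent - vs[0]) / 2.0
    else:
        seeds = _draw(geometry.n_cells)

    if geometry.n_cells == 1:
        labels = mask.astype(np.int64)
    else:
        tree = cKDTree(seeds)
        pts = np.stack([g[mask] for g in grids], axis=1)
        _, owner = tree.query(pts)
        labels = np.zeros(shape, dtype=np.int64)
        labels[mask] = owner + 1

    vol = LabelVolume(labels, geometry.voxel_size).relabel_contiguous()
    boundary = vol.boundary_mask()
    img = np.full(shape, float(geometry.background_level))
    img[boundary] += geometry.membrane_intensity
    if any(s > 0 for s in geometry.psf_sigma_um):
        img = ndi.gaussian_filter(
            img, sigma=np.asarray(geometry.psf_sigma_um) / vs, mode="nearest"
        )
    if geometry.noise is not None:
        img = geometry.noise.apply(img, rng)
    return ImageStack(img, geometry.voxel_size), vol, mask


# ---------------------------------------------------------------------------
# spot rendering

def render_gaussian_spots(
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
    centers_um: np.ndarray,
    amplitudes: np.ndarray,
    psf_sigma_um: tuple[float, ...],
    background: float = 0.0,
) -> np.ndarray:
    """Additively render anisotropic Gaussian spots at continuous centres.

    Each spot is ``A * exp(-sum((x - c)^2 / 2 sigma^2))`` evaluated at voxel
    centres, truncated at 5 sigma.
    """
    img = np.full(shape, float(background))
    centers = np.atleast_2d(np.asarray(centers_um, dtype=float))
    if centers.size == 0:
        return img
    vs = np.asarray(voxel_size, dtype=float)
    sig = np.asarray(psf_sigma_um, dtype=float)
    half = np.ceil(5.0 * sig / vs).astype(int)
    for c, amp in zip(centers, np.broadcast_to(amplitudes, (len(centers),))):
        cv = c / vs
        lo = np.maximum(np.floor(cv).astype(int) - half, 0)
        hi = np.minimum(np.floor(cv).astype(int) + half + 1, shape)
        if (hi <= lo).any():
            continue
        axes = [
            np.exp(
                -((np.arange(a, b) * v - cc) ** 2) / (2.0 * s**2)
            )
            for a, b, v, cc, s in zip(lo, hi, vs, c, sig)
        ]
        prof = amp * np.einsum("i,j,k->ijk", *axes) if len(axes) == 3 else (
            amp * np.outer(axes[0], axes[1])
        )
        img[tuple(slice(a, b) for a, b in zip(lo, hi))] += prof
    return img


def true_integrated_intensity(
    amplitude: float,
    psf_sigma_um: tuple[float, ...],
    voxel_size: tuple[float, ...],
) -> float:
    """Analytic voxel-sum of a rendered Gaussian spot (background-free)."""
    sig = np.asarray(psf_sigma_um) / np.asarray(voxel_size)
    return float(amplitude * np.prod(np.sqrt(2 * np.pi) * sig))


def _membrane_tree(labels: LabelVolume) -> tuple[cKDTree, np.ndarray]:
    boundary = labels.boundary_mask()
    if not boundary.any():
        raise ValueError("label volume has no membrane voxels")
    vs = np.asarray(labels.voxel_size)
    pts = np.argwhere(boundary) * vs
    return cKDTree(pts), boundary


def place_and_render_spots(
    labels: LabelVolume, params: SpotPlacementParams
) -> tuple[ImageStack, GroundTruth]:
    """Place spots relative to the membrane and render the spot channel.

    Ground-truth membrane distances are centre-of-spot to nearest
    membrane-voxel centre (brute-force nearest neighbour, independent of the
    analysis pipeline's distance transform).
    """
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(labels.voxel_size)
    tree, boundary = _membrane_tree(labels)
    inside = labels.labels > 0
    dist_vox = ndi.distance_transform_edt(~boundary, sampling=vs)

    band_vox = np.argwhere(inside & (dist_vox <= params.band_width_um))
    out_vox = np.argwhere(inside & (dist_vox > params.band_width_um))
    if params.p_membrane is not None:
        if params.p_membrane > 0 and len(band_vox) == 0:
            raise ValueError(
                "p_membrane > 0 requested but no membrane-band voxels exist"
            )
        if params.p_membrane < 1 and len(out_vox) == 0:
            raise ValueError("no interior voxels beyond the band")
    all_vox = np.argwhere(inside)

    rows = []
    for i in range(params.n_spots):
        if params.p_membrane is None:
            pool, want_band = all_vox, None
        elif rng.random() < params.p_membrane:
            pool, want_band = band_vox, True
        else:
            pool, want_band = out_vox, False
        for _ in range(200):  # rejection-sample the sub-voxel jitter
            v = pool[rng.integers(len(pool))]
            pos = (v + rng.uniform(-0.5, 0.5, size=3)) * vs
            d = float(tree.query(pos)[0])
            if want_band is None:
                break
            if want_band and d <= params.band_width_um:
                break
            if want_band is False and d > params.band_width_um:
                break
        else:  # pragma: no cover - pathological geometry
            raise RuntimeError("could not place spot in the requested band")
        bright = rng.random() < params.frac_bright
        median = params.amplitude_bright if bright else params.amplitude_dim
        amp = float(median * np.exp(rng.normal(0.0, params.amplitude_sigma)))
        rows.append(
            dict(
                spot_id=i,
                channel=0,
                **{"class": "translation" if bright else "mature"},
                z_um=pos[0], y_um=pos[1], x_um=pos[2],
                amplitude=amp,
                membrane_distance_um=d,
                pair_id=-1,
            )
        )
    gt = _gt_frame(rows)
    centers = gt[["z_um", "y_um", "x_um"]].to_numpy() if len(gt) else np.empty((0, 3))
    img = render_gaussian_spots(
        labels.labels.shape,
        labels.voxel_size,
        centers,
        gt["amplitude"].to_numpy() if len(gt) else np.empty(0),
        params.psf_sigma_um,
        background=params.background_level,
    )
    if params.noise is not None:
        img = params.noise.apply(img, rng)
    return ImageStack(img, labels.voxel_size), GroundTruth(spots=gt)


# ---------------------------------------------------------------------------
# colocalization scenes

def generate_coloc_pair(
    labels: LabelVolume, params: ColocParams
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Two spot channels with a known true overlap fraction and per-channel
    detection efficiency; pairings are recorded in the ground truth."""
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(labels.voxel_size)
    shape = labels.labels.shape
    extent = np.asarray(shape) * vs
    inside = np.argwhere(labels.labels > 0)
    if len(inside) == 0 and params.n_mrna > 0:
        raise ValueError("label volume has no interior voxels")
    tree = _membrane_tree(labels)[0] if params.n_mrna else None

    rows = []
    sid = 0
    for m in range(params.n_mrna):
        v = inside[rng.integers(len(inside))]
        pos = (v + rng.uniform(-0.5, 0.5, size=3)) * vs
        paired = rng.random() < params.true_overlap_fraction
        # partner offset uniform in a sphere of the allowed radius
        if paired and params.max_pairing_offset_um > 0:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = params.max_pairing_offset_um * rng.random() ** (1 / 3)
            partner = np.clip(pos + r * u, 0, extent - vs / 2)
        else:
            partner = pos.copy()
        for ch, p, eff in (
            (1, pos, params.detection_efficiency[0]),
            (2, partner, params.detection_efficiency[1]),
        ):
            if ch == 2 and not paired:
                continue
            if rng.random() >= eff:
                continue
            amp = float(
                params.amplitude * np.exp(rng.normal(0.0, params.amplitude_sigma))
            )
            rows.append(
                dict(
                    spot_id=sid,
                    channel=ch,
                    **{"class": "mrna"},
                    z_um=p[0], y_um=p[1], x_um=p[2],
                    amplitude=amp,
                    membrane_distance_um=float(tree.query(p)[0]),
                    pair_id=m if paired else -1,
                )
            )
            sid += 1
    gt = _gt_frame(rows)

    stacks = []
    for ch in (1, 2):
        sub = gt[gt.channel == ch]
        img = render_gaussian_spots(
            shape,
            labels.voxel_size,
            sub[["z_um", "y_um", "x_um"]].to_numpy(),
            sub["amplitude"].to_numpy(),
            params.psf_sigma_um,
            background=params.background_level,
        )
        if params.noise is not None:
            img = params.noise.apply(img, rng)
        stacks.append(ImageStack(img, labels.voxel_size))
    return stacks[0], stacks[1], GroundTruth(spots=gt)


# ---------------------------------------------------------------------------
# FRAP traces

def simulate_frap(params: FrapSimParams) -> tuple[FrapTrace, GroundTruth]:
    """Simulate bleached-region, reference-region and background traces.

    Frames before t=0 sit at the pre-bleach plateau; at t=0 the bleached
    region loses ``bleach_depth`` of its signal and recovers exponentially.
    Acquisition bleaching multiplies both regions by
    ``acquisition_bleach_rate`` per frame (counted from the first recorded
    frame); background is additive.  The ground truth stores the noiseless
    recovery curve both as a fraction of the bleached amount and normalized
    to the pre-bleach level.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_s
    n_pre = params.n_prebleach_frames
    n_post = int(np.floor(params.duration_s / dt)) + 1
    idx = np.arange(n_pre + n_post)
    time = (idx - n_pre) * dt

    t_post = np.clip(time, 0, None)
    recovery = params.mobile_fraction * (
        1.0 - np.exp(-t_post * np.log(2.0) / params.half_time_s)
    )
    frac_of_pre = np.where(
        time < 0,
        1.0,
        (1.0 - params.bleach_depth) + params.bleach_depth * recovery,
    )
    decay = params.acquisition_bleach_rate ** idx
    bg = float(params.background_level)
    bleached = params.prebleach_intensity * frac_of_pre * decay + bg
    reference = params.reference_intensity * decay + bg
    background = np.full_like(time, bg)

    if params.noise_sd > 0:
        bleached = bleached + rng.normal(0, params.noise_sd, bleached.shape)
        reference = reference + rng.normal(0, params.noise_sd, reference.shape)
        background = background + rng.normal(0, params.noise_sd, background.shape)

    trace = FrapTrace(
        time_s=time,
        bleached=bleached,
        reference=reference,
        background=background,
        n_prebleach=n_pre,
    )
    post = time >= 0
    gt = GroundTruth(
        spots=_gt_frame([]),
        kinetic_params=params.model_dump(),
        time_s=time[post],
        recovery_fraction=recovery[post],
        normalized_prebleach=params.bleach_depth * recovery[post],
    )
    return trace, gt


# ---------------------------------------------------------------------------
# line-scan fixtures

def generate_linescan_image(
    apical_value: float,
    cyto_value: float,
    background_value: float,
    shape: tuple[int, int] = (96, 128),
    voxel_size: tuple[float, float] = (0.1, 0.1),
    ridge_x_px: int = 48,
    ridge_width_px: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, dict]:
    """2D fixture: background | apical ridge | cytoplasm, left to right.

    Returns the image plus a layout dictionary with ready-made line-scan
    anchors and region boxes so the downstream ratio is fixed by
    construction: ``(apical - bg) / (cyto - bg)``.
    """
    if not (apical_value >= cyto_value >= background_value >= 0):
        raise ValueError("require apical >= cyto >= background >= 0")
    h, w = shape
    img = np.full(shape, float(background_value))
    img[:, ridge_x_px : ridge_x_px + ridge_width_px] = apical_value
    img[:, ridge_x_px + ridge_width_px :] = cyto_value
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, shape)
    stack = ImageStack(img, voxel_size)
    vy, vx = voxel_size
    scan_len = 30 * vx
    layout = {
        # scans cross the ridge perpendicular to the membrane (along +x)
        "scan_anchors_um": [
            ((h // 4) * vy, (ridge_x_px - 12) * vx),
            ((h // 2) * vy, (ridge_x_px - 12) * vx),
            ((3 * h // 4) * vy, (ridge_x_px - 12) * vx),
        ],
        "scan_direction": (0.0, 1.0),
        "scan_length_um": scan_len,
        "cyto_box_px": (slice(h // 4, 3 * h // 4), slice(ridge_x_px + ridge_width_px + 10, w - 4)),
        "background_box_px": (slice(h // 4, 3 * h // 4), slice(4, ridge_x_px - 20)),
        "expected_ratio": (
            (apical_value - background_value) / (cyto_value - background_value)
            if cyto_value > background_value
            else np.nan
        ),
    }
    return stack, layout
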