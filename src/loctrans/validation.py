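"""Parameter-recovery validation scenarios on synthetic scenes.

Each function builds a frozen synthetic scenario, runs the corresponding
analysis chain end to end, and returns the measured quantities next to the
ground truth.  They are the package's self-checks: the scene sizes are
chosen so every scenario runs in minutes on one CPU while keeping the
detector in its validated operating regime (spot spacing well above the
axial PSF for most spots).

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import synthetic as syn
from .config import DetectionConfig, RunConfig
from .detection import detect_spots
from .frap import correct_trace, fit_recovery
from .linescan import enrichment_ratio, line_scan, region_mean
from .localization import proximity_fraction, spot_membrane_distances
from .pipeline import analyze_localized_translation
from .segmentation import denoise_spot_channel, distance_to_membrane
from .stack import ImageStack, LabelVolume

__all__ = [
    "distance_oracle_check",
    "membrane_enrichment_recovery",
    "zflip_symmetric_check",
    "zflip_enriched_check",
    "detection_operating_point",
    "coloc_recovery",
    "frap_recovery",
    "ratio_recovery",
    "determinism_check",
]

_SIGMA = (0.35, 0.13, 0.13)
_VS = (0.3, 0.1, 0.1)


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------

def distance_oracle_check(seed: int = 0, n_volumes: int = 100) -> dict:
    """Distance transform vs exact nearest-boundary-voxel search.

    Random label volumes up to 32 voxels per side with anisotropic voxel
    sizes; the oracle is a KD-tree nearest-neighbour query against the
    boundary voxel centres, independent of the transform under test.
    """
    from .segmentation import distance_to_membrane

    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_volumes:
        shape = tuple(rng.integers(4, 33, size=3))
        vs = tuple(rng.uniform(0.05, 0.5, size=3))
        labels = rng.integers(0, 4, size=shape).astype(np.int64)
        vol = LabelVolume(labels, vs)
        boundary = vol.boundary_mask()
        if not boundary.any():
            continue
        dmap = distance_to_membrane(vol)
        pts = (
            np.stack(
                np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), -1
            ).reshape(-1, 3)
            * np.asarray(vs)
        )
        oracle = cKDTree(np.argwhere(boundary) * np.asarray(vs)).query(pts)[0]
        worst = max(worst, float(np.abs(dmap.distances.ravel() - oracle).max()))
        done += 1
    return {"max_abs_error_um": worst, "n_volumes": done}


def _recovery_embryo(seed: int) -> tuple:
    geom = syn.EmbryoGeometry(
        volume_shape=(80, 288, 288), voxel_size=_VS, n_cells=12, seed=seed
    )
    membrane, labels, _ = syn.generate_embryo(geom)
    return membrane, labels, distance_to_membrane(labels)


def membrane_enrichment_recovery(
    p_membrane: float, seed: int = 0, n_embryos: int = 3, n_spots: int = 2000
) -> dict:
    """Full detect -> distance -> fraction chain on embryos with a known
    membrane-proximal spot fraction; returns the mean recovered fraction."""
    cfg = RunConfig()
    fractions = []
    truths = []
    seeds = _child_seeds(seed, 2 * n_embryos)
    for i in range(n_embryos):
        membrane, labels, dmap = _recovery_embryo(seeds[2 * i])
        params = syn.SpotPlacementParams(
            n_spots=n_spots, p_membrane=p_membrane, seed=seeds[2 * i + 1]
        )
        channel, gt = syn.place_and_render_spots(labels, params)
        den = denoise_spot_channel(channel, cfg.segmentation.denoise_sigma_um)
        spots = detect_spots(den, cfg.detection)
        spots = spot_membrane_distances(spots, dmap)
        res = proximity_fraction(spots, cfg.proximity.cutoff_um)
        fractions.append(res.fraction_within)
        truths.append(
            float((gt.spots.membrane_distance_um <= 0.35).mean())
        )
    return {
        "p_membrane": p_membrane,
        "recovered_fraction": float(np.mean(fractions)),
        "per_embryo": fractions,
        "realized_truth": float(np.mean(truths)),
        "n_embryos": n_embryos,
        "n_spots": n_spots,
    }


def _run_pair(membrane, labels, channel, cfg):
    _, obs = analyze_localized_translation(
        membrane, channel, cfg, labels=labels
    )
    _, null = analyze_localized_translation(
        membrane, channel, cfg, labels=labels, null="zflip"
    )
    return obs, null


def zflip_symmetric_check(seed: int = 0, n_embryos: int = 20) -> dict:
    """Uniform spots in z-symmetric embryos: the z-flip null must be
    statistically indistinguishable from the observed fraction (pooled
    two-proportion z)."""
    cfg = RunConfig()
    seeds = _child_seeds(seed, 2 * n_embryos)
    obs_w = obs_n = null_w = null_n = 0
    for i in range(n_embryos):
        geom = syn.EmbryoGeometry(
            volume_shape=(40, 128, 128), voxel_size=_VS, n_cells=8,
            z_symmetric=True, seed=seeds[2 * i],
        )
        membrane, labels, _ = syn.generate_embryo(geom)
        params = syn.SpotPlacementParams(
            n_spots=120, p_membrane=None, seed=seeds[2 * i + 1]
        )
        channel, _ = syn.place_and_render_spots(labels, params)
        obs, null = _run_pair(membrane, labels, channel, cfg)
        obs_w += obs.n_within
        obs_n += obs.n_spots
        null_w += null.n_within
        null_n += null.n_spots
    p1, p2 = obs_w / obs_n, null_w / null_n
    pool = (obs_w + null_w) / (obs_n + null_n)
    se = np.sqrt(pool * (1 - pool) * (1 / obs_n + 1 / null_n))
    return {
        "observed_fraction": p1,
        "null_fraction": p2,
        "two_proportion_z": float((p1 - p2) / se) if se > 0 else 0.0,
        "n_embryos": n_embryos,
    }


def zflip_enriched_check(seed: int = 0, n_embryos: int = 20) -> dict:
    """Membrane-enriched spots (p=0.8) in z-asymmetric embryos: the z-flip
    null fraction must fall below the observed fraction per embryo."""
    cfg = RunConfig()
    seeds = _child_seeds(seed + 1, 2 * n_embryos)
    wins = 0
    obs_f, null_f = [], []
    for i in range(n_embryos):
        geom = syn.EmbryoGeometry(
            volume_shape=(48, 128, 128), voxel_size=_VS, n_cells=8,
            center_um=(6.2, 6.4, 6.4), semi_axes_um=(4.2, 5.4, 5.4),
            seed=seeds[2 * i],
        )
        membrane, labels, _ = syn.generate_embryo(geom)
        params = syn.SpotPlacementParams(
            n_spots=120, p_membrane=0.8, seed=seeds[2 * i + 1]
        )
        channel, _ = syn.place_and_render_spots(labels, params)
        obs, null = _run_pair(membrane, labels, channel, cfg)
        obs_f.append(obs.fraction_within)
        null_f.append(null.fraction_within)
        wins += obs.fraction_within > null.fraction_within
    return {
        "observed_mean": float(np.mean(obs_f)),
        "null_mean": float(np.mean(null_f)),
        "null_below_observed": int(wins),
        "n_embryos": n_embryos,
    }


def detection_operating_point(seed: int = 0, n_spots: int = 60) -> dict:
    """Recall / precision / centre accuracy at SNR 5 with >= 4 sigma
    spacing under Poisson noise."""
    rng = np.random.default_rng(seed)
    shape = (32, 128, 128)
    sig = np.asarray(_SIGMA)
    lo = 4 * sig + 0.3
    hi = np.asarray(shape) * np.asarray(_VS) - lo
    pts: list[np.ndarray] = []
    while len(pts) < n_spots:
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm((c - p) / sig) >= 4 for p in pts):
            pts.append(c)
    truth = np.asarray(pts)
    img = syn.render_gaussian_spots(
        shape, _VS, truth, np.full(n_spots, 50.0), _SIGMA, background=100.0
    )
    noisy = syn.NoiseParams().apply(img, rng)  # shot-noise sd 10 -> SNR 5
    tab = detect_spots(
        ImageStack(noisy, _VS), DetectionConfig(threshold=25.0)
    )
    det = tab[["z_um", "y_um", "x_um"]].to_numpy()
    d_det, j = cKDTree(truth).query(det)
    d_gt, _ = cKDTree(det).query(truth)
    tp = d_det < 0.3
    err = np.linalg.norm((det[tp] - truth[j[tp]]) / np.asarray(_VS), axis=1)
    return {
        "recall": float((d_gt < 0.3).mean()),
        "precision": float(tp.mean()),
        "median_center_error_voxels": float(np.median(err)),
        "n_spots": n_spots,
    }


def _gt_tables(gt):
    from .image_io import new_spot_table

    out = []
    for ch in (1, 2):
        sub = gt.spots[gt.spots.channel == ch]
        t = new_spot_table(sub[["z_um", "y_um", "x_um"]].to_numpy())
        t["spot_id"] = sub.spot_id.values
        out.append(t)
    return out


def coloc_recovery(seed: int = 0, n_mrna: int = 1000) -> dict:
    """Overlap-fraction and probe-efficiency recovery on dual-channel
    scenes with known pairing structure."""
    from .coloc import match_spots, probe_efficiency

    seeds = _child_seeds(seed + 2, 3)
    geom = syn.EmbryoGeometry(
        volume_shape=(48, 192, 192), voxel_size=_VS, n_cells=8, seed=seeds[0]
    )
    _, labels, _ = syn.generate_embryo(geom)

    p1 = syn.ColocParams(
        n_mrna=n_mrna, true_overlap_fraction=0.6,
        max_pairing_offset_um=0.1, seed=seeds[1],
    )
    _, _, gt1 = syn.generate_coloc_pair(labels, p1)
    a, b = _gt_tables(gt1)
    m = match_spots(a, b, 0.26)

    p2 = syn.ColocParams(
        n_mrna=n_mrna, true_overlap_fraction=1.0,
        detection_efficiency=(1.0, 0.62), max_pairing_offset_um=0.1,
        seed=seeds[2],
    )
    _, _, gt2 = syn.generate_coloc_pair(labels, p2)
    a2, b2 = _gt_tables(gt2)
    eff = probe_efficiency(a2, b2, 0.26)
    return {
        "overlap_fraction": m.overlap_fraction_a,
        "true_overlap": 0.6,
        "efficiency_channel1": eff["efficiency_channel1"],
        "true_efficiency": 0.62,
        "n_mrna": n_mrna,
    }


def frap_recovery(seed: int = 0, n_noisy: int = 50) -> dict:
    """Correction-chain round trip and kinetic parameter recovery."""
    base = dict(
        mobile_fraction=0.6, half_time_s=120.0, bleach_depth=0.8,
        acquisition_bleach_rate=0.995, background_level=50.0,
    )
    trace, gt = syn.simulate_frap(syn.FrapSimParams(**base, seed=seed))
    c = correct_trace(trace)
    roundtrip = float(
        np.abs(c.corrected[c.post] - gt.normalized_prebleach).max()
    )
    fit = fit_recovery(c)
    ms = []
    for s in _child_seeds(seed + 3, n_noisy):
        t, _ = syn.simulate_frap(
            syn.FrapSimParams(**base, noise_sd=50.0, seed=s)
        )
        ms.append(fit_recovery(correct_trace(t))["mobile_fraction"])
    return {
        "roundtrip_max_abs_error": roundtrip,
        "mobile_fraction": fit["mobile_fraction"],
        "half_time_s": fit["half_time_s"],
        "true_mobile_fraction": 0.6,
        "true_half_time_s": 120.0,
        "noisy_median_mobile_fraction": float(np.median(ms)),
        "n_noisy": n_noisy,
    }


def ratio_recovery(seed: int = 0, n_replicates: int = 100) -> dict:
    """Line-scan enrichment-ratio recovery on the ridge fixture."""
    vals = []
    for s in _child_seeds(seed + 4, n_replicates):
        img, layout = syn.generate_linescan_image(
            300.0, 100.0, 50.0, noise_sd=2.0, seed=s
        )
        peaks = [
            line_scan(
                img, a, layout["scan_direction"], layout["scan_length_um"],
                width_px=15,
            ).peak_value
            for a in layout["scan_anchors_um"]
        ]
        cyto = [region_mean(img, layout["cyto_box_px"])] * 3
        bg = [region_mean(img, layout["background_box_px"])] * 3
        vals.append(enrichment_ratio(peaks, cyto, bg).ratio)
    return {
        "mean_ratio": float(np.mean(vals)),
        "true_ratio": 5.0,
        "n_replicates": n_replicates,
    }


def determinism_check(seed: int = 0) -> dict:
    """Two full runs with the same seed must agree bit for bit."""
    cfg = RunConfig()

    def run():
        geom = syn.EmbryoGeometry(
            volume_shape=(32, 96, 96), voxel_size=_VS, n_cells=8, seed=seed
        )
        membrane, labels, _ = syn.generate_embryo(geom)
        params = syn.SpotPlacementParams(
            n_spots=80, p_membrane=0.6, seed=seed + 1
        )
        channel, _ = syn.place_and_render_spots(labels, params)
        spots, res = analyze_localized_translation(
            membrane, channel, cfg, labels=labels
        )
        return membrane.data, channel.data, spots, res

    m1, c1, s1, r1 = run()
    m2, c2, s2, r2 = run()
    identical = (
        np.array_equal(m1, m2)
        and np.array_equal(c1, c2)
        and s1.equals(s2)
        and r1 == r2
    )
    return {"identical": bool(identical), "fraction_within": r1.fraction_within}
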