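"""Photobleaching-recovery (FRAP) correction and kinetics.

The correction chain, applied per frame i:

1. background subtraction: ``b_i = bleached_i - background_i`` and
   ``r_i = reference_i - background_i``;
2. acquisition-bleaching correction from the reference region:
   ``c_i = r_i / mean(r, pre-bleach frames)`` and ``B_i = b_i / c_i``;
3. zero baseline: the corrected intensity of the first post-bleach frame
   (t = 0) is subtracted;
4. normalization: division by the mean corrected pre-bleach intensity
   (default) or by the bleached amount (pre-bleach mean minus the t=0
   value), selected by ``normalize_by``.

The chain is invariant to a global detector gain, and with the
``bleached_amount`` normalization its asymptote is the mobile fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FrapTrace", "correct_trace", "average_animal", "fit_recovery"]


@dataclass
class FrapTrace:
    """Aligned per-frame intensities for one bleaching experiment.

    ``time_s`` is strictly increasing with t=0 at the first post-bleach
    frame; ``n_prebleach`` frames precede it.  ``corrected`` is filled by
    :func:`correct_trace` (NaN over the pre-bleach frames only in the sense
    that they are reported for QC, not used downstream).
    """

    time_s: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    n_prebleach: int
    corrected: np.ndarray | None = None
    bleach_depth_measured: float | None = None
    normalize_by: str | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = len(self.time_s)
        for name in ("bleached", "reference", "background"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time axis")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 1 <= self.n_prebleach < n:
            raise ValueError("need >= 1 pre-bleach frame before t=0")
        # first post-bleach frame defines t = 0
        if not (self.time_s[self.n_prebleach - 1] < 0 <= self.time_s[self.n_prebleach]):
            raise ValueError("t=0 must be the first post-bleach frame")

    @property
    def post(self) -> np.ndarray:
        return self.time_s >= 0


def correct_trace(trace: FrapTrace, normalize_by: str = "prebleach") -> FrapTrace:
    """Apply the background / acquisition-bleaching / baseline /
    normalization chain (see module docstring).

    Returns a new trace with ``corrected`` filled for every frame and the
    measured bleach depth (1 - B_0 / pre-bleach mean) attached.
    """
    if normalize_by not in ("prebleach", "bleached_amount"):
        raise ValueError("normalize_by must be prebleach|bleached_amount")
    npre = trace.n_prebleach
    b = trace.bleached - trace.background
    r = trace.reference - trace.background
    r_pre = float(np.mean(r[:npre]))
    if r_pre <= 0:
        raise ValueError("invalid trace: nonpositive pre-bleach reference")
    c = r / r_pre
    if np.any(c <= 0):
        raise ValueError("invalid trace: nonpositive acquisition correction")
    B = b / c
    B_pre = float(np.mean(B[:npre]))
    if B_pre <= 0:
        raise ValueError("invalid trace: nonpositive pre-bleach intensity")
    B0 = float(B[npre])  # first post-bleach frame, t = 0
    depth = 1.0 - B0 / B_pre
    scale = B_pre if normalize_by == "prebleach" else B_pre - B0
    if scale <= 0:
        raise ValueError("invalid trace: no bleached amount to normalize by")
    corrected = (B - B0) / scale
    return replace(
        trace,
        corrected=corrected,
        bleach_depth_measured=depth,
        normalize_by=normalize_by,
    )


def average_animal(traces: list[FrapTrace], per_animal: int = 2) -> FrapTrace:
    """Frame-wise mean of the corrected recovery of one animal's traces."""
    if len(traces) != per_animal:
        raise ValueError(
            f"expected {per_animal} traces per animal, got {len(traces)}"
        )
    t0 = traces[0]
    for t in traces[1:]:
        if len(t.time_s) != len(t0.time_s) or not np.allclose(
            t.time_s, t0.time_s
        ):
            raise ValueError("traces do not share a time grid; refusing to resample")
        if t.corrected is None:
            raise ValueError("run correct_trace before averaging")
    if t0.corrected is None:
        raise ValueError("run correct_trace before averaging")
    mean_corr = np.mean([t.corrected for t in traces], axis=0)
    return replace(t0, corrected=mean_corr)


def _model(t, m, t_half):
    return m * (1.0 - np.exp(-t * np.log(2.0) / t_half))


def fit_recovery(trace: FrapTrace) -> dict:
    """Least-squares single-exponential fit of the corrected recovery.

    Fits ``A * (1 - exp(-t ln2 / t_half))`` to the post-bleach corrected
    series with multi-start initialization, ``A`` bounded to [0, 1.5].  When
    the trace was normalized to the pre-bleach level, the amplitude is the
    product of bleach depth and mobile fraction, so the reported
    ``mobile_fraction`` divides out the measured bleach depth.
    """
    if trace.corrected is None:
        raise ValueError("run correct_trace first")
    post = trace.post
    t = trace.time_s[post]
    y = trace.corrected[post]
    if len(t) < 10:
        raise ValueError("need >= 10 post-bleach frames to fit")
    span = float(t[-1] - t[0]) or 1.0
    best = None
    for th0 in (span / 50, span / 10, span / 3, span):
        try:
            popt, pcov = curve_fit(
                _model,
                t,
                y,
                p0=[max(float(y[-1]), 1e-3), th0],
                bounds=([0.0, 1e-6], [1.5, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        raise RuntimeError("recovery fit did not converge from any start")
    (amp, t_half), pcov, resid = best
    immobile = amp < 0.01
    depth = trace.bleach_depth_measured
    if trace.normalize_by == "prebleach" and depth and depth > 0:
        mobile = amp / depth
    else:
        mobile = amp
    return {
        "mobile_fraction": float(mobile),
        "amplitude": float(amp),
        "half_time_s": float(t_half),
        "half_time_identifiable": not immobile,
        "rss": resid,
        "n_frames": int(len(t)),
    }
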