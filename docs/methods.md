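# Methods

This note records the models behind each stage, the parameters that
matter, and what the synthetic scenes do and do not emulate.

## Coordinate and intensity conventions

Voxel indices are 0-based; index `i` along an axis with spacing `s` µm
maps to the physical position `i·s` at the voxel centre.  All distances
are centre-to-centre in µm; anisotropic voxel sizes (typically 0.3–0.4 µm
axially vs 0.1 µm laterally) are respected everywhere.  Intensities are
arbitrary detector units (ADU).  There is no absolute intensity
calibration, so the published gate values carried as configuration
defaults (25 000 for translation spots in the overlap assay, 2 000 in the
re-localization assay, 50 000 for mRNA spots) only apply to data from the
camera they were chosen on; for synthetic scenes gates must be set
relative to the simulated intensity law.

## Synthetic scenes

The generator produces the conditions the analysis assumes, not
photorealistic microscopy.

**Embryo.** An ellipsoid (default semi-axes 0.42× the volume extent)
holds `n_cells` cells: seed points drawn uniformly inside the ellipsoid
define a Voronoi tessellation in the physical metric.  The membrane
channel is background (100 ADU) plus a bright shell (600 ADU) on the
inter-cell/surface boundary voxels, blurred by a Gaussian PSF stand-in
(σ = 0.35 µm axial, 0.13 µm lateral — a typical confocal operating point).
With `z_symmetric=True` seeds are mirrored about the grid's z mid-plane
(and the ellipsoid centred there), making the label volume exactly
invariant under a z-flip; this geometry isolates the behaviour of the
randomized control.

**Spots.** Rendered as anisotropic Gaussians of the same PSF at
continuous centres, truncated at 5σ; diffraction-limited spots are well
approximated this way and every readout (peak, integrated sum) has a
closed form.  A spot is membrane-proximal with probability `p_membrane`
and is then placed uniformly in the band {0 ≤ d ≤ 0.35 µm} of the
distance-to-membrane field; otherwise uniformly beyond the band
(`p_membrane=None` places uniformly regardless).  Uniform-in-band
placement makes `p_membrane` exactly recoverable.  Ground-truth membrane
distances are brute-force nearest-boundary-voxel-centre distances
(KD-tree), independent of the analysis path.  Amplitudes are lognormal:
bright "translation" spots (median 400 ADU) vs dim "mature" spots
(median 40 ADU), σ_log = 0.3 — an order-of-magnitude class separation so
intensity gating is meaningful but not trivial.

**Camera noise** is Poisson–Gaussian (shot noise at a configurable gain
plus additive read noise) and **off by default**, so closed-form checks
are exact; recovery tests switch it on explicitly.

**Colocalization scenes.** `n_mrna` molecules are placed uniformly in
cells; with probability `true_overlap_fraction` a partner spot is placed
within `max_pairing_offset_um` (uniform in the sphere).  Channel 1
renders the mRNA spots, channel 2 the partners, each thinned by its
`detection_efficiency`.  Pairings among rendered spots are recorded.

**FRAP traces.** Pre-bleach frames at a plateau (1000 ADU); at t = 0 the
bleached region loses `bleach_depth` (default 0.8 — bleaching is
deliberately incomplete, as in practice) and recovers as
`M·(1 − e^{−t·ln2/t_half})` of the bleached amount.  Both the bleached and
a reference region decay by `acquisition_bleach_rate` per frame;
a constant background is added to every measured series; optional
Gaussian noise.  Defaults follow the imaging protocol: 20 s frame
interval, 20 min duration, 5 pre-bleach frames.

**What is not emulated:** optical sectioning and a realistic PSF (no
Airy/Gibson–Lanni model), spot motion and cell division, spatially varying
background, chromatic offsets between channels, detector fixed-pattern
noise.  Passing recovery tests therefore demonstrates correctness of the
measurement chain under the stated statistical model, not performance on
any particular microscope's data.

## Segmentation

Membrane enhancement = unsharp masking (radius 0.3 µm, amount 1) followed
by edge boosting: the output is the background-subtracted sharpened
signal plus `edge_gain`×(Gaussian gradient magnitude, σ 0.2 µm), so both
the membrane ridge centre and its flanks score high; a constant image
maps to zero.  Cells are a seeded watershed inside the embryo mask:
seeds are h-minima (depth 50 ADU) of a heavily smoothed landscape
(σ 0.4 µm) for stability, while flooding runs on a lightly smoothed one
(σ 0.15 µm) so watershed lines track the ridge; the outside is raised
above the maximum so basins cannot leak.  The embryo mask is the
slice-wise convex hull of the Otsu-thresholded membrane signal, eroded by
one voxel to compensate the outward half-width of the blurred shell.
Exclusion regions (e.g. visibly dividing cells) are user-supplied boxes;
there is no automatic mitosis detector.

"Edge of the membrane" is *defined* as the inter-label boundary voxel set
of the segmentation (voxels inside a nonzero label facing a different
label or the outside), and the distance map is the exact Euclidean
distance transform of that set with per-axis physical sampling.  Spot
distances are read from the map by trilinear interpolation; no sub-voxel
boundary interpolation is attempted, so distances carry an error of at
most about half a voxel near the membrane.

## Spot detection

The detector is a difference-of-Gaussians band-pass at the expected spot
scale (k = 1.6), *normalized so an isolated Gaussian spot of amplitude A
scores ≈ A*: thresholds are therefore in ADU and transfer across image
sizes.  Maxima are extracted with an h-maxima transform whose depth is
the "split sensitivity" — maxima shallower than the depth merge into one
spot, the standard remedy for over-segmentation of close spots.  Centres
are response-weighted centroids in a ±2σ window (sub-voxel; ≈0.01 µm on
isolated noiseless spots, ≈0.2 voxel at SNR 5).  Integrated intensity is
the sum over a 3σ ellipsoid minus its local background, the median of the
3–5σ shell — the quantity conventional spot-counting plugins report.
Gates are strict (`intensity > gate`) and inclusion rules follow the
assay conventions: ≥25 spots (proximity), >3 (overlap), >7
(re-localization).

Two spots closer than roughly the axial PSF produce a single response
maximum and merge irrecoverably; the operating point is validated at
≥4σ spacing (recall and precision ≥0.95 at SNR 5).  At the stress density
used in the recovery scenarios (2000 spots per embryo) a moderate
merge-loss remains and is the dominant residual bias (1–3 percentage
points) of the recovered proximal fraction.

## Membrane proximity and the z-flip null

The proximity statistic counts spots with distance ≤ cutoff (closed band:
the printed range "0–0.35 µm" includes its endpoint).  The null control
reverses only the spot channel along z — segmentation and membrane stay
fixed — and re-runs the *identical* detection + distance pipeline;
flipped spots that leave the embryo are discarded.  The flip is applied
to raw pixels, not detected coordinates, so any detector bias affects
both conditions equally.  On z-symmetric geometry the flip is a symmetry
of the scene and observed and null fractions agree exactly; on real
(asymmetric) geometry the null falls toward the chance level set by the
band's volume fraction.

Spot categorization (nuclear pore / plasma membrane / cytosol) replaces
visual scoring with a distance rule: nuclear distance ≤ cutoff →
nuclear_pore, else membrane distance ≤ cutoff → plasma_membrane, else
cytosol; the categorization cutoff defaults to the proximity cutoff.
Without a nuclear map only the membrane/cytosol split is made.  This is a
deliberate deviation from manual scoring in favour of reproducibility.

## Colocalization

Object-based matching: mutual nearest neighbours within a physical
radius, conflicts resolved greedily by ascending offset with a
deterministic (offset, id, id) tie-break.  On well-separated spots this
equals the global minimum-offset assignment.  The match radius default
(0.26 µm ≈ 2 projected spot σ) is a documented choice — the original
plugin's maximum-distance parameter is not published — and is
configuration.  Overlap is asymmetric by design: matched translation
spots over all translation spots.  Probe efficiency divides matches by
each channel's own count.

## Line scans and enrichment ratios

A line scan samples the image every (smallest) pixel along a direction
with linear interpolation and averages over `width_px` parallel offsets;
its peak is the apical readout — the interpretation of a wide-line "peak
histogram intensity".  Ratios are `(mean apical − mean bg)/(mean cyto −
mean bg)` over three scans/regions each (count configurable); with
background subtraction the ratio is exactly invariant to detector gain.
A nonpositive denominator flags the ratio as undefined rather than
reporting a number.  Scan and region placement is user-supplied; cells
are not identified automatically.

## FRAP correction and kinetics

Per frame: (1) background subtraction for bleached and reference series;
(2) acquisition-bleaching correction `c_i = r_i / mean(r_pre)` from the
reference region, `B_i = b_i / c_i`; (3) the first post-bleach value
`B_0` is subtracted (zero baseline at t = 0); (4) normalization by the
pre-bleach mean of `B` (default) or by the bleached amount
`mean(B_pre) − B_0` (`normalize_by="bleached_amount"`).  The order
follows the protocol's sequential description; both normalizations are
implemented because the prose leaves the denominator ambiguous.  Under
the default, the curve's asymptote is bleach-depth × mobile-fraction, so
the kinetic fit divides its amplitude by the measured bleach depth
`1 − B_0/mean(B_pre)` to report the mobile fraction itself; under the
alternative the asymptote is the mobile fraction directly.  The chain is
invariant to global gain and exactly inverts the generator's corruption
in the noiseless case.

The recovery model is a single exponential with multi-start least
squares, amplitude bounded to [0, 1.5]; diffusion–reaction models are out
of scope.  An amplitude below 0.01 flags the half-time as unidentifiable.
Two traces per animal are averaged frame-wise (count configurable;
mismatched time grids are refused, never resampled).

## Validation scenarios and problem sizes

`loctrans.validation` freezes the self-check scenarios (all driven by one
seed): 100 random label volumes ≤ 32³ for the distance-transform oracle;
three 12-cell embryos of 80×288×288 voxels with 2000 spots each per
proximal fraction ∈ {0.3, 0.5, 0.8}; 20 z-symmetric and 20 z-offset
embryos (40–48 z-planes, 8 cells, 120 spots) for the null control; 60
spots at SNR 5 for the operating point; 1000-molecule dual-channel scenes
for overlap (0.6) and efficiency (0.62) recovery; 50 noisy FRAP
replicates; 100 noisy ratio fixtures.  These sizes keep the whole
validation run to a few minutes on one CPU while holding the statistical
error of each recovered quantity well inside its tolerance.  The
colocalization recovery measures the matcher on ground-truth spot tables
(with efficiency thinning and pairing jitter); image-based detection
feeding the matcher is exercised separately by the operating-point
scenario and the unit tests.

## Known limitations

- Distance accuracy is limited to about half a voxel near the membrane
  (voxel-centre boundary definition plus trilinear map sampling).
- The detector cannot split spots merged below ~2σ separation; dense
  scenes bias detected-population statistics slightly toward emptier
  regions.
- The watershed replaces a proprietary membrane-based segmenter; its
  probability-threshold analogue (h-minima depth) needs per-dataset
  tuning just as the original did, and the published per-embryo values
  are unrecoverable.
- Statistical comparison between conditions (ANOVA and friends) is
  delegated to standard statistics packages; this package reports
  per-embryo values and mean ± s.d. summaries only.
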