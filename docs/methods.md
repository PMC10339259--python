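# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic scene generators do and do not
emulate, and the known limitations.

## Conventions

Image coordinates have the origin at the top-left corner, x rightward
along the channel axis, y downward. Frames are 0-based; the time of frame
k is k/frame_rate. Positions and lengths are in μm, speeds in μm/s. The
channel inlet lies at −x by default; `ChannelGeometry` makes the inlet
vector n̂ configurable. All angles are measured in degrees from n̂, in
(−180°, 180°], so 0° means flow toward the inlet.

## Ciliary beat frequency

The motion map is the per-pixel population standard deviation (ddof = 0)
of intensity across frames. A temporally constant pixel maps to 0; a pure
sinusoid of amplitude A maps to A/√2.

Otsu's threshold (256-bin histogram over the map's full range) segments
the motion map into beating vs static area. Otsu always splits a
histogram, so a *minimum-motion guard* suppresses segmentation of pure
noise: a map whose dynamic range falls below an absolute floor
(`min_motion`, default 1.0 intensity units — above the spread of the
noise-only std estimate at typical camera noise, far below any beating
signal) yields an empty mask, and the Otsu threshold is additionally
clamped to at least the floor. Beat density is the mask fraction;
consequently it is invariant under intensity rescaling (Otsu is
scale-equivariant).

Per masked pixel, the time series is mean-detrended, smoothed with a
3-frame moving average (configurable; `smooth_frames<=1` disables it, and
on clean signals smoothing does not move the spectral argmax), and the
dominant frequency is the argmax of the FFT magnitude over the open band
(f_min, Nyquist). f_min defaults to 2 Hz to exclude DC leakage and slow
drift while keeping the whole physiological ciliary band (~4–20 Hz).
Frequency resolution is frame_rate/n_frames; every recovery test asserts
agreement within one bin. Pixels with no spectral peak above a tiny floor
(temporally constant pixels inside the mask) are excluded as NaN. The
per-field value is the mean over defined masked pixels;
`region_mean_frequencies` additionally averages within 8-connected motion
regions of at least 10 px (a region being roughly one ciliated cell),
dropping smaller segmentation specks.

Per-sample summaries average fields of view unweighted. A field with no
detected motion contributes density 0 but is excluded from the frequency
mean, where frequency is undefined.

## Bead tracking

Detection: the negative scale-normalized Laplacian-of-Gaussian response at
scale σ (default 1.5 px, matching the rendered point-spread function) is
peak-picked with a minimum separation of σ; peaks below an absolute
intensity floor over the median background are discarded, and positions
are refined to sub-pixel precision by an intensity-weighted centroid over
a ±2σ window.

Linking: greedy mutual-nearest-neighbour association between consecutive
frames within `max_disp_um` (default 3× the expected per-frame directed
displacement). Ties resolve by smallest distance, then lowest spot index,
making linking fully deterministic. There is no gap closing — a missed
detection splits a track — and no merge/split handling; this is adequate
at the high bead dilutions of transport assays, where spots are sparse,
and downstream statistics are robust to track splits. Tracks shorter than
`min_track_len` (default 5) nodes are dropped.

## Trajectory classification

Nine per-trajectory features: mean/median/sd of step speed, path length,
Euclidean (net) distance, directness (net/path, defined as 0 for a
stationary track), mean flow angle, node count, maximal acceleration
(largest |Δspeed|/Δt). "Mean flow angle" is implemented as the angle of
the *mean displacement vector* rather than the circular mean of step
angles: it is equivalent for persistent tracks and avoids wrap-around
pathologies for diffusive ones. All features are invariant to rigid
translation; the angle is equivariant with the inlet convention.

Two classifiers:

* a decision tree (max depth 5, min leaf 5, deterministic seed) whose
  reported accuracy is always the mean held-out accuracy over stratified
  5-fold cross-validation, never training accuracy;
* a transparent three-feature rule — *background iff Euclidean distance,
  median speed and directness all fall below thresholds*. Default
  thresholds (26.5 μm, 9.4 μm/s, 0.79) were calibrated once by maximizing
  balanced accuracy on a quantile grid over an independent synthetic
  calibration scene at default conditions, and are stored as package
  defaults; `ThresholdClassifier.calibrate` re-derives them for other
  regimes.

`filter_background` removes background-labeled tracks without touching
surviving coordinates.

## MCC statistics

PO = û·n̂ with û = ⟨[sin θᵢ, cos θᵢ]⟩. In the frame where θ is measured
from n̂ this reduces to the mean of cos θᵢ — documented prominently
because the sign convention (0° = inlet) is the easiest thing to get
wrong. PO is bounded in [−1, 1] (a mean of unit vectors dotted with a unit
vector); reversing n̂ negates it exactly. Trajectories with zero net
displacement carry no direction: they are excluded from the angle set
(logged) but still contribute velocity observations. Angle histograms
weight per trajectory, matching the "overall transport direction per bead"
reading, over equal bins of (−180°, 180°].

The Eulerian field assigns each step's velocity to the grid cell of its
*midpoint* (symmetric; start-point binning would bias cells along the flow
direction), then averages per cell over all observations. Grid spacing
defaults to 20 μm, a compromise between spatial resolution and
observations per cell at ~1200 μm fields.

Coverage: the alpha shape (Delaunay triangles with circumradius ≤ alpha;
areas summed — Delaunay triangles are interior-disjoint) is computed over
the *corner points* of active cells rather than cell centers, so that a
fully active grid yields exactly the full field area; with center points
the half-cell margin would bias coverage low by ~3% at default geometry.
Alpha defaults to 2× the grid spacing: large enough to bridge adjacent
active cells into coherent areas, small enough not to fill genuinely
inactive regions. Fewer than 3 active cells enclose no area. C_mcc is
clipped to [0, 1] with A_total the full field-of-view area (occlusion
masks are out of scope). M̄ = C_mcc·⟨|U|⟩ never exceeds ⟨|U|⟩, with
equality only at full coverage. Note the alpha shape intentionally fills
small holes in sparse Lagrangian sampling — the brute-force cell-count
oracle and the alpha-shape area agree within 10% only on densely sampled
regions, which is what the oracle tests use.

Pooling movies of one sample concatenates angles *before* recomputing PO
(the statistic of the pooled trajectories, not a mean of per-movie POs)
and averages field-level metrics weighted by field area.

## Immunofluorescence quantification

Area fraction: median filter (radius 2 px) → CLAHE (clip 0.01) to flatten
illumination → automatic threshold (Otsu default; triangle and mean
exposed) → positive-pixel fraction. Images whose dynamic range is below a
degeneracy floor (blank or uniformly saturated) return fraction 0 with a
flag, because any automatic threshold on a unimodal histogram is
arbitrary.

Crescent detection: denoising runs Gaussian (σ 1 px) → median (3 px) →
Wiener (5 px) in that order; the ridge response is the Hessian-eigenvalue
(Sato vesselness) filter for bright tubular structures, maximized over
scales {1, 2, 4} px; Otsu binarizes the response; components under 10 px
are removed. A denoised dynamic range below `min_contrast` (20 intensity
units) short-circuits to an empty mask, since Otsu on a noise-only
response map would segment spurious ridges.

Crescent density: each 8-connected component is skeletonized to a
single-pixel centreline and measured by corner-corrected chain counting
with Vossepoel–Smeulders weights (0.980 per orthogonal step, 1.406 per
diagonal, −0.091 per corner). Plain (1, √2) chain weighting overestimates
digitized segments by up to ~8% at intermediate orientations (and ~5% on
average over arc tangents), which would exceed the 5% tolerance the
length checks demand; the corrected weights bound the error near 2.5% at
any orientation. Diagonal edges with an orthogonal two-step detour are
skipped so L-corners are not double-counted; an isolated pixel counts one
pixel of length. D_C = ΣLᵢ/A holds exactly by construction, with A the
full field area in μm². Per-donor summaries average fields of view
unweighted.

## Synthetic scenes: what they emulate, and what they do not

The generators reproduce the *statistical structure* the analysis stages
rely on, with exact ground truth, at the acquisition geometry of the
assays (cilia: 200 frames/s, ~3 px/μm; beads: 30 frames/s, ~1200 μm
fields, 1-μm beads):

* Cilia: circular patches whose pixels oscillate as
  baseline + A·sin(2πft + φ) plus additive Gaussian noise. No waveform
  asymmetry, metachronal phase gradients, or spatial frequency mixing —
  so passing tests certify frequency/density recovery, not robustness to
  non-sinusoidal beating.
* Bead transport: directed tracks advance at a per-track speed drawn from
  N(20, 5) μm/s (a typical strong-transport regime; configurable, as real
  speed distributions vary widely) along a configurable direction with
  0.3 μm per-step jitter; background tracks are Brownian with
  D = 0.4 μm²/s — the Stokes–Einstein value for a 1-μm bead in aqueous
  buffer at room temperature — plus a slow constant drift
  (0.3, 0.1) μm/s emulating bulk flow in cell-free chips. Track spans are
  drawn uniformly (20–300 nodes) within a 300-frame movie. Real background
  flow may be spatially structured; the classifier is only certified
  against this Brownian-plus-drift null.
* Rendering: isotropic Gaussian point-spread function (σ 1.5 px),
  additive Gaussian noise, 8-bit clipping. No Poisson shot noise, motion
  blur, defocus or vignetting.
* Crescents: arcs/segments with Gaussian cross-profile on a noisy
  background; manifest records exact analytic lengths and the detectable
  footprint (noiseless intensity ≥ max(3·noise_sd, 10% peak)).
* Marker images: smoothed-noise blobs thresholded at the exact requested
  pixel count, then bimodal intensities plus noise; fractions 0 and 1 are
  generated but flagged degenerate.

All generators are bit-reproducible under a fixed seed, and each manifest
suffices to compute every downstream target without re-reading pixels.

## Benchmark problem sizes

The end-to-end benchmark (`mucoflow benchmark`, `pipeline.run_benchmark`)
uses a 120×120 px, 256-frame cilia scene with two patches; 600 labeled
trajectories over a full 1200 μm field for classification and statistics;
and a rendered 400×400 μm, 120-frame movie with 45 beads for the
detect→link→classify→stats round trip — sizes chosen so the full suite
runs in well under a minute while every tolerance (one FFT bin for CBF,
±0.02 density, ±0.05 PO and coverage, ≥95% classifier accuracy) is
exercised meaningfully. The classifier acceptance benchmark uses 2,000
labeled trajectories, a deliberate scale-down from the ~40,000 a full
manual labeling campaign would provide; accuracy at this size is already
stable to well under a percentage point.

## Known limitations

* The tracker has no gap closing or merge/split resolution; heavy bead
  crossing or blinking fragments tracks.
* Background classification assumes the directed and diffusive regimes
  are separable in the nine-feature space; transport barely above the
  background drift speed will be misclassified.
* Coverage treats the full field of view as tissue; fields partially
  covered by channel walls or debris need external masking.
* Crescent detection was calibrated on the synthetic generator only; real
  VANGL1 stainings with strong membranous background may need different
  ridge scales and contrast floors.
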