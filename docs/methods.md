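# Methods

## Measurement model

The quantity of interest is the integrated fluorescence of a spot-like
organelle above its local background — a proxy for PCM scaffold mass. The
estimator is deliberately simple and fully specified:

* **Seed detection.** The centrosome centre is the argmax of the frame
  after a Gaussian blur of σ = 1 px (ties break to the smallest row, then
  column). The blur is used *only* for localization; all statistics and
  masses are computed on the unblurred image. On frames after the first,
  the argmax is restricted to a (2·`search_radius`+1)² window around the
  previous seed (`search_radius` = 10 px by default), which follows a
  centrosome drifting toward the cortex; the window only advances while
  the ROI is non-empty, so once the signal vanishes the seed does not
  random-walk away.
* **Background annulus.** Pixels whose centre distance d from the seed
  satisfies inner < d ≤ outer, with inner = 7 px (chosen to enclose the
  full lateral extent of the PCM signal) and outer = 10 px. The mean μ_bg
  and population standard deviation σ_bg (ddof = 0; configurable) over the
  annulus summarize the local background. Annuli clipped by the image edge
  are flagged.
* **Threshold.** T = μ_bg + k·σ_bg with k = 3, computed on the first frame
  and held fixed for the whole movie. A fixed threshold makes frame-to-frame
  masses directly comparable and makes "mass 0" meaningful once the signal
  falls below detectability.
* **ROI.** The 8-connected component of strictly-suprathreshold pixels that
  contains the seed. Seed-connectivity keeps unrelated debris from
  inflating the mass; strict `>` guarantees exactly-uniform frames measure
  zero. A sub-threshold seed yields an empty ROI, reported as mass 0 with a
  flag (not an error) — this is the "no longer detectable" state.
* **Integrated mass.** M = (mean_ROI − T)·area_ROI ≡ Σ_ROI (pixel − T),
  in counts·px. M scales exactly linearly with the image (multiplying a
  frame by c > 0 multiplies μ_bg, σ_bg, T and M by c with ROI membership
  unchanged) and is invariant to integer translation — both properties are
  enforced by tests.
* **Merged mode.** When the two centrosomes cannot be resolved, the annulus
  radii are doubled (14/20 px; the appropriate factor is data-dependent and
  configurable) and every M is divided by two, yielding a per-centrosome
  average. The halved value intentionally breaks the
  (mean−T)·area identity and is flagged `merged_halved`.

### Known biases

Thresholding subtracts T from every ROI pixel and loses the sub-threshold
tails of the point-spread function, so M underestimates the true integrated
signal by roughly (T − background)·area plus a small tail term. Near the
detection floor this deficit dominates: accuracy is within ~1% at peak
signal and degrades below ~10× the floor (defined as the integrated mass
whose peak amplitude equals k·σ of the per-pixel camera noise). Ratio and
reduction quantities are largely insensitive because the bias is shared
between numerator and denominator. Pure-noise frames measured at a given
centre return mass 0 in ≈100% of trials; an adversarial seed chosen as the
blurred argmax of the noise itself can pick up small positive mass more
often, but that situation does not arise in the pipeline (first-frame seeds
sit on real signal; later empty frames use the tracked window).

## Kinetics estimators

Curves are normalized per-centrosome to their own maximum (the source
material normalizes per stack). Downstream quantities:

* **Onset** = time of the maximum of the moving-average-smoothed normalized
  curve (window 2·`smooth_window`+1 samples, default 5; ties earliest).
  Averaging across an asymmetric peak (decay steeper than the late rise)
  places the smoothed argmax ~1–2 frames *early*; the unsmoothed argmax is
  unbiased on clean data, and the default window buys robustness to noise
  at that cost. Onset accuracy within ±2 frames under realistic noise is a
  tested property.
* **Rate** = least-squares slope of normalized mass versus time from onset
  until the curve first falls below half its onset value. For an
  exponential decay with rate k and no residual, the window mean slope is
  −0.5·k/ln 2 ≈ −0.72·k, so percent *reductions* between conditions equal
  the k-ratio reduction. With a residual plateau f, the true initial slope
  is −(1−f)·k: slope-space reductions then exceed k-space reductions (a
  condition with k at 41% of wild type *and* f = 0.25 shows a ~71% slope
  reduction). The estimator is applied uniformly; an exponential
  (log-linear) fit over the same window is available via
  `method="exponential"`.
* **Rate reduction** = 100·(1 − |rate_treated|/|rate_reference|).
* **Persistence** = median normalized mass over the trailing window of the
  movie (default last 60 s); the median resists single-frame noise. The
  movie must extend well past onset so the window samples the plateau.
* **Ensembles** — curves aligned at NEBD or onset; pointwise mean with a
  normal-approximation 95% band (±1.96·SE) wherever ≥2 curves contribute.

The `PCMDisassemblyModel` / `PCMDisassemblyResults` pair packages these
estimators statsmodels-style: construct from curves (or a tidy DataFrame),
`fit()`, inspect `params`, `summary()`, `ensemble()`.

## Two-channel ratiometry

Per centrosome, the ROI is segmented on the total-scaffold channel and the
same pixel set is integrated in both channels against channel-specific
annulus thresholds; the ratio A/B therefore controls for PCM size, and
common rescaling of both channels cancels exactly. Ratios are normalized to
the interphase mean (interphase mean ≡ 1 after normalization; idempotent).
Stages are compared with Welch's unequal-variance t-test — the safer
default where only "unpaired t-test" is specified — with degenerate
zero-variance pairs reported as p = 1 and flagged.

## Synthetic data

The simulator emulates what the quantification assumes about the real
movies, with per-frame ground truth:

* **Geometry** — a 96×160 px field (0.11 µm/px, typical of a 60×
  EMCCD setup) containing an ellipsoidal embryo (semi-axes 40×72 px) of
  uniform cytoplasmic background on a dark field; two centrosome foci on
  the long axis, rendered as 2D isotropic Gaussians of σ_psf = 2 px on the
  projection plane. An optional z-stack mode distributes spot and
  background across slices with a Gaussian axial profile so that SUM
  projection reproduces the 2D render in expectation.
* **Kinetics** — true mass follows a logistic rise (k_grow = 0.02 /s,
  rescaled to reach the peak exactly at onset) to m_peak = 3×10⁵ counts·px
  at t_onset, then m_peak·(f + (1−f)·e^(−k_decay·(t−t_onset))). Wild type:
  t_onset = 275 s post-NEBD, k_decay = 0.012 /s anterior and 0.016 /s
  posterior (posterior faster; mass undetectable by ~550 s), f = 0.
  Depletion presets scale k_decay by the reported slowdowns (0.46/0.35
  for the phosphatase depletion, 0.73 posterior-only for the force
  depletion, 0.41/0.28 with f = 0.25 and an earlier 230 s onset for the
  double depletion, whose unresolvable pair triggers merged-mode
  quantification).
* **Motion** — centrosomes drift along the long axis toward the nearer
  cortex at 0.004 µm/s (0.001 µm/s in force-depleted presets) from onset
  onward; merged pairs do not drift. Spindle oscillations are not
  modelled.
* **Camera** — expected counts = background (500 counts inside the embryo
  mask, a summed-z-stack scale) + spots; Poisson noise at photon level
  (1 count/photon), Gaussian read noise (σ = 6), offset 100. With shot and
  read noise disabled the render is deterministic; identical seeds give
  bit-identical movies.
* **Two-channel images** — single spots with channel-B mass lognormal
  around 1.5×10⁵ counts·px and channel A = stage-ratio × B at the identical
  centre; the default stage profile is (1, 2, 4, 1.5)× interphase for
  interphase, prophase/metaphase, anaphase, telophase.

What the simulator does **not** reproduce: PCM fragmentation geometry and
packet shedding, microtubule asters, anaphase spindle oscillations,
photobleaching, inhomogeneous cytoplasmic background, multi-cell stages.
Passing recovery tests therefore demonstrates the estimators are correct
for diffraction-blurred compact spots under camera noise — not that the
macro is robust to fragmentation or background structure in real movies.

## Problem sizes and numerics

Recovery studies use 10–20 replicate movies per condition at 10 s/frame:
60 frames (600 s) for rate and onset studies, 90–130 frames where the
residual plateau must be sampled. These sizes give sub-percent Monte-Carlo
error on the recovered means while keeping any study a few seconds of
compute. All image arithmetic is float64; sums over z are widened before
summation so 16-bit inputs cannot overflow. Seeds are explicit everywhere;
one seed fully determines a movie.

Numerical edge cases are handled explicitly: all-constant frames flag a
low-confidence seed; empty annuli (tiny frames) and all-zero curves raise
informative errors; curves that never reach half-maximum refuse a rate fit
rather than extrapolate; single-curve ensembles report an absent confidence
band.

## Open design choices

Where the source procedure is under-specified, this package chose once and
made the choice configurable: post-NEBD cropping keeps the NEBD frame
(t = 0 must exist for alignment); the hemisphere boundary is user-supplied
(default midline); σ_bg is the population estimate; the merged-mode radius
factor is 2×; onset is the smoothed argmax; the rate window is
onset-to-half-maximum; persistence is a trailing 60 s median; the stage
t-test is Welch's. Each appears in the output metadata so an analysis is
reproducible from its logs.
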