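# Methods

## Scope and data model

`sticsflow` estimates flow vector fields from single-channel 2D+t
fluorescence series.  The central container is `ImageSeries`: a
`(time, row, col)` lattice with explicit physical calibration (µm/pixel,
s/frame) supplied by the user — TIFF tags are never trusted.  Row 0 is
the top of the image; x is the column axis (rightward), y the row axis
(downward).  Vector angles are reported mathematically: 0° = rightward,
+90° = toward the top of the image, so `vy` is positive upward.

## Registration

Frames are registered translationally against a single reference frame
(default: frame 0) by phase correlation.  The cross-power spectrum is
whitened with a regularization term (1% of the mean magnitude): pure
phase normalization lets near-zero high-frequency components dominate on
smooth images, while the regularized form keeps the sharp peak and is
exact for cyclic integer shifts.  Shifts are integer by default and
applied by cyclic roll; an optional subpixel refinement reports the
center of mass of the 3×3 neighborhood of the correlation peak (frames
are still rolled by the rounded shift).  All-zero frames have an
undefined correlation; they are flagged and assigned shift (0, 0).
First-frame referencing is a choice: the intended use case is cells that
are non-migratory over the recording, where any fixed reference works.

## Spatial filters

**Gaussian filter.**  Per-frame 2D Gaussian convolution (σ in pixels,
kernel truncated at 4σ, <1e−4 mass loss), replicate boundary so constant
frames pass through unchanged and no dark border is introduced that
would correlate spuriously.  σ should exceed the spacing between
neighboring structures; the reference setting used throughout is 7 px.

**Heterogeneity map.**  `HM = (I − µ)/µ`, where µ is the mean under a
normalized circular (disk) kernel.  The disk contains every pixel whose
center lies within diameter/2 of the kernel center (so diameter 3 fills
the full 3×3 block, corner distance √2 ≤ 1.5); the lattice side is the
smallest odd integer ≥ diameter.  The map is computed as
`(n·I − S)/S` with S the disk sum, where the numerator comes from a
single convolution with an integer-valued kernel (`n·δ_center − disk`);
this makes the response to a spatially uniform frame *exactly* zero
rather than zero up to float rounding.  Pixels whose local mean does not
exceed a guard (default 1e−12 × frame max) are set to 0 and counted in
the log.  Properties relied on elsewhere: zero response to uniform
frames, invariance under global gain, sign equal to the sign of
(I − µ).  Bright-in-context pixels map positive.  The kernel diameter
should roughly match one structure plus its clear surround (reference
settings: 8 px for diffraction-limited puncta, 16 px for micron-scale
podosome-like structures).

Both filters are purely per-frame, so they commute with any frame
reordering.

## Flow simulator

The simulator emulates the two flow archetypes with full ground truth:

* **contiguous layer** — `n_particles` point emitters uniformly placed
  on the canvas, each a 2D Gaussian PSF with 1/e² intensity radius
  `psf_e2_radius` (σ = radius/2) whose continuous integral equals
  `photon_rate × exposure`; the whole layer drifts rigidly at
  `drift_speed` along `drift_direction`.
* **noncontiguous layer** — `wave_n_particles` wide-PSF emitters seeded
  on the horizontal line `wave_line_fraction` of the canvas height up
  from the bottom; the rendered envelope translates vertically at
  `wave_speed`.  Whether such a wave should translate, oscillate or
  amplitude-modulate is an open modeling choice; pure translation is
  implemented because it produces the canonical vertically-aligned
  vector field the filters are meant to isolate.

Defaults (the reference study conditions): 100×100 px canvas at
0.14 µm/px, 200 emitters with 0.5 µm PSF radius emitting 400 photons/s,
drifting rightward at 0.5 µm/min; 100 wave emitters with 2 µm PSF
radius moving upward at 0.5 µm/min; 30 frames at 15 s intervals, 1 s
exposure.  Presets: `contiguous`, `wave`, `mixed-add`, `mixed-multiply`.

Rendering evaluates each PSF at pixel centers and multiplies by the
pixel area, so the frame sum reproduces the photon budget to better
than 1%.  With the default `boundary="wrap"` the PSF is placed
toroidally (a particle near one edge contributes to the opposite edge),
which makes the frame photon sum independent of particle positions —
exactly stationary statistics for correlation analysis — and matches
the cyclic spatial correlation used downstream.  A `disappear` option
exists for realism checks.  Multiplied videos are divided by the global
mean of the wave layer so the output stays on the particle layer's
intensity scale; only relative fluctuations matter to STICS, so this
scaling is cosmetic.

What the simulator deliberately omits: photon (Poisson) noise,
photobleaching, blinking, diffusion, 3D PSFs, and non-rigid motion.
Passing tests on these videos therefore demonstrate correctness of the
estimator on clean rigid flows, not robustness to detection noise or
complex cell-like dynamics.

## STICS engine

For each square ROI (default 32 px side, tiled every 4 px) and sliding
time-of-interest window (default 5 frames, shifted by 1):

1. **Immobile-fraction handling** (`immobile` parameter).  `"series"`
   (default) subtracts each pixel's temporal mean over the *whole*
   movie; `"toi"` subtracts it per window; `"none"` skips it.  The
   whole-series default matters: with slow flows (here ~0.9 px/frame)
   a 5-frame local mean is itself a nearly identical copy of the moving
   pattern, and subtracting it injects ghost correlation structure that
   roughly doubles recovered speeds.  The movie-long mean is far less
   correlated with the instantaneous pattern and leaves velocity
   recovery accurate to a few percent, while still removing genuinely
   static background.

2. **Correlation.**  Per frame the ROI spatial mean is removed
   (δi = i − ⟨i⟩); for each lag τ the cyclic spatial cross-correlation
   of δi_t and δi_{t+τ} is computed by FFT, averaged over all frame
   pairs, and divided by the pixel count.  When every frame's spatial
   mean exceeds a guard (1e−9 × the stack maximum) the pairs are
   additionally divided by ⟨i⟩_t·⟨i⟩_{t+τ}; after immobile subtraction
   the means are ~0, the guard triggers, and the unnormalized
   cross-covariance is used instead — the peak *position*, the only
   quantity entering velocities, is identical either way
   (`normalization_used` records the branch taken per τ).

   A 2D **Hann taper** (overlap-normalized by the window's own cyclic
   autocorrelation, floored at 1e−3 of its maximum) is applied by
   default.  The ROI window truncates structures non-periodically;
   plain cyclic correlation of such windows acquires wrap-edge
   artifacts that systematically pull the peak toward zero lag once the
   structure scale approaches the ROI size — precisely the regime
   created by heavy Gaussian filtering.  On the wave-only benchmark the
   taper removes most of that bias while leaving fine-textured data
   unchanged; `taper="none"` restores the plain estimator for
   cross-checks.

3. **Peak fitting and tracking.**  Each lag slice is fitted with
   `A·exp(−((ξ−ξ₀)² + (η−η₀)²)/w²) + c` over a window of radius
   `peak_search_radius` (default roi_size/4, which also keeps
   displacements below the cyclic-wrap ambiguity).  The fit starts from
   the discrete argmax in the window (first maximum in row-major order,
   i.e. smallest (η, ξ) on ties) with a moment-based width guess.  τ=1
   is searched around zero lag; each later τ within the search radius
   of the previous accepted center (continuity).  Lags whose fit fails
   or wanders out of range are dropped.  The solver is a batched
   Levenberg–Marquardt implementation (analytic Jacobian, multiplicative
   damping, per-fit stall detection) that fits all ROIs of a TOI
   simultaneously as a few hundred array operations; on correlation
   surfaces whose peak is wider than the window the width is barely
   identifiable and a generic solver spends thousands of iterations in
   the degenerate valley for no change in the fitted center.

4. **Velocity.**  Ordinary least squares (with intercept) of ξ₀ and η₀
   against τ ≥ 1; τ = 0 is computed but excluded (its peak sits at zero
   by construction whenever static structure dominates).  Slopes are
   converted via pixel size and frame interval; R² is the mean of the
   two per-axis regression R² values, defined as 1 for an exact fit of
   constant positions so a truly static region scores as a perfect zero
   vector.  Vectors with fewer than `min_lags_for_fit` (default 3)
   tracked lags, R² below `r2_threshold` (default 0.8), or an empty ROI
   (fluctuation amplitude ≤ 1e−12 of the series scale, which absorbs
   the one-ulp residue of mean-subtracting a static movie) are marked
   invalid with `rejection_reason` ∈ {fit_failed, peak_out_of_range,
   low_r2, empty_roi}.  These rejection rules are this package's own
   quality gating.

`analyze` emits exactly one `FlowVector` per ROI per TOI; its batched
internals are checked against the public per-ROI operations on
well-conditioned data by the test suite.

## Summary metrics

The alignment percentage of a vector field against a reference axis is
100 × the median cosine of the angular differences over valid vectors,
kept signed: 100% is perfect alignment, 0% orthogonality, −100%
anti-alignment (an even count takes the midpoint of the two central
cosines).  Speed summaries (mean/median/max, µm/min) also use valid
vectors only.

## Known limitations

* Velocity magnitudes for structures whose spatial scale is comparable
  to the ROI are intrinsically less accurate than for fine-textured
  data: the window truncation that the Hann taper mitigates cannot be
  removed entirely, and residual biases of several percent remain on
  heavily filtered series.
* The Gaussian-filter branch separates superimposed flows cleanly only
  when the blur actually suppresses the fine-scale layer's contrast; at
  low emitter density substantial density fluctuations survive the blur,
  the correlation contains both a broad vertical and a sharp horizontal
  component, and single-Gaussian peak fits land between them.  Raising
  the emitter density (or σ) restores the separation.  The acceptance
  suite documents this regime explicitly.
* Registration handles pure translation only; rotation, scaling and
  non-rigid deformation are out of scope, as are two-color
  cross-correlation, diffusion-coefficient estimation from correlation
  widths, and temporal filtering.
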