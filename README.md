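# sticsflow

Spatial filtering + spatiotemporal image correlation spectroscopy (STICS)
for quantifying **superimposed protein flows** in fluorescence image time
series.

## The problem

Live-cell fluorescence movies often contain two kinds of correlated
intensity fluctuations at the same place and time:

* **contiguous flow** — a labeled structure physically moves, carrying its
  intensity profile with it (e.g. myosin puncta displacing along
  actomyosin bundles, podosomes drifting laterally);
* **noncontiguous flow** — structures stay put while label exchanges
  between neighbors, so a wave of intensity travels across stationary
  structures (e.g. F-actin content oscillations propagating through a
  podosome cluster).

STICS estimates flow by correlating the intensity fluctuations of a small
region of interest (ROI) with the same region at later time lags τ and
tracking the correlation-peak displacement versus τ.  When both flow types
are superimposed, the ensemble correlation mixes them and a single
velocity per ROI cannot represent either.  Because the two processes
usually live on different spatial scales, filtering each frame before
STICS separates them:

* a **Gaussian filter** (σ in pixels) computationally widens the point
  spread function, erasing fine structure so the large-scale traveling
  intensity wave dominates the correlation;
* a **heterogeneity map** (HM) normalizes each pixel to the mean of its
  circular neighborhood, `HM = (I − µ)/µ` with µ the mean under a
  normalized disk kernel.  It accentuates local texture regardless of
  absolute brightness, so structure displacement dominates.

## The estimator

For each ROI (default 32 px, shifted by 4 px) and sliding 5-frame time
window, after immobile-fraction subtraction the correlation

r(ξ, η, τ) = ⟨ δi(x, y, t) · δi(x + ξ, y + η, t + τ) ⟩

is computed by FFT (Hann-tapered, overlap-normalized), a 2D Gaussian
`A·exp(−((ξ−ξ₀)² + (η−η₀)²)/w²) + c` is fitted to the peak of every lag
slice, and the peak displacement is regressed against τ.  The slopes give
the flow velocity: `v [µm/min] = slope [px/frame] × pixel_size × 60 /
frame_interval`.  Vectors failing quality gates (insufficient tracked
lags, regression R² < 0.8, peak outside the search radius) are flagged
invalid with a reason.

A two-layer flow simulator (drifting point emitters + traveling wide-PSF
wave, combined by addition or multiplication, noise-free, with full ground
truth) is included as the built-in source of test data.

## Worked example

```python
from sticsflow import SticsParams, analyze, preset, simulate, summarize

video, truth = simulate(preset("contiguous", seed=1))   # 200 emitters, 30 frames
fields = analyze(video, SticsParams())                  # ROI 32/4, TOI 5/1
vectors = [v for f in fields for v in f.valid_vectors]
s = summarize(vectors)
print(f"valid vectors:   {s.n_valid}")
print(f"mean speed:      {s.mean_speed:.3f} um/min (ground truth {truth.config.drift_speed:.3f})")
print(f"horizontal alignment: {s.alignment_pct_horizontal:.1f}%")
```

prints

```
valid vectors:   5620
mean speed:      0.514 um/min (ground truth 0.500)
horizontal alignment: 99.9%
```

i.e. the emitters drift rightward at 0.5 µm/min and STICS recovers the
speed within ~3% with essentially perfect horizontal alignment (100% =
median cosine of 1 against the 0° axis).

## Command line

```bash
sticsflow simulate --preset mixed-multiply --seed 1 --out video.tif
sticsflow filter video.tif --mode heterogeneity --kernel-diameter 16 --out hm.tif
sticsflow stics hm.tif --roi-size 32 --roi-shift 4 --out vectors.csv
sticsflow metrics vectors.csv --out summary.csv
sticsflow pipeline --preset mixed-multiply --seed 1 --out run1   # all branches
```

`pipeline` analyzes the original, Gaussian-filtered and heterogeneity-map
branches side by side and writes vector CSVs, per-TOI summaries and a
manifest capturing every parameter.

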