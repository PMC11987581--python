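"""Spatial pre-filters applied before STICS.

Two complementary filters act on each frame independently:

* a 2D **Gaussian filter** that computationally widens the point spread
  function, attenuating small-scale structure so that large-scale
  (noncontiguous, intensity-propagation) fluctuations dominate;
* a **heterogeneity map** (HM) that normalizes each pixel to the mean
  intensity of its circular neighborhood, ``HM = (I − µ)/µ``, accentuating
  local texture irrespective of absolute brightness so that small-scale
  (contiguous, structure-displacement) fluctuations dominate.

Pixels brighter than their neighborhood get positive HM values; the map is
invariant under global multiplicative rescaling of the image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ImageSeries

__all__ = [
    "DiskKernel",
    "FilterConfig",
    "make_disk_kernel",
    "local_mean",
    "heterogeneity_map",
    "gaussian_filter",
    "apply_filter",
]

logger = logging.getLogger(__name__)

_BOUNDARY_MODES = {"replicate": "nearest", "zero": "constant"}


@dataclass(frozen=True)
class DiskKernel:
    """Normalized circular averaging kernel.

    A pixel of the kernel lattice belongs to the disk iff the Euclidean
    distance from its center to the kernel center is ≤ diameter/2; all disk
    pixels carry the same weight and the weights sum to 1.  The lattice side
    is the smallest odd integer ≥ diameter.
    """

    diameter: int
    weights: np.ndarray


def make_disk_kernel(diameter: int) -> DiskKernel:
    if not float(diameter).is_integer() or diameter < 1:
        raise ValueError(f"kernel diameter must be a positive integer, got {diameter}")
    diameter = int(diameter)
    side = diameter if diameter % 2 == 1 else diameter + 1
    center = (side - 1) / 2.0
    ii, jj = np.mgrid[0:side, 0:side]
    inside = np.hypot(ii - center, jj - center) <= diameter / 2.0
    weights = inside.astype(float)
    weights /= weights.sum()
    return DiskKernel(diameter=diameter, weights=weights)


@dataclass
class FilterConfig:
    """Parameters of one filtering stage.

    ``mode`` selects the branch; ``gaussian_sigma`` is the Gaussian σ in
    pixels, ``hm_kernel_diameter`` the disk diameter in pixels.  Boundary
    extension is replicate by default ("zero" is available for
    cross-checks).  ``hm_epsilon`` guards the HM division; when ``None`` it
    defaults to 1e−12 × the frame maximum.
    """

    mode: str = "gaussian"  # gaussian | heterogeneity
    gaussian_sigma: float = 7.0
    hm_kernel_diameter: int = 16
    boundary_mode: str = "replicate"
    hm_epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian", "heterogeneity"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.mode == "gaussian" and self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.mode == "heterogeneity" and self.hm_kernel_diameter < 1:
            raise ValueError("hm_kernel_diameter must be ≥ 1")
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


def local_mean(
    frame: np.ndarray, kernel: DiskKernel, boundary_mode: str = "replicate"
) -> np.ndarray:
    """Convolve one frame with the normalized disk kernel.

    Replicate (edge-extend) boundary by default; output shape equals input
    shape.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("local_mean expects a single 2D frame")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    kr, kc = kernel.weights.shape
    if kr > 2 * frame.shape[0] or kc > 2 * frame.shape[1]:
        raise ValueError(
            f"kernel {kernel.weights.shape} too large for frame {frame.shape}"
        )
    return ndimage.convolve(frame, kernel.weights, mode=_BOUNDARY_MODES[boundary_mode])


def heterogeneity_map(
    series: ImageSeries,
    kernel_diameter: int,
    epsilon: float | None = None,
    boundary_mode: str = "replicate",
) -> ImageSeries:
    """Per-frame local-contrast normalization ``HM = (I − µ)/µ``.

    µ is the local mean under the normalized disk kernel.  Pixels whose
    local mean does not exceed the guard ``epsilon`` (default 1e−12 × frame
    max) are set to 0; their count is logged.  The output carries
    provenance ``"heterogeneity"`` and may be negative — pixels dimmer than
    their neighborhood map below zero, brighter pixels above.
    """
    if series.frames.size and series.frames.min() < 0:
        raise ValueError("heterogeneity_map expects a nonnegative series")
    kernel = make_disk_kernel(kernel_diameter)
    mask = (kernel.weights > 0).astype(float)
    n_disk = mask.sum()
    # (I − µ)/µ = (n·I − S)/S with S the disk sum; the numerator is computed
    # as a single convolution with (n·δ_center − mask) so that a spatially
    # uniform frame cancels exactly (integer kernel entries sum to zero)
    diff_kernel = -mask.copy()
    center = (mask.shape[0] - 1) // 2
    diff_kernel[center, center] += n_disk
    mode = _BOUNDARY_MODES[boundary_mode]
    out = np.empty(series.frames.shape, dtype=float)
    n_guarded = 0
    for t in range(series.n_frames):
        frame = series.frames[t].astype(float)
        disk_sum = ndimage.convolve(frame, mask, mode=mode)
        numerator = ndimage.convolve(frame, diff_kernel, mode=mode)
        mu = disk_sum / n_disk
        eps = epsilon if epsilon is not None else 1e-12 * max(frame.max(), 0.0)
        ok = mu > eps
        n_guarded += int((~ok).sum())
        hm = np.zeros_like(frame)
        np.divide(numerator, disk_sum, out=hm, where=ok)
        out[t] = hm
    if n_guarded:
        logger.warning(
            "heterogeneity_map: %d pixel(s) had local mean <= guard; set to 0",
            n_guarded,
        )
    return series.with_frames(out, origin_note="heterogeneity")


def gaussian_filter(
    series: ImageSeries, sigma: float, boundary_mode: str = "replicate"
) -> ImageSeries:
    """Per-frame 2D Gaussian convolution (kernel truncated at 4σ).

    Replicate boundary by default, so constant frames pass through
    unchanged and no dark border is introduced.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = np.empty(series.frames.shape, dtype=float)
    for t in range(series.n_frames):
        out[t] = ndimage.gaussian_filter(
            series.frames[t].astype(float),
            sigma=sigma,
            mode=_BOUNDARY_MODES[boundary_mode],
            truncate=4.0,
        )
    return series.with_frames(out, origin_note="gaussian")


def apply_filter(series: ImageSeries, config: FilterConfig) -> ImageSeries:
    """Dispatch on :class:`FilterConfig.mode`."""
    if config.mode == "gaussian":
        return gaussian_filter(series, config.gaussian_sigma, config.boundary_mode)
    return heterogeneity_map(
        series, config.hm_kernel_diameter, config.hm_epsilon, config.boundary_mode
    )
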