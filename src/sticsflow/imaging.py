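"""Image-series data model, multi-page TIFF I/O and Fourier-based registration.

The central container is :class:`ImageSeries`: a ``(time, row, col)`` intensity
lattice with physical calibration (µm per pixel, seconds per frame) attached
explicitly, never read from TIFF tags.

Coordinate convention used throughout the package: row 0 is the TOP of the
image, ``x`` is the column axis increasing rightward, ``y`` is the row axis
increasing downward.  Vector angles are nevertheless reported mathematically
(0° = +x, counter-clockwise positive), so +90° points toward the top of the
image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageSeries",
    "RegistrationResult",
    "read_tiff_series",
    "write_tiff_series",
    "register_series",
    "crop_roi",
]

#: provenance values an ImageSeries may carry
PROVENANCES = ("raw", "registered", "gaussian", "heterogeneity", "simulated")

#: provenances that must hold nonnegative intensities
_NONNEGATIVE = ("raw", "simulated")


@dataclass
class ImageSeries:
    """A single-channel fluorescence image time series with calibration.

    Parameters
    ----------
    frames
        3D array indexed ``(time, row, col)``; arbitrary linear intensity
        units (photons for simulated data).
    pixel_size
        Lateral calibration in µm per pixel.
    frame_interval
        Temporal calibration in seconds per frame.
    origin_note
        Provenance tag, one of ``raw | registered | gaussian |
        heterogeneity | simulated``.  Only the heterogeneity stage is
        allowed to carry negative values.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    origin_note: str = "raw"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (time, row, col); got ndim={self.frames.ndim}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 µm")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 s")
        if self.origin_note not in PROVENANCES:
            raise ValueError(f"unknown origin_note {self.origin_note!r}")
        if self.origin_note in _NONNEGATIVE and self.frames.size and self.frames.min() < 0:
            raise ValueError(f"{self.origin_note} series must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray, origin_note: str | None = None) -> "ImageSeries":
        """Return a new series with replaced frames, keeping calibration."""
        return replace(
            self, frames=frames, origin_note=origin_note or self.origin_note
        )


@dataclass
class RegistrationResult:
    """Per-frame translations recovered by phase correlation.

    ``shifts[f]`` is the (row, col) displacement of frame ``f`` relative to
    the reference frame, i.e. frame ``f`` looks like the reference rolled by
    ``shifts[f]``.  The reference frame's shift is (0, 0).
    """

    shifts: np.ndarray  # (n_frames, 2), (row, col) in pixels
    reference_index: int
    flagged: list[int] = field(default_factory=list)


def read_tiff_series(path: str | Path, pixel_size: float, frame_interval: float) -> ImageSeries:
    """Read a single-channel multi-page TIFF into an :class:`ImageSeries`.

    Calibration is taken from the arguments; TIFF resolution tags are
    deliberately ignored (tag dialects are unreliable).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        shapes = [p.shape for p in tif.pages]
        if not shapes:
            raise ValueError(f"{path} contains no pages")
        for i, s in enumerate(shapes):
            if len(s) != 2:
                raise ValueError(
                    f"{path} page {i} is not single-channel grayscale (shape {s})"
                )
            if s != shapes[0]:
                raise ValueError(
                    f"{path} page {i} has shape {s}, expected {shapes[0]}"
                )
        frames = tif.asarray()
    if frames.ndim == 2:  # single page
        frames = frames[None]
    origin_note = "raw"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        try:
            recorded = json.loads(sidecar.read_text()).get("provenance")
            if recorded in PROVENANCES:
                origin_note = recorded
        except (json.JSONDecodeError, OSError):
            pass
    return ImageSeries(frames, pixel_size, frame_interval, origin_note=origin_note)


def write_tiff_series(series: ImageSeries, path: str | Path) -> Path:
    """Write one TIFF page per frame plus a JSON calibration sidecar.

    Integer data is written bit-exactly; floating-point data (e.g. filtered
    series, which may be signed) is written as 32-bit float.  The sidecar
    ``<stem>.json`` records pixel size, frame interval and provenance.
    """
    if series.n_frames == 0:
        raise ValueError("refusing to write an empty series")
    path = Path(path)
    data = series.frames
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size_um": series.pixel_size,
                "frame_interval_s": series.frame_interval,
                "provenance": series.origin_note,
            },
            indent=2,
        )
    )
    return path


def _phase_correlation_surface(ref_spec: np.ndarray, frame_spec: np.ndarray) -> np.ndarray:
    """Inverse FFT of the normalized cross-power spectrum.

    Peaks at (dr, dc) when the frame equals the reference cyclically rolled
    by (dr, dc).
    """
    cross = frame_spec * np.conj(ref_spec)
    mag = np.abs(cross)
    # regularized whitening: pure phase normalization lets near-zero
    # high-frequency components dominate for smooth images; the epsilon
    # keeps them down-weighted while preserving the sharp peak
    norm = cross / (mag + 1e-2 * mag.mean() + np.finfo(float).tiny)
    return np.fft.ifft2(norm).real


def _wrap_shift(idx: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    out = np.array(idx, dtype=float)
    for ax in (0, 1):
        if out[ax] > shape[ax] // 2:
            out[ax] -= shape[ax]
    return out


def register_series(
    series: ImageSeries,
    reference_index: int = 0,
    subpixel: bool = False,
) -> tuple[ImageSeries, RegistrationResult]:
    """Translationally register every frame to a single reference frame.

    Integer-pixel phase correlation; each frame is cyclically rolled so its
    correlation peak against the reference sits at zero lag.  With
    ``subpixel=True`` the reported shift is refined by the center of mass of
    the 3×3 neighborhood of the correlation peak (frames are still rolled by
    the rounded shift).  All-zero frames have an undefined correlation; they
    are flagged and assigned shift (0, 0).
    """
    if series.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    if not 0 <= reference_index < series.n_frames:
        raise IndexError("reference_index out of range")

    frames = series.frames.astype(float)
    shape = series.frame_shape
    ref = frames[reference_index]
    ref_zero = not np.any(ref)
    ref_spec = np.fft.fft2(ref)

    shifts = np.zeros((series.n_frames, 2))
    flagged: list[int] = []
    out = np.empty_like(frames)
    for f in range(series.n_frames):
        frame = frames[f]
        if f == reference_index:
            out[f] = frame
            continue
        if ref_zero or not np.any(frame):
            flagged.append(f)
            out[f] = frame
            continue
        surface = _phase_correlation_surface(ref_spec, np.fft.fft2(frame))
        peak = np.unravel_index(int(np.argmax(surface)), shape)
        shift = _wrap_shift(peak, shape)
        if subpixel:
            # center of mass of the 3x3 neighborhood (cyclic indexing),
            # weights lifted to be nonnegative
            rows = (peak[0] + np.arange(-1, 2)) % shape[0]
            cols = (peak[1] + np.arange(-1, 2)) % shape[1]
            win = surface[np.ix_(rows, cols)]
            w = win - win.min()
            if w.sum() > 0:
                dr = float((w.sum(axis=1) * np.arange(-1, 2)).sum() / w.sum())
                dc = float((w.sum(axis=0) * np.arange(-1, 2)).sum() / w.sum())
                shift = shift + np.array([dr, dc])
        shifts[f] = shift
        roll = -np.round(shift).astype(int)
        out[f] = np.roll(frame, roll, axis=(0, 1))

    registered = series.with_frames(out, origin_note="registered")
    return registered, RegistrationResult(shifts, reference_index, flagged)


def crop_roi(
    series: ImageSeries, origin: tuple[int, int], size: tuple[int, int]
) -> ImageSeries:
    """Crop a spatial window (same calibration, all frames)."""
    r0, c0 = origin
    nr, nc = size
    rows, cols = series.frame_shape
    if r0 < 0 or c0 < 0 or nr <= 0 or nc <= 0 or r0 + nr > rows or c0 + nc > cols:
        raise ValueError(
            f"ROI origin {origin} size {size} exceeds frame bounds {(rows, cols)}"
        )
    return series.with_frames(series.frames[:, r0 : r0 + nr, c0 : c0 + nc])
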