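"""Spatiotemporal image correlation spectroscopy (STICS) engine.

For every spatial region of interest (ROI) and sliding time-of-interest
(TOI) window the engine

1. subtracts the immobile fraction (each pixel's temporal mean over the
   TOI),
2. computes the spatiotemporal correlation function
   ``r(ξ, η, τ)`` — the average over frame pairs ``(t, t+τ)`` of the cyclic
   spatial cross-correlation of the intensity fluctuations,
3. fits a 2D Gaussian to the correlation peak at each time lag τ and tracks
   the peak from lag to lag under a continuity constraint,
4. regresses the peak displacement against τ; the slopes, converted with
   the pixel size and frame interval, are the flow velocity components.

Conventions: ξ is the column (x) lag, η the row lag; velocities are
reported with ``vy`` positive toward the TOP of the image so that angles
follow the usual mathematical convention (0° = rightward, +90° = up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .imaging import ImageSeries

__all__ = [
    "SticsParams",
    "CorrelationFunction",
    "PeakFit",
    "FlowVector",
    "VectorField",
    "tile_rois",
    "subtract_immobile",
    "correlation_function",
    "fit_gaussian_peak",
    "track_peaks",
    "velocity_from_peaks",
    "analyze",
    "fields_to_dataframe",
]

#: fraction of the stack maximum below which a spatial mean is considered
#: zero and the unnormalized cross-covariance is used instead
_NORMALIZATION_GUARD = 1e-9


@dataclass
class SticsParams:
    """Analysis parameters.

    Defaults follow the reference analysis settings: 32 px ROIs shifted by
    4 px, 5-frame TOIs shifted by 1 frame, time lags 1…4.  Vector rejection
    (``min_lags_for_fit``, ``r2_threshold``, ``peak_search_radius``) is this
    package's own quality gating.

    ``immobile`` selects the immobile-fraction subtraction: ``"series"``
    (default) removes each pixel's temporal mean over the whole movie,
    ``"toi"`` removes it per TOI window, ``"none"`` skips it.  The
    whole-series mean is preferred because a short TOI mean still contains
    a strongly correlated copy of any slowly moving pattern and biases the
    recovered displacement.
    """

    roi_size: int = 32
    roi_shift: int = 4
    toi_size: int = 5
    toi_shift: int = 1
    max_lag: int | None = None  # default: toi_size − 1
    immobile: str = "series"  # series | toi | none
    normalize: bool = True
    taper: str = "hann"  # hann | none
    min_lags_for_fit: int = 3
    r2_threshold: float = 0.8
    peak_search_radius: float | None = None  # default: roi_size / 4

    def __post_init__(self) -> None:
        if self.roi_size < 2 or self.roi_shift < 1:
            raise ValueError("roi_size must be ≥ 2 and roi_shift ≥ 1")
        if self.toi_size < 2 or self.toi_shift < 1:
            raise ValueError("toi_size must be ≥ 2 and toi_shift ≥ 1")
        if self.max_lag is None:
            self.max_lag = self.toi_size - 1
        if not 1 <= self.max_lag <= self.toi_size - 1:
            raise ValueError("need 1 ≤ max_lag ≤ toi_size − 1")
        if self.min_lags_for_fit < 2:
            raise ValueError("min_lags_for_fit must be ≥ 2")
        if self.immobile not in ("series", "toi", "none"):
            raise ValueError(f"unknown immobile mode {self.immobile!r}")
        if self.taper not in ("hann", "none"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.peak_search_radius is None:
            self.peak_search_radius = self.roi_size / 4.0


@dataclass
class CorrelationFunction:
    """The r(ξ, η, τ) lattice for one ROI/TOI.

    ``values[τ]`` is a centered 2D lag map: index ``(i, j)`` corresponds to
    lags ``η = i − rows//2`` and ``ξ = j − cols//2``.
    """

    values: np.ndarray  # (max_lag+1, roi, roi)
    roi_origin: tuple[int, int]
    toi_start: int
    normalization_used: list[bool]
    empty: bool = False

    @property
    def max_lag(self) -> int:
        return self.values.shape[0] - 1

    @property
    def center(self) -> tuple[int, int]:
        return self.values.shape[1] // 2, self.values.shape[2] // 2


@dataclass
class PeakFit:
    """Result of a 2D Gaussian fit to one correlation lag slice."""

    center: tuple[float, float]  # (ξ0, η0) in lag pixels, subpixel
    amplitude: float
    width: float
    offset: float
    residual_norm: float
    converged: bool


@dataclass
class FlowVector:
    """One velocity estimate at an ROI center.

    Positions are µm from the top-left frame corner (y downward); ``vy``
    is µm/min positive toward the top of the image, so ``angle`` is the
    mathematical angle of (vx, vy).
    """

    position: tuple[float, float]  # (x, y) µm
    time: float  # s at TOI center
    vx: float  # µm/min
    vy: float  # µm/min, up-positive
    speed: float
    angle: float  # degrees
    r2: float
    valid: bool
    rejection_reason: str = "none"  # none|fit_failed|low_r2|peak_out_of_range|empty_roi


@dataclass
class VectorField:
    """All ROI vectors of one TOI."""

    vectors: list[FlowVector]
    params: SticsParams
    toi_index: int
    toi_start: int
    provenance: str = "raw"

    @property
    def valid_vectors(self) -> list[FlowVector]:
        return [v for v in self.vectors if v.valid]


def tile_rois(
    frame_dims: tuple[int, int], roi_size: int, roi_shift: int
) -> list[tuple[int, int]]:
    """ROI origins at 0, shift, 2·shift, … with origin + size ≤ dim, row-major."""
    rows, cols = frame_dims
    if roi_size > rows or roi_size > cols:
        raise ValueError(f"roi_size {roi_size} exceeds frame dims {frame_dims}")
    r_origins = range(0, rows - roi_size + 1, roi_shift)
    c_origins = range(0, cols - roi_size + 1, roi_shift)
    return [(r, c) for r in r_origins for c in c_origins]


def subtract_immobile(roi_stack: np.ndarray) -> np.ndarray:
    """Remove each pixel's temporal mean over the TOI (immobile fraction)."""
    stack = np.asarray(roi_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (time ≥ 2, rows, cols) stack")
    return stack - stack.mean(axis=0, keepdims=True)


@lru_cache(maxsize=8)
def _taper_window(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann taper and its (floored) cyclic autocorrelation, cached by shape."""
    w = np.outer(np.hanning(rows), np.hanning(cols))
    spec = np.fft.fft2(w)
    ww = np.fft.ifft2(spec * np.conj(spec)).real
    # the autocorrelation vanishes toward extreme lags; floor it so the
    # overlap normalization cannot blow up numerical noise there
    ww = np.maximum(ww, 1e-3 * ww.max())
    return w, ww


def correlation_function(
    roi_stack: np.ndarray,
    max_lag: int,
    normalize: bool = True,
    taper: str = "hann",
    roi_origin: tuple[int, int] = (0, 0),
    toi_start: int = 0,
) -> CorrelationFunction:
    """Spatiotemporal correlation of one ROI stack via FFTs.

    For each lag τ the cyclic spatial cross-correlation of the per-frame
    fluctuations δi_t = i_t − ⟨i⟩_t is averaged over all frame pairs
    ``(t, t+τ)`` and divided by the pixel count; when ``normalize`` is on
    and both spatial means exceed a guard each pair is additionally divided
    by ``⟨i⟩_t · ⟨i⟩_{t+τ}`` (otherwise the unnormalized cross-covariance is
    kept and recorded in ``normalization_used``).  A rightward-moving
    pattern peaks at positive ξ for τ > 0.

    ``taper="hann"`` (default) multiplies the fluctuations by a 2D Hann
    window and divides the correlation by the window's own cyclic
    autocorrelation.  The ROI window truncates structures non-periodically;
    without tapering the resulting wrap-around edge artifacts systematically
    pull the correlation peak toward zero lag for structures whose spatial
    scale approaches the ROI size (e.g. heavily Gaussian-filtered series).
    ``taper="none"`` gives the plain cyclic estimator.
    """
    stack = np.asarray(roi_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("roi_stack must be (time, rows, cols)")
    if taper not in ("hann", "none"):
        raise ValueError(f"unknown taper {taper!r}")
    n_t, rows, cols = stack.shape
    if not 1 <= max_lag < n_t:
        raise ValueError("need 1 ≤ max_lag < number of frames")

    means = stack.mean(axis=(1, 2))
    delta = stack - means[:, None, None]
    empty = not np.any(delta) and not np.any(stack)
    guard = _NORMALIZATION_GUARD * max(np.abs(stack).max(), np.finfo(float).tiny)
    if taper == "hann":
        win, overlap = _taper_window(rows, cols)
        delta = delta * win
    else:
        overlap = float(rows * cols)
    spectra = np.fft.fft2(delta)

    values = np.empty((max_lag + 1, rows, cols))
    normalization_used: list[bool] = []
    for tau in range(max_lag + 1):
        # peak of ifft2(F_{t+τ}·conj(F_t)) sits at the displacement of
        # frame t+τ relative to frame t
        pair = np.fft.ifft2(
            spectra[tau:] * np.conj(spectra[: n_t - tau])
        ).real / overlap
        use_norm = bool(normalize and np.all(means > guard))
        if use_norm:
            denom = means[tau:] * means[: n_t - tau]
            pair = pair / denom[:, None, None]
        values[tau] = np.fft.fftshift(pair.mean(axis=0))
        normalization_used.append(use_norm)

    return CorrelationFunction(
        values=values,
        roi_origin=roi_origin,
        toi_start=toi_start,
        normalization_used=normalization_used,
        empty=empty,
    )


def _window_center(init_rc, rad, shape):
    """Clamp a requested window center so a (2*rad+1)**2 window fits the lattice."""
    rows, cols = shape
    ci = min(max(int(init_rc[0]), rad), rows - 1 - rad)
    cj = min(max(int(init_rc[1]), rad), cols - 1 - rad)
    return ci, cj


def _lm_gauss_batch(
    z: np.ndarray, xs: np.ndarray, ys: np.ndarray, n_iter: int = 40
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Levenberg-Marquardt fit of ``A*exp(-d^2/w^2) + c``.

    ``z`` is (n_fits, n_points); ``xs``/``ys`` are the shared sample
    coordinates relative to the window center.  Returns the parameter
    array (n_fits, 5) ordered (amp, x0, y0, w, offset) with centers
    relative to the window center, the final and initial costs, and a
    success mask (cost did not increase, positive amplitude and width).

    A fixed iteration count with a per-fit damping schedule is used: the
    surfaces here are small (a few hundred points) and many are nearly
    degenerate (peak wider than the window), where classic LM burns
    thousands of evaluations refining an unidentifiable width.  Batching
    across ROIs makes the whole lag-slice fit a handful of array ops.
    """
    n, n_pts = z.shape
    base = np.median(z, axis=1)
    amp0 = z.max(axis=1) - base
    imax = np.argmax(z, axis=1)  # row-major first max = smallest (eta, xi)
    u0, v0 = xs[imax], ys[imax]
    mass = np.clip(z - base[:, None], 0.0, None)
    msum = mass.sum(axis=1)
    d2 = (xs[None, :] - u0[:, None]) ** 2 + (ys[None, :] - v0[:, None]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = np.sqrt(2.0 * (mass * d2).sum(axis=1) / np.maximum(msum, 1e-300))
    w0 = np.where(msum > 0, w0, 2.0)
    half_span = max(float(xs.max()), float(ys.max()), 1.0)
    w0 = np.clip(w0, 1.0, 2.0 * half_span)

    p = np.column_stack([amp0, u0, v0, w0, base])
    lam = np.full(n, 1e-2)

    def _residual(params: np.ndarray) -> np.ndarray:
        a, x0, y0, w, c = params.T
        w2 = np.maximum(w * w, 1e-12)[:, None]
        e = np.exp(-(((xs[None, :] - x0[:, None]) ** 2
                      + (ys[None, :] - y0[:, None]) ** 2) / w2))
        return a[:, None] * e + c[:, None] - z

    r = _residual(p)
    cost = (r * r).sum(axis=1)
    cost0 = cost.copy()
    eye = np.eye(5)
    stale = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        a, x0, y0, w, _c = p.T
        w2 = np.maximum(w * w, 1e-12)
        dx = xs[None, :] - x0[:, None]
        dy = ys[None, :] - y0[:, None]
        d2 = dx * dx + dy * dy
        e = np.exp(-d2 / w2[:, None])
        ae = a[:, None] * e
        jac = np.stack(
            [
                e,
                ae * 2.0 * dx / w2[:, None],
                ae * 2.0 * dy / w2[:, None],
                ae * 2.0 * d2 / (np.maximum(np.abs(w), 1e-6) ** 3)[:, None],
                np.ones_like(e),
            ],
            axis=2,
        )  # (n, n_pts, 5)
        g = np.einsum("np,npk->nk", r, jac)
        h = np.einsum("npk,npl->nkl", jac, jac)
        damped = h + lam[:, None, None] * (
            np.einsum("nkk->nk", h)[:, :, None] * eye + 1e-12 * eye
        )
        try:
            step = -np.linalg.solve(damped, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.solve(damped + 1e-9 * eye, g[..., None])[..., 0]
        p_try = p + step
        r_try = _residual(p_try)
        cost_try = (r_try * r_try).sum(axis=1)
        # fits that have stalled twice are frozen so each item's LM
        # trajectory is independent of what the rest of the batch does
        active = stale < 2
        better = active & np.isfinite(cost_try) & (cost_try < cost)
        p = np.where(better[:, None], p_try, p)
        r = np.where(better[:, None], r_try, r)
        improvement = np.where(better, 1.0 - cost_try / np.maximum(cost, 1e-300), 0.0)
        cost = np.where(better, cost_try, cost)
        lam = np.where(active, np.where(better, lam * 0.33, lam * 6.0), lam)
        stale = np.where(improvement < 1e-10, stale + 1, 0)
        if not np.any(stale < 2):
            break
    p[:, 3] = np.abs(p[:, 3])
    ok = (p[:, 0] > 0) & (p[:, 3] > 0) & np.isfinite(cost) & (cost <= cost0)
    return p, cost, cost0, ok


def _fit_coords(rad: int) -> tuple[np.ndarray, np.ndarray]:
    span = np.arange(-rad, rad + 1, dtype=float)
    xs = np.tile(span, 2 * rad + 1)
    ys = np.repeat(span, 2 * rad + 1)
    return xs, ys


def fit_gaussian_peak(
    corr_slice: np.ndarray,
    init_center: tuple[float, float] = (0.0, 0.0),
    search_radius: float = 8.0,
) -> PeakFit:
    """Fit ``A*exp(-((xi-xi0)^2 + (eta-eta0)^2)/w^2) + c`` near ``init_center``.

    The fit window has radius ``search_radius`` around ``init_center``
    (lag coordinates, clamped so the window fits the lattice); the
    optimizer starts from the discrete argmax within that window (first
    maximum in row-major order, i.e. smallest (eta, xi) on ties) with a
    moment-based width guess.  Non-convergence, a non-positive fitted
    amplitude or width, or a center escaping the lag lattice all yield
    ``converged=False``.
    """
    corr_slice = np.asarray(corr_slice, dtype=float)
    if not np.all(np.isfinite(corr_slice)):
        raise ValueError("correlation slice contains non-finite values")
    rows, cols = corr_slice.shape
    cr, cc = rows // 2, cols // 2
    rad = min(int(np.ceil(search_radius)), (rows - 1) // 2, (cols - 1) // 2)
    if rad < 1:
        return PeakFit((np.nan, np.nan), np.nan, np.nan, np.nan, np.inf, False)

    ci, cj = _window_center(
        (int(round(init_center[1])) + cr, int(round(init_center[0])) + cc),
        rad, (rows, cols),
    )
    window = corr_slice[ci - rad : ci + rad + 1, cj - rad : cj + rad + 1]

    if window.size == 0 or np.ptp(window) == 0:
        # constant window: degenerate model
        return PeakFit((np.nan, np.nan), np.nan, np.nan, np.nan, np.inf, False)

    xs, ys = _fit_coords(rad)
    p, cost, _cost0, ok = _lm_gauss_batch(window.reshape(1, -1), xs, ys)
    amp, u, v, w, offset = p[0]
    xi0 = float(u + cj - cc)
    eta0 = float(v + ci - cr)
    resid = float(np.sqrt(cost[0]))
    in_lattice = (-cc <= xi0 <= cols - 1 - cc) and (-cr <= eta0 <= rows - 1 - cr)
    converged = bool(ok[0]) and in_lattice
    return PeakFit((xi0, eta0), float(amp), float(w), float(offset), resid, converged)


def track_peaks(
    corr: CorrelationFunction, params: SticsParams
) -> tuple[list[tuple[int, tuple[float, float]]], list[str]]:
    """Follow the correlation peak across time lags τ = 1…max_lag.

    τ = 1 is searched around zero lag; each subsequent lag is searched
    within ``peak_search_radius`` of the previously accepted center
    (continuity constraint).  Lags whose fit fails, or whose fitted center
    leaves the search window, are dropped.  Returns the surviving
    ``(τ, (ξ₀, η₀))`` centers and the drop reasons.
    """
    radius = float(params.peak_search_radius)
    centers: list[tuple[int, tuple[float, float]]] = []
    reasons: list[str] = []
    prev = (0.0, 0.0)
    for tau in range(1, corr.max_lag + 1):
        fit = fit_gaussian_peak(corr.values[tau], init_center=prev, search_radius=radius)
        if not fit.converged:
            reasons.append("fit_failed")
            continue
        if np.hypot(fit.center[0] - prev[0], fit.center[1] - prev[1]) > radius:
            reasons.append("peak_out_of_range")
            continue
        centers.append((tau, fit.center))
        prev = fit.center
    return centers, reasons


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line with intercept; returns (slope, R²).

    R² is defined as 1 for an exact fit even when ``y`` is constant (zero
    total variance), so a perfectly static peak scores as a perfect zero
    velocity rather than an undefined one.
    """
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-20:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), r2


def velocity_from_peaks(
    peaks: list[tuple[int, tuple[float, float]]],
    pixel_size: float,
    frame_interval: float,
) -> tuple[float, float, float]:
    """OLS line (with intercept) of peak position vs τ, converted to µm/min.

    Returns ``(vx, vy, r2)`` with ``vy`` up-positive; ``r2`` is the mean of
    the two per-axis regression R² values.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peak centers for a velocity fit")
    taus = np.array([t for t, _ in peaks], dtype=float)
    xis = np.array([c[0] for _, c in peaks], dtype=float)
    etas = np.array([c[1] for _, c in peaks], dtype=float)

    to_um_min = pixel_size * 60.0 / frame_interval
    slope_xi, r2x = _ols_line(taus, xis)
    slope_eta, r2y = _ols_line(taus, etas)
    vx = slope_xi * to_um_min
    vy = -slope_eta * to_um_min  # row lag grows downward; vy is up-positive
    return vx, vy, (r2x + r2y) / 2.0


def _invalid_vector(position, time, reason) -> FlowVector:
    return FlowVector(
        position=position, time=time, vx=np.nan, vy=np.nan, speed=np.nan,
        angle=np.nan, r2=np.nan, valid=False, rejection_reason=reason,
    )


def _batch_correlation(
    stacks: np.ndarray, max_lag: int, normalize: bool, taper: str
) -> np.ndarray:
    """Correlation lattices for many ROI stacks at once (same math as
    :func:`correlation_function`, vectorized over the ROI axis)."""
    n, n_t, rows, cols = stacks.shape
    means = stacks.mean(axis=(2, 3))
    delta = stacks - means[:, :, None, None]
    if taper == "hann":
        win, overlap = _taper_window(rows, cols)
        delta = delta * win
    else:
        overlap = float(rows * cols)
    spectra = np.fft.fft2(delta)
    guard = _NORMALIZATION_GUARD * np.maximum(
        np.abs(stacks).max(axis=(1, 2, 3)), np.finfo(float).tiny
    )
    use_norm = normalize & np.all(means > guard[:, None], axis=1)
    values = np.empty((n, max_lag + 1, rows, cols))
    for tau in range(max_lag + 1):
        pair = np.fft.ifft2(
            spectra[:, tau:] * np.conj(spectra[:, : n_t - tau])
        ).real / overlap
        denom = np.where(
            use_norm[:, None], means[:, tau:] * means[:, : n_t - tau], 1.0
        )
        pair = pair / denom[:, :, None, None]
        values[:, tau] = np.fft.fftshift(pair.mean(axis=1), axes=(-2, -1))
    return values


def _track_batch(
    values: np.ndarray, params: SticsParams
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorized peak tracking over many ROIs.

    ``values`` is (n_rois, max_lag+1, rows, cols).  Returns per-ROI,
    per-lag fitted centers ``xi`` and ``eta`` (NaN where the lag was
    dropped) and the first drop reason per ROI (empty string if none).
    """
    n, n_lags, rows, cols = values.shape
    max_lag = n_lags - 1
    cr, cc = rows // 2, cols // 2
    radius = float(params.peak_search_radius)
    rad = min(int(np.ceil(radius)), (rows - 1) // 2, (cols - 1) // 2)
    xs, ys = _fit_coords(rad)
    span = np.arange(-rad, rad + 1)

    prev_xi = np.zeros(n)
    prev_eta = np.zeros(n)
    xi = np.full((n, max_lag), np.nan)
    eta = np.full((n, max_lag), np.nan)
    reasons = [""] * n
    idx = np.arange(n)
    for tau in range(1, max_lag + 1):
        ci = np.clip(np.round(prev_eta).astype(int) + cr, rad, rows - 1 - rad)
        cj = np.clip(np.round(prev_xi).astype(int) + cc, rad, cols - 1 - rad)
        windows = values[
            idx[:, None, None], tau, (ci[:, None] + span)[:, :, None],
            (cj[:, None] + span)[:, None, :],
        ].reshape(n, -1)
        const = np.ptp(windows, axis=1) == 0
        p, _cost, _cost0, ok = _lm_gauss_batch(windows, xs, ys)
        fit_xi = p[:, 1] + (cj - cc)
        fit_eta = p[:, 2] + (ci - cr)
        in_lattice = (
            (fit_xi >= -cc) & (fit_xi <= cols - 1 - cc)
            & (fit_eta >= -cr) & (fit_eta <= rows - 1 - cr)
        )
        near = np.hypot(fit_xi - prev_xi, fit_eta - prev_eta) <= radius
        good_fit = ok & ~const & in_lattice
        accept = good_fit & near
        xi[accept, tau - 1] = fit_xi[accept]
        eta[accept, tau - 1] = fit_eta[accept]
        prev_xi = np.where(accept, fit_xi, prev_xi)
        prev_eta = np.where(accept, fit_eta, prev_eta)
        for i in np.nonzero(~accept)[0]:
            if not reasons[i]:
                reasons[i] = "fit_failed" if not good_fit[i] else "peak_out_of_range"
    return xi, eta, reasons


def analyze(series: ImageSeries, params: SticsParams | None = None) -> list[VectorField]:
    """Run the full STICS pipeline; one :class:`VectorField` per TOI.

    Every ROI position yields exactly one :class:`FlowVector`; vectors
    failing the quality gates carry ``valid=False`` and a rejection
    reason.  All ROIs of a TOI are correlated and fitted as one batch;
    the math is identical to composing :func:`correlation_function`,
    :func:`track_peaks` and :func:`velocity_from_peaks` per ROI.
    """
    params = params or SticsParams()
    frames = series.frames.astype(float)
    n_frames = frames.shape[0]
    if n_frames < params.toi_size:
        raise ValueError(
            f"series has {n_frames} frames; need >= toi_size = {params.toi_size}"
        )
    intensity_scale = np.abs(frames).max() if frames.size else 0.0
    if params.immobile == "series":
        # subtracting the whole-movie temporal mean removes the static
        # background while staying nearly uncorrelated with the moving
        # pattern; a short per-TOI mean would itself contain a strongly
        # correlated copy of the pattern and bias the peak displacement
        frames = frames - frames.mean(axis=0, keepdims=True)

    origins = tile_rois(series.frame_shape, params.roi_size, params.roi_shift)
    n_rois = len(origins)
    half_roi = params.roi_size / 2.0
    positions = [
        ((c0 + half_roi) * series.pixel_size, (r0 + half_roi) * series.pixel_size)
        for (r0, c0) in origins
    ]
    to_um_min = series.pixel_size * 60.0 / series.frame_interval

    fields: list[VectorField] = []
    toi_starts = range(0, n_frames - params.toi_size + 1, params.toi_shift)
    for toi_index, t0 in enumerate(toi_starts):
        toi = frames[t0 : t0 + params.toi_size]
        stacks = np.stack(
            [
                toi[:, r0 : r0 + params.roi_size, c0 : c0 + params.roi_size]
                for (r0, c0) in origins
            ]
        )
        if params.immobile == "toi":
            stacks = stacks - stacks.mean(axis=1, keepdims=True)
        # relative threshold: mean subtraction of a static movie leaves
        # one-ulp residues that must still count as an empty ROI
        nonempty = np.abs(stacks).max(axis=(1, 2, 3)) > 1e-12 * intensity_scale
        time = (t0 + params.toi_size / 2.0) * series.frame_interval

        values = _batch_correlation(
            stacks, params.max_lag, params.normalize, params.taper
        )
        xi, eta, reasons = _track_batch(values, params)

        vectors: list[FlowVector] = []
        for i in range(n_rois):
            if not nonempty[i]:
                vectors.append(_invalid_vector(positions[i], time, "empty_roi"))
                continue
            have = ~np.isnan(xi[i])
            if have.sum() < params.min_lags_for_fit:
                vectors.append(
                    _invalid_vector(positions[i], time, reasons[i] or "fit_failed")
                )
                continue
            taus = np.nonzero(have)[0] + 1.0
            sx, r2x = _ols_line(taus, xi[i][have])
            se, r2y = _ols_line(taus, eta[i][have])
            vx = sx * to_um_min
            vy = -se * to_um_min
            r2 = (r2x + r2y) / 2.0
            speed = float(np.hypot(vx, vy))
            angle = float(np.degrees(np.arctan2(vy, vx)))
            valid = r2 >= params.r2_threshold
            vectors.append(
                FlowVector(positions[i], time, vx, vy, speed, angle, r2,
                           valid=valid,
                           rejection_reason="none" if valid else "low_r2")
            )
        fields.append(
            VectorField(vectors=vectors, params=params, toi_index=toi_index,
                        toi_start=t0, provenance=series.origin_note)
        )
    return fields


def fields_to_dataframe(fields: list[VectorField]) -> pd.DataFrame:
    """Flatten vector fields into the standard CSV layout."""
    records = []
    for field_ in fields:
        for v in field_.vectors:
            records.append(
                {
                    "toi_index": field_.toi_index,
                    "time_s": v.time,
                    "x_um": v.position[0],
                    "y_um": v.position[1],
                    "vx_um_min": v.vx,
                    "vy_um_min": v.vy,
                    "speed_um_min": v.speed,
                    "angle_deg": v.angle,
                    "r2": v.r2,
                    "valid": v.valid,
                    "rejection_reason": v.rejection_reason,
                }
            )
    return pd.DataFrame.from_records(records)
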