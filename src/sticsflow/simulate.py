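"""Two-layer fluorescence flow simulator.

Generates noise-free synthetic videos containing two superimposed flow
types with full ground truth:

* a **contiguous layer**: point emitters (Gaussian PSF, 1/e² intensity
  radius ``psf_e2_radius``) scattered uniformly over the canvas and drifting
  rigidly at constant speed — structure displacement;
* a **noncontiguous layer**: wide-PSF emitters seeded on a horizontal line
  one third of the canvas up from the bottom, whose rendered envelope
  translates vertically — a traveling intensity wave over stationary
  structures when superimposed on the first layer.

Layers are combined by addition or multiplication.  Default parameter
values describe the reference study conditions: 100×100 px canvas at
0.14 µm/px, 200 drifting particles with a 0.5 µm 1/e² PSF radius emitting
400 photons/s each, drifting rightward at 0.5 µm/min; 100 wave particles
with a 2 µm PSF radius moving upward at 0.5 µm/min; 30 frames at 15 s
intervals, 1 s exposure, no photon noise, no bleaching or blinking.

Positions are continuous (x, y) coordinates in µm, x increasing rightward
(columns) and y increasing downward (rows); directions are mathematical
angles in degrees (0° = rightward, +90° = upward, i.e. toward row 0).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .imaging import ImageSeries

__all__ = [
    "SimulationConfig",
    "ParticleLayer",
    "SimulationTruth",
    "preset",
    "init_particles",
    "advance_particles",
    "render_frame",
    "combine_layers",
    "simulate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full ground-truth description of a synthetic two-layer video."""

    canvas: tuple[int, int] = (100, 100)  # (rows, cols) px
    pixel_size: float = 0.14  # µm / px
    n_particles: int = 200
    psf_e2_radius: float = 0.5  # µm, 1/e² intensity radius
    photon_rate: float = 400.0  # photons/s per particle (PSF integral)
    drift_speed: float = 0.5  # µm/min
    drift_direction: float = 0.0  # degrees, 0 = rightward
    wave_n_particles: int = 100
    wave_psf_radius: float = 2.0  # µm
    wave_line_fraction: float = 1.0 / 3.0  # of canvas height, from the bottom
    wave_speed: float = 0.5  # µm/min
    wave_direction: float = 90.0  # degrees, +90 = upward
    combine_mode: str = "none"  # none | add | multiply
    n_frames: int = 30
    frame_interval: float = 15.0  # s
    exposure: float = 1.0  # s
    seed: int = 0
    boundary: str = "wrap"  # wrap | disappear

    def __post_init__(self) -> None:
        rows, cols = self.canvas
        if rows < 1 or cols < 1:
            raise ValueError("canvas must be at least 1×1 px")
        for name in ("pixel_size", "psf_e2_radius", "photon_rate", "frame_interval",
                     "exposure", "wave_psf_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.drift_speed < 0 or self.wave_speed < 0:
            raise ValueError("speeds must be ≥ 0")
        if not 0 < self.wave_line_fraction < 1:
            raise ValueError("wave_line_fraction must lie in (0, 1)")
        if self.combine_mode not in ("none", "add", "multiply"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if self.combine_mode == "multiply" and (
            self.n_particles < 1 or self.wave_n_particles < 1
        ):
            raise ValueError("combine_mode='multiply' requires both layers enabled")
        if self.combine_mode == "none" and self.n_particles > 0 and self.wave_n_particles > 0:
            raise ValueError(
                "combine_mode='none' allows only one enabled layer; "
                "use 'add' or 'multiply' for superpositions"
            )
        if self.boundary not in ("wrap", "disappear"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the canvas in µm."""
        return self.canvas[1] * self.pixel_size, self.canvas[0] * self.pixel_size


_PRESETS = {
    # contiguous-only: drifting point emitters, no wave layer
    "contiguous": dict(combine_mode="none", wave_n_particles=0),
    # wave-only: traveling wide-PSF intensity wave
    "wave": dict(combine_mode="none", n_particles=0),
    # both layers superimposed
    "mixed-multiply": dict(combine_mode="multiply"),
    "mixed-add": dict(combine_mode="add"),
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named study-condition presets.

    ``contiguous`` / ``wave`` / ``mixed-multiply`` / ``mixed-add``, all
    sharing the reference defaults of :class:`SimulationConfig`.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, **kwargs)


@dataclass
class ParticleLayer:
    """Continuous emitter positions (µm, not snapped to pixels)."""

    positions: np.ndarray  # (n, 2) columns (x, y) in µm; y increases downward
    photon_rate: float  # photons/s per particle
    psf_radius: float  # µm, 1/e² intensity radius


def init_particles(
    config: SimulationConfig, layer: str, rng: np.random.Generator
) -> ParticleLayer:
    """Seed one layer's emitters.

    ``main``: uniform over the canvas area.  ``wave``: x uniform over the
    canvas width, y fixed on the horizontal line ``wave_line_fraction`` of
    the canvas height up from the bottom edge.
    """
    width, height = config.extent
    if layer == "main":
        n = config.n_particles
        pos = np.column_stack(
            [rng.uniform(0.0, width, n), rng.uniform(0.0, height, n)]
        )
        return ParticleLayer(pos, config.photon_rate, config.psf_e2_radius)
    if layer == "wave":
        n = config.wave_n_particles
        y = (1.0 - config.wave_line_fraction) * height
        pos = np.column_stack([rng.uniform(0.0, width, n), np.full(n, y)])
        return ParticleLayer(pos, config.photon_rate, config.wave_psf_radius)
    raise ValueError(f"unknown layer {layer!r}")


def advance_particles(
    layer: ParticleLayer,
    speed: float,
    direction: float,
    dt: float,
    extent: tuple[float, float] | None = None,
    boundary: str = "wrap",
) -> ParticleLayer:
    """Displace every emitter by ``speed·dt/60`` along ``direction``.

    Angles follow the mathematical convention with y increasing downward,
    so +90° decreases y (moves toward the top).  With ``boundary="wrap"``
    positions wrap cyclically over the canvas extent; with ``"disappear"``
    they are left to exit (and simply stop contributing light).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    step = speed * dt / 60.0
    theta = np.deg2rad(direction)
    disp = np.array([step * np.cos(theta), -step * np.sin(theta)])
    pos = layer.positions + disp
    if boundary == "wrap":
        if extent is None:
            raise ValueError("wrap boundary requires the canvas extent")
        pos = np.mod(pos, np.asarray(extent))
    return replace(layer, positions=pos)


def render_frame(layer: ParticleLayer, config: SimulationConfig) -> np.ndarray:
    """Render one noise-free frame of a layer in photons.

    Each emitter contributes ``A·exp(−2 d²/r²)`` sampled at pixel centers,
    with ``A`` set so the continuous 2D integral equals
    ``photon_rate × exposure`` (the Gaussian integrates to ``π r²/2``).
    Contributions add linearly.  Under ``boundary="wrap"`` the PSF is
    placed toroidally so the frame photon sum does not depend on emitter
    position; under ``"disappear"`` plain Euclidean distances are used and
    off-canvas emitters contribute only their on-canvas tail.
    """
    rows, cols = config.canvas
    frame = np.zeros((rows, cols))
    if layer.positions.shape[0] == 0:
        return frame
    px = config.pixel_size
    width, height = config.extent
    r = layer.psf_radius
    amplitude = 2.0 * layer.photon_rate * config.exposure / (np.pi * r * r)

    xc = (np.arange(cols) + 0.5) * px  # pixel-center x, µm
    yc = (np.arange(rows) + 0.5) * px
    dx = xc[None, :] - layer.positions[:, 0][:, None]  # (n, cols)
    dy = yc[None, :] - layer.positions[:, 1][:, None]  # (n, rows)
    if config.boundary == "wrap":
        dx = (dx + width / 2.0) % width - width / 2.0
        dy = (dy + height / 2.0) % height - height / 2.0
    gx = np.exp(-2.0 * dx**2 / (r * r))
    gy = np.exp(-2.0 * dy**2 / (r * r))
    # separable Gaussian: frame = Σ_n gy_n ⊗ gx_n
    frame = np.einsum("nr,nc->rc", gy, gx)
    return frame * amplitude * px * px


def combine_layers(a: ImageSeries, b: ImageSeries, mode: str) -> ImageSeries:
    """Frame-wise sum or product of two co-registered layer videos.

    ``multiply`` divides the raw product (photons²) by the global mean of
    layer ``b`` so the output stays on layer ``a``'s intensity scale; STICS
    only sees relative fluctuations, so this scale choice is cosmetic.
    """
    if a.frames.shape != b.frames.shape:
        raise ValueError("layer shapes differ")
    if a.pixel_size != b.pixel_size or a.frame_interval != b.frame_interval:
        raise ValueError("layer calibrations differ")
    if mode == "add":
        frames = a.frames + b.frames
    elif mode == "multiply":
        scale = b.frames.mean()
        if scale <= 0:
            raise ValueError("multiply mode needs a nonzero second layer")
        frames = a.frames * b.frames / scale
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return ImageSeries(frames, a.pixel_size, a.frame_interval, origin_note="simulated")


@dataclass
class SimulationTruth:
    """Ground-truth record accompanying a simulated video."""

    config: SimulationConfig
    main_initial_positions: np.ndarray | None
    wave_initial_positions: np.ndarray | None
    main_displacement_per_frame: tuple[float, float]  # (dx, dy) µm, y downward
    wave_displacement_per_frame: tuple[float, float]

    def to_dict(self) -> dict:
        d = {
            "config": asdict(self.config),
            "main_displacement_per_frame_um": list(self.main_displacement_per_frame),
            "wave_displacement_per_frame_um": list(self.wave_displacement_per_frame),
        }
        if self.main_initial_positions is not None:
            d["main_initial_positions_um"] = self.main_initial_positions.tolist()
        if self.wave_initial_positions is not None:
            d["wave_initial_positions_um"] = self.wave_initial_positions.tolist()
        return d


def _per_frame_displacement(speed: float, direction: float, dt: float) -> tuple[float, float]:
    step = speed * dt / 60.0
    theta = np.deg2rad(direction)
    return step * np.cos(theta), -step * np.sin(theta)


def simulate(config: SimulationConfig) -> tuple[ImageSeries, SimulationTruth]:
    """Generate the full video plus its ground-truth record.

    Layer initialization order is fixed (main, then wave) so a given seed
    is reproducible.  Per frame both layers are rendered at their current
    positions, combined per ``combine_mode``, then advanced by one frame
    interval.
    """
    rng = np.random.default_rng(config.seed)
    main = init_particles(config, "main", rng) if config.n_particles > 0 else None
    wave = init_particles(config, "wave", rng) if config.wave_n_particles > 0 else None
    if main is None and wave is None:
        raise ValueError("no layer enabled")

    extent = config.extent
    main_frames, wave_frames = [], []
    for _ in range(config.n_frames):
        if main is not None:
            main_frames.append(render_frame(main, config))
            main = advance_particles(
                main, config.drift_speed, config.drift_direction,
                config.frame_interval, extent, config.boundary,
            )
        if wave is not None:
            wave_frames.append(render_frame(wave, config))
            wave = advance_particles(
                wave, config.wave_speed, config.wave_direction,
                config.frame_interval, extent, config.boundary,
            )

    def _series(frames: list[np.ndarray]) -> ImageSeries:
        return ImageSeries(
            np.stack(frames), config.pixel_size, config.frame_interval,
            origin_note="simulated",
        )

    if config.combine_mode == "none":
        video = _series(main_frames if main_frames else wave_frames)
    else:
        video = combine_layers(
            _series(main_frames), _series(wave_frames), config.combine_mode
        )

    rng0 = np.random.default_rng(config.seed)
    main0 = init_particles(config, "main", rng0).positions if config.n_particles > 0 else None
    wave0 = init_particles(config, "wave", rng0).positions if config.wave_n_particles > 0 else None
    truth = SimulationTruth(
        config=config,
        main_initial_positions=main0,
        wave_initial_positions=wave0,
        main_displacement_per_frame=_per_frame_displacement(
            config.drift_speed, config.drift_direction, config.frame_interval
        ),
        wave_displacement_per_frame=_per_frame_displacement(
            config.wave_speed, config.wave_direction, config.frame_interval
        ),
    )
    return video, truth
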