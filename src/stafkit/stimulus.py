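"""Stimulus protocol construction and panoramic frame rendering.

The display is modelled as a one-dimensional azimuthal ring of ON/OFF pixels
(figures span the full vertical extent of the physical arena, so vertical
structure carries no information here).  A figure is a window of textured
pixels that replaces the background; the window position (figure motion, FM)
and the texture inside it (elementary motion, EM) are stepped independently,
each by at most one pixel per frame.

Azimuth convention: 0° at front center, positive clockwise, wrapped to
(-180°, 180°].  Frame 0 is the pre-motion state; the step stored at frame t
moves the figure between frames t-1 and t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msequence import MSequence

__all__ = [
    "DisplayGeometry",
    "StimulusRealization",
    "FrameSequence",
    "wrap_azimuth",
    "make_background",
    "build_compound_protocol",
    "render_frames",
    "make_trisweep",
]


def wrap_azimuth(deg):
    """Wrap angles (degrees) into (-180, 180]."""
    d = np.mod(np.asarray(deg, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class DisplayGeometry:
    """Panoramic LED-arena geometry.

    Defaults model a 96-pixel ring at 3.75°/pixel with a 30° (8-pixel) figure
    window.  The physical arena leaves an 8-pixel access gap at the rear; the
    simulation uses the full 360° logical ring and the gap is kept only as
    metadata (``rear_gap_pixels``) for optional masking.
    """

    n_pixels_azimuth: int = 96
    pixel_pitch: float = 3.75
    figure_width_pixels: int = 8
    frame_rate: float = 25.0
    rear_gap_pixels: int = 8

    def __post_init__(self):
        if abs(self.n_pixels_azimuth * self.pixel_pitch - 360.0) > 1e-9:
            raise ValueError("n_pixels_azimuth * pixel_pitch must equal 360")
        if self.figure_width_pixels < 3:
            raise ValueError("figure_width_pixels must be >= 3")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def azimuth_grid(self) -> np.ndarray:
        """Pixel-center azimuths, sorted ascending within (-180, 180]."""
        return np.sort(wrap_azimuth(np.arange(self.n_pixels_azimuth)
                                    * self.pixel_pitch))

    def pixel_index(self, azimuth) -> np.ndarray:
        """Nearest pixel index (0-based, pixel 0 at azimuth 0) for an angle."""
        return np.mod(np.rint(np.asarray(azimuth) / self.pixel_pitch)
                      .astype(int), self.n_pixels_azimuth)


@dataclass(frozen=True)
class StimulusRealization:
    """Frame-by-frame step traces for one protocol run.

    ``delta_fm[t]`` and ``delta_em[t]`` are the window and texture steps (in
    pixels) applied between frames t-1 and t; index 0 is always 0.  ``gamma``
    is the figure-centroid azimuth per frame, the wrapped cumulative sum of
    ``delta_fm`` from ``start_azimuth``.
    """

    delta_fm: np.ndarray = field(repr=False)
    delta_em: np.ndarray = field(repr=False)
    gamma: np.ndarray = field(repr=False)
    sign_flag: int
    start_azimuth: float
    n_periods: int
    frame_rate: float
    drift_balanced_flag: bool = False

    def __post_init__(self):
        for name in ("delta_fm", "delta_em", "gamma"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (len(self.delta_fm) == len(self.delta_em) == len(self.gamma)):
            raise ValueError("step and position traces must share a length")
        if np.max(np.abs(self.delta_fm)) > 1 or np.max(np.abs(self.delta_em)) > 1:
            raise ValueError("steps are limited to one pixel per frame")

    @property
    def n_frames(self) -> int:
        return len(self.delta_fm)

    def figure_velocity(self, geometry: DisplayGeometry) -> np.ndarray:
        """Implied figure velocity (deg/s) per frame."""
        return self.delta_fm * geometry.pixel_pitch * self.frame_rate

    def em_velocity(self, geometry: DisplayGeometry) -> np.ndarray:
        """Implied internal-texture velocity (deg/s) per frame."""
        return self.delta_em * geometry.pixel_pitch * self.frame_rate


@dataclass
class FrameSequence:
    """Rendered binary frames (time x pixel), with background bookkeeping."""

    frames: np.ndarray
    background: np.ndarray
    refresh_log: list

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        self.background = np.asarray(self.background, dtype=np.uint8)


def make_background(geometry: DisplayGeometry, rng_seed) -> np.ndarray:
    """A random ON/OFF background pattern, each pixel Bernoulli(0.5)."""
    rng = np.random.default_rng(rng_seed)
    return rng.integers(0, 2, size=geometry.n_pixels_azimuth,
                        dtype=np.uint8)


def build_compound_protocol(m_fm: MSequence, m_em: MSequence,
                            sign_flag: int = 1, start_azimuth: float = 0.0,
                            geometry: DisplayGeometry | None = None,
                            n_periods: int = 1,
                            drift_balanced: bool = False) -> StimulusRealization:
    """Build the two-sequence compound stimulus for one run.

    The figure window follows ``m_fm`` repeated ``n_periods`` times; the
    internal texture follows ``sign_flag * m_em``.  The two sequences must be
    distinct: the paired sign-flip estimators can only cancel figure-position
    and sequence cross-talk contamination when two different m-sequences drive
    the two streams.
    """
    geometry = geometry or DisplayGeometry()
    if sign_flag not in (1, -1):
        raise ValueError("sign_flag must be +1 or -1")
    if m_fm.p == m_em.p and np.array_equal(m_fm.values, m_em.values):
        raise ValueError(
            "m_fm and m_em are identical; decontamination by the sign-flip "
            "protocol requires two distinct m-sequences")
    if m_fm.p != m_em.p:
        raise ValueError("m_fm and m_em must have equal period")
    steps_fm = np.concatenate([[0], np.tile(m_fm.values, n_periods)])
    steps_em = np.concatenate([[0], sign_flag * np.tile(m_em.values,
                                                        n_periods)])
    gamma = wrap_azimuth(start_azimuth
                         + np.cumsum(steps_fm) * geometry.pixel_pitch)
    return StimulusRealization(
        delta_fm=steps_fm, delta_em=steps_em, gamma=gamma,
        sign_flag=sign_flag, start_azimuth=float(wrap_azimuth(start_azimuth)),
        n_periods=n_periods, frame_rate=geometry.frame_rate,
        drift_balanced_flag=drift_balanced)


def make_trisweep(amplitude_deg: float = 90.0,
                  geometry: DisplayGeometry | None = None,
                  n_cycles: int = 1) -> StimulusRealization:
    """Triangle-wave sweep of a Fourier bar (texture moves with the window).

    The figure starts at ``-amplitude/2``, steps one pixel per frame up to
    ``+amplitude/2`` and back; one cycle returns it to the start, so the net
    displacement is zero.  ``delta_em == delta_fm`` at every frame.
    """
    geometry = geometry or DisplayGeometry()
    n_steps = amplitude_deg / geometry.pixel_pitch
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"amplitude {amplitude_deg} deg is not a multiple of the pixel "
            f"pitch {geometry.pixel_pitch} deg")
    n_steps = int(round(n_steps))
    cycle = np.concatenate([np.ones(n_steps), -np.ones(n_steps)])
    steps = np.concatenate([[0], np.tile(cycle, n_cycles)])
    start = -amplitude_deg / 2.0
    gamma = wrap_azimuth(start + np.cumsum(steps) * geometry.pixel_pitch)
    return StimulusRealization(
        delta_fm=steps, delta_em=steps.copy(), gamma=gamma, sign_flag=1,
        start_azimuth=float(start), n_periods=n_cycles,
        frame_rate=geometry.frame_rate, drift_balanced_flag=False)


def _window_columns(center_px: int, width: int, n_pixels: int) -> np.ndarray:
    offs = np.arange(width) - width // 2
    return np.mod(center_px + offs, n_pixels)


def render_frames(realization: StimulusRealization,
                  geometry: DisplayGeometry | None = None,
                  rng_seed=0) -> FrameSequence:
    """Render a protocol run to binary panoramic frames.

    Per frame, in order:

    * at the start of every third m-sequence period (frames 0, 3p+1, 6p+1,
      ...) the whole background is replaced with a fresh random pattern, to
      wash out chance figure/ground spatiotemporal correlations;
    * the window texture scrolls within the window by ``delta_em - delta_fm``
      pixels (texture and window move on the same screen, so the relative
      shift is their difference); columns that wrap in are drawn fresh;
    * in drift-balanced mode the whole texture is re-randomized each frame
      instead, leaving no coherent first-order motion;
    * on a syndirectional step (``delta_fm == delta_em != 0``, when no fresh
      column would otherwise appear) both boundary columns of the window are
      redrawn at random, equalizing the number of coherently-moving interpixel
      boundaries between syn- and antidirectional steps;
    * the window overwrites the background at the current azimuth.
    """
    geometry = geometry or DisplayGeometry()
    width = geometry.figure_width_pixels
    if width > geometry.n_pixels_azimuth:
        raise ValueError("figure window wider than the display")
    rng = np.random.default_rng(rng_seed)
    n_px = geometry.n_pixels_azimuth
    p = (realization.n_frames - 1) // max(realization.n_periods, 1)

    background = rng.integers(0, 2, size=n_px, dtype=np.uint8)
    texture = rng.integers(0, 2, size=width, dtype=np.uint8)
    frames = np.empty((realization.n_frames, n_px), dtype=np.uint8)
    refresh_log = [0]

    for t in range(realization.n_frames):
        period_idx, phase = divmod(t - 1, p) if t > 0 else (-1, 0)
        if t > 0 and phase == 0 and period_idx % 3 == 0 and period_idx > 0:
            background = rng.integers(0, 2, size=n_px, dtype=np.uint8)
            refresh_log.append(t)
        dfm = int(realization.delta_fm[t])
        dem = int(realization.delta_em[t])
        if realization.drift_balanced_flag:
            texture = rng.integers(0, 2, size=width, dtype=np.uint8)
        else:
            rel = dem - dfm
            if rel != 0:
                texture = np.roll(texture, rel)
                if rel > 0:
                    texture[:rel] = rng.integers(0, 2, size=rel)
                else:
                    texture[rel:] = rng.integers(0, 2, size=-rel)
            if dfm != 0 and dfm == dem:
                texture[0] = rng.integers(0, 2)
                texture[-1] = rng.integers(0, 2)
        frame = background.copy()
        cols = _window_columns(geometry.pixel_index(realization.gamma[t]),
                               width, n_px)
        frame[cols] = texture
        frames[t] = frame

    return FrameSequence(frames=frames, background=background,
                         refresh_log=refresh_log)
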