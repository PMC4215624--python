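"""Synthetic quasi-linear behavioral plant.

Generates steering-effort (ΔWBA) traces from a ground-truth two-stream
superposition model so that every downstream stage — estimation, assembly,
prediction — can be validated without animal data.  The ground truth mimics
the qualitative shapes reported for tethered flies:

* the EM stream responds to texture motion with an impulse-like kernel
  (alpha function: short onset delay, ~100 ms rise, decay to a near-zero
  asymptote), strongest for figures in the frontal field and falling off as
  a broad Gaussian of azimuth;
* the FM stream responds to figure-position steps with a slow, persistent
  step response (~200 ms onset delay, saturating by ~2 s) whose spatial
  profile is a center-surround difference-of-Gaussians with near-zero
  azimuthal integral (excitatory frontally, sign-inverted in the periphery
  beyond roughly ±90°).

All amplitudes are fixture values in arbitrary ΔWBA units per one-pixel
step; they are design choices of this simulator, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import STAF
from .prediction import predict_response, trajectory_from_realization
from .stimulus import DisplayGeometry, StimulusRealization, wrap_azimuth

__all__ = [
    "GroundTruthParams",
    "PlantModel",
    "ResponseTrace",
    "make_ground_truth_stafs",
    "simulate_response",
]


@dataclass(frozen=True)
class GroundTruthParams:
    """Shape parameters of the synthetic ground-truth STAF pair.

    Time constants in seconds, spatial widths in degrees, amplitudes in
    ΔWBA units per pixel step.
    """

    em_amplitude: float = 1.0
    em_delay: float = 0.04
    em_rise: float = 0.1          # alpha-function time-to-peak after delay
    em_sigma: float = 50.97       # frontal Gaussian sigma (60 deg HWHM)
    fm_amplitude: float = 1.0
    fm_delay: float = 0.2
    fm_saturation: float = 0.4    # exponential saturation time constant
    fm_sigma_center: float = 80.0
    fm_sigma_surround: float = 300.0
    duration_frames: int = 127    # one order-7 period at 25 Hz

    def __post_init__(self):
        if min(self.em_rise, self.fm_saturation) <= 0:
            raise ValueError("time constants must be positive")
        if min(self.em_sigma, self.fm_sigma_center,
               self.fm_sigma_surround) <= 0:
            raise ValueError("spatial widths must be positive")


def make_ground_truth_stafs(geometry: DisplayGeometry | None = None,
                            params: GroundTruthParams | None = None,
                            uniform_azimuth: bool = False
                            ) -> tuple[STAF, STAF]:
    """Build the (EM, FM) ground-truth STAF pair on the full pixel grid.

    With ``uniform_azimuth=True`` the spatial profiles are constant (their
    frontal peak value everywhere); useful for exactness tests where the
    quasi-linear local-position approximation should drop out entirely.
    """
    geometry = geometry or DisplayGeometry()
    params = params or GroundTruthParams()
    az = geometry.azimuth_grid
    t = np.arange(params.duration_frames) / geometry.frame_rate

    # temporal shapes
    te = np.clip(t - params.em_delay, 0.0, None) / params.em_rise
    alpha = te * np.exp(1.0 - te)                     # unit peak at delay+rise
    tf = np.clip(t - params.fm_delay, 0.0, None)
    step = 1.0 - np.exp(-tf / params.fm_saturation)
    step[t <= params.fm_delay] = 0.0

    # spatial profiles
    if uniform_azimuth:
        a_em = np.full_like(az, params.em_amplitude)
        a_fm = np.full_like(az, params.fm_amplitude)
    else:
        a_em = params.em_amplitude * np.exp(-az**2
                                            / (2 * params.em_sigma**2))
        center = np.exp(-az**2 / (2 * params.fm_sigma_center**2))
        surround = np.exp(-az**2 / (2 * params.fm_sigma_surround**2))
        k = center.sum() / surround.sum()   # zero azimuthal integral
        a_fm = params.fm_amplitude * (center - k * surround)

    staf_em = STAF(grid=np.outer(alpha, a_em), time_axis=t, azimuth_axis=az,
                   kind="EM", provenance={"ground_truth": True})
    staf_fm = STAF(grid=np.outer(step, a_fm), time_axis=t, azimuth_axis=az,
                   kind="FM", provenance={"ground_truth": True})
    return staf_em, staf_fm


@dataclass(frozen=True)
class ResponseTrace:
    """A sampled steering-effort time series aligned to stimulus frames.

    Positive values denote rightward (clockwise) steering effort.
    ``alignment`` is the index of the first stimulus frame (protocol traces
    carry one pre-motion frame at index 0).
    """

    y: np.ndarray = field(repr=False)
    frame_rate: float
    alignment: int = 0

    def __post_init__(self):
        object.__setattr__(self, "y", np.asarray(self.y, float))
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.y)) / self.frame_rate


@dataclass(frozen=True)
class PlantModel:
    """Ground truth STAF pair plus output noise model.

    ``noise_sigma`` is the standard deviation of additive white Gaussian
    noise on ΔWBA; the default of 2.5 matches the noiseless response
    standard deviation of a frontal compound-protocol run (SNR ≈ 1 per
    sample), so single-period kernel estimates are visibly noisy while
    repeat averages are clean.  ``drift_amplitude`` adds a slow sinusoidal
    baseline wander (period ~30 s, random phase).  ``saturation`` optionally
    applies a static ``sat * tanh(y / sat)`` output map.
    """

    staf_em_true: STAF
    staf_fm_true: STAF
    noise_sigma: float = 2.5
    drift_amplitude: float = 0.0
    drift_period: float = 30.0
    saturation: float | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for s in (self.staf_em_true, self.staf_fm_true):
            if not np.all(np.isfinite(s.grid)):
                raise ValueError("ground-truth grids must be finite")
        if self.staf_em_true.kind != "EM" or self.staf_fm_true.kind != "FM":
            raise ValueError("plant STAFs must be (EM, FM)")


def simulate_response(plant: PlantModel,
                      realization: StimulusRealization,
                      geometry: DisplayGeometry | None = None,
                      rng=None, noiseless: bool = False,
                      include_initial_position: bool = True,
                      precomputed_clean: ResponseTrace | None = None
                      ) -> ResponseTrace:
    """Simulate the ΔWBA response to one stimulus realization.

    The noiseless response is the same discrete superposition used for
    prediction (the plant *is* the forward model evaluated on the ground
    truth), optionally followed by the static saturation.  Noise and drift
    are then added from ``rng`` (defaults to a generator seeded with
    ``plant.rng_seed``).  ``precomputed_clean`` lets callers reuse one
    noiseless simulation across repeated noisy draws of the same stimulus.
    """
    geometry = geometry or DisplayGeometry()
    if precomputed_clean is not None:
        y = precomputed_clean.y.copy()
    else:
        traj = trajectory_from_realization(realization, geometry)
        y = predict_response(plant.staf_em_true, plant.staf_fm_true, traj,
                             include_initial_position=include_initial_position)
        if plant.saturation is not None:
            y = plant.saturation * np.tanh(y / plant.saturation)
    if not noiseless:
        if rng is None:
            rng = np.random.default_rng(plant.rng_seed)
        elif not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if plant.drift_amplitude > 0:
            t = np.arange(len(y)) / realization.frame_rate
            phase = rng.uniform(0, 2 * np.pi)
            y = y + plant.drift_amplitude * np.sin(
                2 * np.pi * t / plant.drift_period + phase)
        if plant.noise_sigma > 0:
            y = y + rng.normal(0.0, plant.noise_sigma, size=len(y))
    return ResponseTrace(y=y, frame_rate=realization.frame_rate, alignment=1)
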