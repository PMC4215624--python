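"""Forward response prediction from a STAF pair, and prediction scoring.

The steering response to an arbitrary figure trajectory is the discrete
superposition

    y(t) = sum_tau [ G_FM(t - tau, gamma(tau)) * dFM(tau)
                   + G_EM(t - tau, gamma(tau)) * dEM(tau) ]
         + sum_theta G_FM(t, theta) * dF(theta)

where the last term accounts for the figure's initial position: one unit
step per azimuth pixel along the shorter arc from front center to gamma(0).
Each step is attributed to the azimuth the figure occupied *before* the step
(the position at which the step command acts); attributing it to the landing
position instead couples the kernel's spatial gradient to the drive sequence
through its own integral and measurably biases kernel estimates on spatial
flanks.  STAF values off the azimuth grid are obtained by linear
interpolation with circular wrap.  Beyond the sampled time axis an EM kernel (an impulse
response) is taken as zero, while an FM kernel (a step response) holds its
final value — steps older than the sampled span keep contributing their
asymptote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import pearsonr

from .estimation import STAF
from .stimulus import DisplayGeometry, StimulusRealization, wrap_azimuth

__all__ = [
    "Trajectory",
    "predict_response",
    "r_squared",
    "staf_transfer_function",
    "trajectory_from_realization",
    "make_rotation_trajectory",
]


@dataclass(frozen=True)
class Trajectory:
    """A figure trajectory expressed as per-frame pixel steps."""

    initial_azimuth: float
    fm_steps: np.ndarray = field(repr=False)
    em_steps: np.ndarray = field(repr=False)
    frame_rate: float = 25.0
    pixel_pitch: float = 3.75

    def __post_init__(self):
        object.__setattr__(self, "fm_steps",
                           np.asarray(self.fm_steps, float))
        object.__setattr__(self, "em_steps",
                           np.asarray(self.em_steps, float))
        if len(self.fm_steps) != len(self.em_steps):
            raise ValueError("fm_steps and em_steps must share a length")

    @property
    def n_frames(self) -> int:
        return len(self.fm_steps)

    def gamma(self) -> np.ndarray:
        """Figure azimuth per frame (degrees, wrapped)."""
        return wrap_azimuth(self.initial_azimuth
                            + np.cumsum(self.fm_steps) * self.pixel_pitch)

    def gamma_pre_step(self) -> np.ndarray:
        """Azimuth occupied before each frame's step was applied."""
        g = self.gamma()
        return np.concatenate([[wrap_azimuth(self.initial_azimuth)],
                               g[:-1]])

    def initial_position_steps(self) -> tuple[np.ndarray, float]:
        """(pixel azimuths theta_i, step sign) decomposing 0 -> gamma(0).

        One one-pixel step per grid pixel along the shorter arc from front
        center to the initial azimuth, all with the sign of gamma(0); each
        step is attributed to its pre-step pixel (0, ±pitch, ...).
        """
        g0 = float(wrap_azimuth(self.initial_azimuth))
        n = int(round(abs(g0) / self.pixel_pitch))
        if n == 0:
            return np.array([]), 0.0
        sign = 1.0 if g0 > 0 else -1.0
        theta = sign * self.pixel_pitch * np.arange(0, n)
        return theta, sign


def trajectory_from_realization(realization: StimulusRealization,
                                geometry: DisplayGeometry | None = None
                                ) -> Trajectory:
    geometry = geometry or DisplayGeometry()
    return Trajectory(initial_azimuth=realization.start_azimuth,
                      fm_steps=realization.delta_fm,
                      em_steps=realization.delta_em,
                      frame_rate=realization.frame_rate,
                      pixel_pitch=geometry.pixel_pitch)


def make_rotation_trajectory(direction: int = 1, n_frames: int = 96,
                             geometry: DisplayGeometry | None = None,
                             initial_azimuth: float = 0.0) -> Trajectory:
    """Constant-rotation (revolving solid bar) trajectory, EM = FM."""
    geometry = geometry or DisplayGeometry()
    steps = np.full(n_frames, float(np.sign(direction)))
    steps[0] = 0.0
    return Trajectory(initial_azimuth=initial_azimuth, fm_steps=steps,
                      em_steps=steps.copy(), frame_rate=geometry.frame_rate,
                      pixel_pitch=geometry.pixel_pitch)


def _circular_interp_weights(axis: np.ndarray, angles: np.ndarray):
    """Linear interpolation weights on a sorted circular azimuth axis."""
    n = len(axis)
    if n == 1:
        z = np.zeros(len(angles), dtype=int)
        return z, z, np.ones(len(angles))
    ext = np.concatenate([axis, axis[:1] + 360.0])
    a = np.mod(np.asarray(angles, float) - axis[0], 360.0) + axis[0]
    idx = np.clip(np.searchsorted(ext, a, side="right") - 1, 0, n - 1)
    span = ext[idx + 1] - ext[idx]
    w_hi = (a - ext[idx]) / span
    return idx, (idx + 1) % n, w_hi


def _staf_column_values(staf: STAF, angles: np.ndarray) -> np.ndarray:
    """STAF grid interpolated at arbitrary azimuths -> (time, len(angles))."""
    j0, j1, w = _circular_interp_weights(staf.azimuth_axis,
                                         np.atleast_1d(angles))
    return staf.grid[:, j0] * (1.0 - w) + staf.grid[:, j1] * w


def _superpose_stream(staf: STAF, steps: np.ndarray, gamma: np.ndarray,
                      persist: bool) -> np.ndarray:
    """Convolve a step train against azimuth-dependent kernel columns."""
    T = len(steps)
    L = staf.grid.shape[0]
    j0, j1, w = _circular_interp_weights(staf.azimuth_axis, gamma)
    y = np.zeros(T)
    # accumulate per azimuth column so each column needs one convolution
    weights = {}
    for jj, ww in ((j0, 1.0 - w), (j1, w)):
        for j in np.unique(jj):
            mask = (jj == j)
            if not np.any(mask):
                continue
            c = np.zeros(T)
            c[mask] = steps[mask] * ww[mask]
            if j in weights:
                weights[j] += c
            else:
                weights[j] = c
    for j, c in weights.items():
        if not np.any(c):
            continue
        y += fftconvolve(c, staf.grid[:, j])[:T]
        if persist and T > L:
            y[L:] += staf.grid[-1, j] * np.cumsum(c)[:T - L]
    return y


def _initial_position_term(staf_fm: STAF, trajectory: Trajectory,
                           n_frames: int) -> np.ndarray:
    theta, sign = trajectory.initial_position_steps()
    if len(theta) == 0:
        return np.zeros(n_frames)
    cols = _staf_column_values(staf_fm, theta)  # (L, n_steps)
    term_profile = sign * cols.sum(axis=1)      # response vs time
    L = len(term_profile)
    out = np.empty(n_frames)
    m = min(L, n_frames)
    out[:m] = term_profile[:m]
    if n_frames > L:
        out[L:] = term_profile[-1]  # step responses persist
    return out


def predict_response(staf_em: STAF, staf_fm: STAF,
                     trajectory: Trajectory,
                     include_initial_position: bool = True) -> np.ndarray:
    """Predicted steering trace for a trajectory, per the superposition model.

    Emits a warning (not an error) when step magnitudes exceed the one-pixel
    calibration step: the quasilinear STAF model is only validated for mean
    speeds near step-size x update-rate.
    """
    if staf_em.kind != "EM" or staf_fm.kind != "FM":
        raise ValueError(
            f"expected (EM, FM) STAFs, got ({staf_em.kind}, {staf_fm.kind})")
    max_step = max(np.max(np.abs(trajectory.fm_steps), initial=0.0),
                   np.max(np.abs(trajectory.em_steps), initial=0.0))
    if max_step > 1.0 + 1e-9:
        warnings.warn(
            f"step magnitude {max_step:.2f} px exceeds the 1-px calibration "
            "step; the prediction leaves the quasilinear validity domain",
            stacklevel=2)
    gamma = trajectory.gamma_pre_step()
    y = (_superpose_stream(staf_fm, trajectory.fm_steps, gamma, persist=True)
         + _superpose_stream(staf_em, trajectory.em_steps, gamma,
                             persist=False))
    if include_initial_position:
        y = y + _initial_position_term(staf_fm, trajectory,
                                       trajectory.n_frames)
    return y


def r_squared(predicted, measured) -> float:
    """Squared Pearson correlation between predicted and measured traces."""
    a = np.asarray(predicted, float)
    b = np.asarray(measured, float)
    if len(a) != len(b):
        raise ValueError("traces must have equal length")
    if np.ptp(b) == 0:
        raise ValueError("measured trace is constant; correlation undefined")
    return float(pearsonr(a, b).statistic ** 2)


def staf_transfer_function(staf: STAF):
    """Per-azimuth DFT of the temporal kernels (descriptive only).

    Returns ``(frequencies_hz, complex_gain)`` with ``complex_gain`` of shape
    (n_frequencies, n_azimuths).  The zero-frequency row equals the temporal
    sum of each kernel.
    """
    t = staf.time_axis
    if len(t) > 1:
        dt = np.diff(t)
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-12):
            raise ValueError("transfer function requires a uniform time axis")
        dt0 = float(dt[0])
    else:
        dt0 = 1.0
    gain = np.fft.rfft(staf.grid, axis=0)
    freqs = np.fft.rfftfreq(staf.grid.shape[0], d=dt0)
    return freqs, gain
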