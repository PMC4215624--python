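"""Kernel estimation from paired response traces and STAF assembly.

The measurement model: with two distinct m-sequences m_FM and m_EM driving
the figure window and its internal texture, the paired protocol records

    y1 = m_FM * g_FM + m_EM * g_EM  (+ noise)
    y2 = m_FM * g_FM - m_EM * g_EM  (+ noise)

(``*`` temporal convolution).  The EM kernel is recovered from the difference
of cross-correlations, 2 u_EM = m_EM x y1 - m_EM x y2, which cancels both the
dc figure-position contamination and the finite m_FM/m_EM cross-talk.  The FM
stream behaves like a *step* response (it may hold a nonzero value at long
lags), so its kernel is recovered through the derivative identity
d(m*g)/dt = m * dg/dt: 2 u_FM = m_FM x dy1/dt + m_FM x dy2/dt estimates
dg_FM/dt, which is integrated back to g_FM.

The integration re-introduces the m-sequence dc error: with the cross-
correlation normalized by ``p + 1``, the derivative estimate is biased by
``-A/(p+1)`` per lag, where ``A`` is the kernel asymptote, so the raw
cumulative sum c(k) = g(k) - (k+1) A / (p+1) would nearly cancel the true
step by lag p-1.  The asymptote is estimated from c over a late window
(default 2-5 s, where the true slope is small) by inverting that relation in
closed form, and the ramp is added back.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .msequence import MSequence, circular_crosscorrelation
from .stimulus import DisplayGeometry, StimulusRealization, wrap_azimuth

__all__ = [
    "Kernel",
    "EstimationConfig",
    "ProtocolConfig",
    "STAF",
    "estimate_em_kernel",
    "estimate_fm_kernel",
    "estimate_kernel_unpaired",
    "assemble_staf",
    "run_staf_protocol",
]


@dataclass(frozen=True)
class EstimationConfig:
    """Knobs of the kernel-extraction stage.

    dc_window
        Time interval (seconds) over which the raw cumulative sum of u_FM is
        averaged to estimate the kernel asymptote; must fall within one
        sequence period.  Default 2-5 s.
    normalization
        Divisor of the circular cross-correlation: "p_plus_1" (default; an
        m-sequence autocorrelation is (p+1)*delta - 1, so this recovers a
        pure-delay kernel with unit peak up to O(1/p)) or "p".
    boxcar_width
        Spatial smoothing width in display pixels applied along azimuth when
        assembling a STAF.
    n_transient_periods
        Leading periods of each run discarded before period-averaging, so
        that the analyzed record is in periodic steady state.
    dc_correction
        "closed_form" (default), "literal" (window mean added without the
        ramp inversion), or "none".
    em_dc_correction
        The EM estimate u carries a uniform offset -sum(g)/(p+1) from the
        m-sequence's -1 off-peak autocorrelation.  Summing the estimator
        relation over lags shows sum(u) equals that offset exactly, so
        ``g = u + sum(u)`` removes it with no free parameters.  Off by
        default: the conventional estimate *is* the raw cross-correlation.
    """

    dc_window: tuple[float, float] = (2.0, 5.0)
    normalization: str = "p_plus_1"
    boxcar_width: int = 4
    n_transient_periods: int = 1
    n_repeats_average: int = 1
    dc_correction: str = "closed_form"
    em_dc_correction: bool = False

    def __post_init__(self):
        if self.boxcar_width < 1:
            raise ValueError("boxcar_width must be >= 1")
        if self.dc_window[1] <= self.dc_window[0] or self.dc_window[0] < 0:
            raise ValueError("dc_window must be a nonempty positive interval")
        if self.normalization not in ("p_plus_1", "p"):
            raise ValueError("normalization must be 'p_plus_1' or 'p'")
        if self.dc_correction not in ("closed_form", "literal", "none"):
            raise ValueError(
                "dc_correction must be 'closed_form', 'literal' or 'none'")

    def divisor(self, p: int) -> float:
        return float(p + 1 if self.normalization == "p_plus_1" else p)


@dataclass(frozen=True)
class Kernel:
    """One temporal kernel estimate tied to a mean figure azimuth.

    ``values`` is the response per unit (one-pixel) step at each lag;
    ``raw_crosscorr`` is the normalized cross-correlation before any
    integration / dc correction (u_EM or u_FM).  EM kernels are impulse
    responses; FM kernels are incremental step responses and may be nonzero
    at long lags.
    """

    values: np.ndarray = field(repr=False)
    raw_crosscorr: np.ndarray = field(repr=False)
    centroid_azimuth: float
    kind: str
    frame_rate: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))
        object.__setattr__(self, "raw_crosscorr",
                           np.asarray(self.raw_crosscorr, float))
        if self.kind not in ("EM", "FM"):
            raise ValueError("kind must be 'EM' or 'FM'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")

    @property
    def p(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class STAF:
    """Spatio-temporal action field: a time x azimuth grid of kernel values.

    ``grid[i, j]`` is the response at time ``time_axis[i]`` after a unit step
    applied while the figure centroid sits at ``azimuth_axis[j]`` (degrees,
    strictly increasing within (-180, 180]).
    """

    grid: np.ndarray = field(repr=False)
    time_axis: np.ndarray = field(repr=False)
    azimuth_axis: np.ndarray = field(repr=False)
    kind: str
    smoothing: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, float))
        object.__setattr__(self, "time_axis",
                           np.asarray(self.time_axis, float))
        object.__setattr__(self, "azimuth_axis",
                           np.asarray(self.azimuth_axis, float))
        if self.grid.shape != (len(self.time_axis), len(self.azimuth_axis)):
            raise ValueError("grid shape must match (time, azimuth) axes")
        if self.kind not in ("EM", "FM"):
            raise ValueError("kind must be 'EM' or 'FM'")
        if len(self.azimuth_axis) > 1 and np.any(
                np.diff(self.azimuth_axis) <= 0):
            raise ValueError("azimuth_axis must be strictly increasing")

    @property
    def frame_rate(self) -> float:
        if len(self.time_axis) < 2:
            return float("nan")
        return 1.0 / float(self.time_axis[1] - self.time_axis[0])

    def scaled(self, factor: float) -> "STAF":
        return replace(self, grid=self.grid * factor)


def _aligned(y, p: int) -> np.ndarray:
    """Return the phase-aligned sample array of a trace."""
    from .plant import ResponseTrace  # local: avoid import cycle
    if isinstance(y, ResponseTrace):
        arr = np.asarray(y.y, float)[y.alignment:]
    else:
        arr = np.asarray(y, float)
    if len(arr) == 0 or len(arr) % p != 0:
        raise ValueError(
            f"trace length {len(arr)} is not a positive multiple of the "
            f"sequence period {p}")
    return arr


def _period_average(arr: np.ndarray, p: int, n_transient: int) -> np.ndarray:
    n_per = len(arr) // p
    skip = min(n_transient, n_per - 1)
    return arr[skip * p:].reshape(-1, p).mean(axis=0)


def _derivative(arr: np.ndarray, p: int, frame_rate: float) -> np.ndarray:
    """First difference scaled to a rate.

    The leading sample wraps circularly when the record is a single period;
    for longer records it differences against the pre-stimulus rest state
    (and falls in the discarded transient period anyway).
    """
    d = np.empty_like(arr)
    d[1:] = arr[1:] - arr[:-1]
    d[0] = arr[0] - (arr[-1] if len(arr) == p else 0.0)
    return d * frame_rate


def _dc_window_frames(config: EstimationConfig, p: int,
                      frame_rate: float) -> np.ndarray:
    k0 = int(np.ceil(config.dc_window[0] * frame_rate))
    k1 = int(np.floor(config.dc_window[1] * frame_rate))
    if k0 > p - 1:
        raise ValueError(
            f"dc_window {config.dc_window} s starts beyond one sequence "
            f"period ({p / frame_rate:.2f} s)")
    k1 = min(k1, p - 1)
    if k1 < k0:
        raise ValueError("dc_window contains no frames")
    return np.arange(k0, k1 + 1)


def _circular_mean_deg(angles) -> float:
    a = np.deg2rad(np.asarray(angles, float))
    return float(wrap_azimuth(np.rad2deg(
        np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))))


def estimate_em_kernel(y1, y2, m_em: MSequence,
                       config: EstimationConfig | None = None,
                       frame_rate: float = 25.0,
                       gamma=None) -> Kernel:
    """EM (texture-motion) impulse-response kernel from a sign-flip pair.

    ``y1`` and ``y2`` are traces from runs driven by (m_FM, +m_EM) and
    (m_FM, -m_EM) with identical m_FM; each must span an integer number of
    periods, phase-aligned with the sequence.  After discarding transient
    periods and period-averaging, u_EM = (m_EM x ybar1 - m_EM x ybar2) / 2,
    normalized per the config.  The centroid is the circular mean of the
    figure azimuth over the analyzed span if ``gamma`` is given.
    """
    config = config or EstimationConfig()
    p = m_em.p
    a1, a2 = _aligned(y1, p), _aligned(y2, p)
    if len(a1) != len(a2):
        raise ValueError("paired traces must have equal length")
    yb1 = _period_average(a1, p, config.n_transient_periods)
    yb2 = _period_average(a2, p, config.n_transient_periods)
    u = 0.5 * (circular_crosscorrelation(m_em.values, yb1)
               - circular_crosscorrelation(m_em.values, yb2))
    u /= config.divisor(p)
    g = _em_dc_corrected(u, p, config) if config.em_dc_correction else u
    centroid = _centroid(gamma, p, config) if gamma is not None else np.nan
    return Kernel(values=g, raw_crosscorr=u, centroid_azimuth=centroid,
                  kind="EM", frame_rate=frame_rate)


def _em_dc_corrected(u: np.ndarray, p: int,
                     config: EstimationConfig) -> np.ndarray:
    # from u = ((p+1) g - sum(g)) / div: sum(g) = div * sum(u), hence
    # g = div * (u + sum(u)) / (p + 1); an identity, not an approximation
    div = config.divisor(p)
    return div * (u + u.sum()) / (p + 1)


def estimate_fm_kernel(y1, y2, m_fm: MSequence,
                       config: EstimationConfig | None = None,
                       frame_rate: float = 25.0,
                       gamma=None) -> Kernel:
    """FM (figure-motion) incremental step-response kernel from a pair.

    Pipeline: differentiate both traces, period-average, cross-correlate with
    m_FM (u_FM = sum of the two, halved), integrate the normalized derivative
    estimate, then correct the accumulating dc error using the asymptote
    estimated over ``config.dc_window`` (see module docstring).
    """
    config = config or EstimationConfig()
    p = m_fm.p
    a1, a2 = _aligned(y1, p), _aligned(y2, p)
    if len(a1) != len(a2):
        raise ValueError("paired traces must have equal length")
    d1 = _derivative(a1, p, frame_rate)
    d2 = _derivative(a2, p, frame_rate)
    db1 = _period_average(d1, p, config.n_transient_periods)
    db2 = _period_average(d2, p, config.n_transient_periods)
    u = 0.5 * (circular_crosscorrelation(m_fm.values, db1)
               + circular_crosscorrelation(m_fm.values, db2))
    u /= config.divisor(p)
    g = _integrate_with_dc_correction(u, p, frame_rate, config)
    centroid = _centroid(gamma, p, config) if gamma is not None else np.nan
    return Kernel(values=g, raw_crosscorr=u, centroid_azimuth=centroid,
                  kind="FM", frame_rate=frame_rate)


def _integrate_with_dc_correction(u: np.ndarray, p: int, frame_rate: float,
                                  config: EstimationConfig) -> np.ndarray:
    c = np.cumsum(u) / frame_rate
    if config.dc_correction == "none":
        return c
    w = _dc_window_frames(config, p, frame_rate)
    denom = float(config.divisor(p))
    ramp = (np.arange(p) + 1.0) / denom
    if config.dc_correction == "closed_form":
        # c(k) = g(k) - (k+1) A / denom and g ~ A over the window, so the
        # window mean of c is A * (1 - mean(ramp over window)); invert.
        shrink = 1.0 - float(np.mean(ramp[w]))
        asymptote = float(np.mean(c[w])) / shrink
    else:  # "literal": window mean taken as the asymptote directly
        asymptote = float(np.mean(c[w]))
    return c + ramp * asymptote


def estimate_kernel_unpaired(y, m: MSequence, kind: str,
                             config: EstimationConfig | None = None,
                             frame_rate: float = 25.0,
                             gamma=None) -> Kernel:
    """Single-run (no sign flip) kernel estimate, for contamination studies.

    Cross-correlates one trace with one sequence; the estimate carries the
    full figure-position dc contamination and m_FM/m_EM cross-talk that the
    paired protocol is designed to cancel.
    """
    config = config or EstimationConfig()
    p = m.p
    a = _aligned(y, p)
    if kind == "EM":
        yb = _period_average(a, p, config.n_transient_periods)
        u = circular_crosscorrelation(m.values, yb) / config.divisor(p)
        g = u
    elif kind == "FM":
        db = _period_average(_derivative(a, p, frame_rate), p,
                             config.n_transient_periods)
        u = circular_crosscorrelation(m.values, db) / config.divisor(p)
        g = _integrate_with_dc_correction(u, p, frame_rate, config)
    else:
        raise ValueError("kind must be 'EM' or 'FM'")
    centroid = _centroid(gamma, p, config) if gamma is not None else np.nan
    return Kernel(values=g, raw_crosscorr=u, centroid_azimuth=centroid,
                  kind=kind, frame_rate=frame_rate)


def _centroid(gamma, p: int, config: EstimationConfig) -> float:
    g = np.asarray(gamma, float)
    if len(g) > p:  # drop pre-motion frame / transient periods
        extra = len(g) % p
        body = g[extra:]
        n_per = len(body) // p
        skip = min(config.n_transient_periods, n_per - 1)
        body = body[skip * p:]
    else:
        body = g
    return _circular_mean_deg(body)


def _circular_boxcar(grid: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return grid.copy()
    kernel = np.ones(n) / n
    out = np.empty_like(grid)
    for i in range(grid.shape[0]):
        padded = np.concatenate([grid[i], grid[i], grid[i]])
        sm = np.convolve(padded, kernel, mode="same")
        out[i] = sm[grid.shape[1]:2 * grid.shape[1]]
    return out


def assemble_staf(kernels, geometry: DisplayGeometry | None = None,
                  config: EstimationConfig | None = None) -> STAF:
    """Concatenate kernels along azimuth into a STAF.

    Kernels are grouped by centroid azimuth (repeat-averaged within a group,
    tolerance half a pixel), placed on the sorted centroid axis, and each time
    slice is smoothed with a circular boxcar.  The boxcar width is specified
    in display pixels and converted to azimuth samples from the axis spacing;
    on axes sampled coarser than the boxcar it degenerates to a no-op.
    """
    geometry = geometry or DisplayGeometry()
    config = config or EstimationConfig()
    kernels = list(kernels)
    if not kernels:
        raise ValueError("no kernels to assemble")
    kind = kernels[0].kind
    if any(k.kind != kind for k in kernels):
        raise ValueError("kernels of mixed kinds cannot share a STAF")
    p = kernels[0].p
    frame_rate = kernels[0].frame_rate
    if any(k.p != p for k in kernels):
        raise ValueError("kernels must share the sequence period")

    tol = geometry.pixel_pitch / 2.0
    groups: list[tuple[float, list]] = []
    for k in sorted(kernels, key=lambda k: k.centroid_azimuth):
        if np.isnan(k.centroid_azimuth):
            raise ValueError("kernel without a centroid azimuth")
        if groups and abs(k.centroid_azimuth - groups[-1][0]) < tol:
            groups[-1][1].append(k)
        else:
            groups.append((k.centroid_azimuth, [k]))
    if len(groups) < 2:
        raise ValueError("need kernels at >= 2 distinct centroid azimuths")

    az = np.array([_circular_mean_deg([k.centroid_azimuth for k in g])
                   for _, g in groups])
    order = np.argsort(az)
    az = az[order]
    grid = np.stack([np.mean([k.values for k in groups[i][1]], axis=0)
                     for i in order], axis=1)

    spacing = np.median(np.diff(az)) if len(az) > 1 else 360.0
    n_sm = max(1, int(round(config.boxcar_width * geometry.pixel_pitch
                            / spacing)))
    n_sm = min(n_sm, len(az))
    grid = _circular_boxcar(grid, n_sm)
    return STAF(
        grid=grid, time_axis=np.arange(p) / frame_rate, azimuth_axis=az,
        kind=kind,
        smoothing={"boxcar_width_pixels": config.boxcar_width,
                   "boxcar_samples": n_sm},
        provenance={"n_kernels": len(kernels),
                    "normalization": config.normalization})


@dataclass(frozen=True)
class ProtocolConfig:
    """Schedule of a full STAF-mapping experiment.

    Block mode runs an independent paired (+m_EM / -m_EM) protocol at each
    start azimuth; sliding mode estimates one kernel per single-period window
    of each long record, assigning each window its own centroid.
    """

    order: int = 7
    taps_fm: tuple[int, ...] | None = None
    taps_em: tuple[int, ...] | None = None
    start_azimuths: tuple[float, ...] | None = None
    n_periods: int = 4
    n_repeats: int = 20
    mode: str = "block"
    drift_balanced: bool = False

    def __post_init__(self):
        if self.mode not in ("block", "sliding"):
            raise ValueError("mode must be 'block' or 'sliding'")
        if self.n_repeats < 1 or self.n_periods < 2:
            raise ValueError("need n_repeats >= 1 and n_periods >= 2")

    def sequences(self) -> tuple[MSequence, MSequence]:
        from .msequence import builtin_taps, generate_msequence
        taps_fm = self.taps_fm or builtin_taps(self.order, 0)
        taps_em = self.taps_em or builtin_taps(self.order, 1)
        return (generate_msequence(self.order, taps_fm),
                generate_msequence(self.order, taps_em))

    def azimuth_grid(self, geometry: DisplayGeometry) -> np.ndarray:
        if self.start_azimuths is not None:
            return np.asarray(self.start_azimuths, float)
        step = geometry.figure_width_pixels * geometry.pixel_pitch
        return wrap_azimuth(np.arange(0.0, 360.0, step))


def run_staf_protocol(source, protocol: ProtocolConfig | None = None,
                      geometry: DisplayGeometry | None = None,
                      config: EstimationConfig | None = None,
                      seed=0) -> tuple[STAF, STAF]:
    """Run (or load) the full paired protocol and assemble both STAFs.

    ``source`` is either a PlantModel (simulation mode: paired runs are
    simulated across the azimuth grid with seeded noise) or a list of run
    records ``{"start_azimuth", "sign", "y", "gamma"}`` produced by the io
    layer, in which case runs are paired by start azimuth and repeat order.
    Returns ``(staf_em, staf_fm)``.
    """
    from .plant import PlantModel  # lazy: cycle guard
    protocol = protocol or ProtocolConfig()
    geometry = geometry or DisplayGeometry()
    config = config or EstimationConfig()
    m_fm, m_em = protocol.sequences()

    if isinstance(source, PlantModel):
        runs = _simulate_runs(source, protocol, geometry, m_fm, m_em, seed)
    else:
        runs = list(source)
    return estimate_stafs_from_runs(runs, m_fm, m_em, geometry, config,
                                    mode=protocol.mode)


def _simulate_runs(plant, protocol: ProtocolConfig,
                   geometry: DisplayGeometry, m_fm: MSequence,
                   m_em: MSequence, seed) -> list[dict]:
    from .plant import simulate_response
    from .stimulus import build_compound_protocol
    rng_seq = np.random.SeedSequence(seed)
    runs = []
    for az in protocol.azimuth_grid(geometry):
        for sign in (1, -1):
            realization = build_compound_protocol(
                m_fm, m_em, sign_flag=sign, start_azimuth=az,
                geometry=geometry, n_periods=protocol.n_periods,
                drift_balanced=protocol.drift_balanced)
            clean = simulate_response(plant, realization, geometry,
                                      noiseless=True)
            for rep in range(protocol.n_repeats):
                child = rng_seq.spawn(1)[0]
                noisy = simulate_response(plant, realization, geometry,
                                          rng=np.random.default_rng(child),
                                          precomputed_clean=clean)
                runs.append({"start_azimuth": float(az), "sign": sign,
                             "repeat": rep, "y": noisy,
                             "gamma": realization.gamma})
    return runs


def _pair_runs(runs) -> dict:
    by_key: dict = {}
    for r in runs:
        key = (round(float(r["start_azimuth"]), 6), int(r["sign"]))
        by_key.setdefault(key, []).append(r)
    paired = {}
    for (az, sign) in sorted(by_key):
        if sign != 1:
            continue
        plus = by_key[(az, 1)]
        minus = by_key.get((az, -1))
        if minus is None or len(minus) != len(plus):
            raise ValueError(
                f"unpaired runs at start azimuth {az}: every +m_EM run needs "
                "a matching -m_EM run")
        paired[az] = (plus, minus)
    if not paired:
        raise ValueError("no paired runs found")
    return paired


def estimate_stafs_from_runs(runs, m_fm: MSequence, m_em: MSequence,
                             geometry: DisplayGeometry,
                             config: EstimationConfig,
                             mode: str = "block") -> tuple[STAF, STAF]:
    paired = _pair_runs(runs)
    em_kernels, fm_kernels = [], []
    for az, (plus, minus) in paired.items():
        for rp, rm in zip(plus, minus):
            if mode == "block":
                em_kernels.append(estimate_em_kernel(
                    rp["y"], rm["y"], m_em, config,
                    frame_rate=geometry.frame_rate, gamma=rp["gamma"]))
                fm_kernels.append(estimate_fm_kernel(
                    rp["y"], rm["y"], m_fm, config,
                    frame_rate=geometry.frame_rate, gamma=rp["gamma"]))
            else:
                em_kernels.extend(_sliding_kernels(
                    rp, rm, m_em, "EM", geometry, config))
                fm_kernels.extend(_sliding_kernels(
                    rp, rm, m_fm, "FM", geometry, config))
    staf_em = assemble_staf(em_kernels, geometry, config)
    staf_fm = assemble_staf(fm_kernels, geometry, config)
    for s in (staf_em, staf_fm):
        s.provenance.update({"order": m_fm.order, "mode": mode})
    return staf_em, staf_fm


def _sliding_kernels(rp, rm, m: MSequence, kind: str,
                     geometry: DisplayGeometry,
                     config: EstimationConfig) -> list[Kernel]:
    """One kernel per steady-state single-period window of a long record."""
    p = m.p
    a1, a2 = _aligned(rp["y"], p), _aligned(rm["y"], p)
    gamma = np.asarray(rp["gamma"], float)
    gamma = gamma[len(gamma) % p:]
    if kind == "FM":
        a1 = _derivative(a1, p, geometry.frame_rate)
        a2 = _derivative(a2, p, geometry.frame_rate)
    n_per = len(a1) // p
    skip = min(config.n_transient_periods, n_per - 1)
    window_cfg = replace(config, n_transient_periods=0)
    kernels = []
    for w in range(skip, n_per):
        s1, s2 = a1[w * p:(w + 1) * p], a2[w * p:(w + 1) * p]
        if kind == "EM":
            u = 0.5 * (circular_crosscorrelation(m.values, s1)
                       - circular_crosscorrelation(m.values, s2))
            u /= config.divisor(p)
            g = u
        else:
            u = 0.5 * (circular_crosscorrelation(m.values, s1)
                       + circular_crosscorrelation(m.values, s2))
            u /= config.divisor(p)
            g = _integrate_with_dc_correction(u, p, geometry.frame_rate,
                                              window_cfg)
        kernels.append(Kernel(
            values=g, raw_crosscorr=u,
            centroid_azimuth=_circular_mean_deg(gamma[w * p:(w + 1) * p]),
            kind=kind, frame_rate=geometry.frame_rate))
    return kernels
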