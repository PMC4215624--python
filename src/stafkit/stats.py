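"""Population statistics over STAF grids.

Comparison of STAF populations across groups or treatments is pixelwise: a
paired t-test at every (time, azimuth) pixel, corrected for multiple testing
with the Benjamini-Hochberg step-up procedure, which controls the false
discovery rate and remains valid under the positive dependence typical of
smooth STAFs.  Dimensionality of a population is characterized separately by
singular value decomposition of the flattened grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .estimation import STAF

__all__ = [
    "StafPopulation",
    "ComparisonResult",
    "paired_t_map",
    "bh_fdr",
    "compare_populations",
    "staf_population_svd",
]


@dataclass
class StafPopulation:
    """Same-shaped STAF grids, one per individual."""

    members: np.ndarray = field(repr=False)
    group_label: str = ""

    def __post_init__(self):
        if isinstance(self.members, (list, tuple)):
            grids = [m.grid if isinstance(m, STAF) else np.asarray(m, float)
                     for m in self.members]
            shapes = {g.shape for g in grids}
            if len(shapes) != 1:
                raise ValueError(f"members have mixed grid shapes: {shapes}")
            self.members = np.stack(grids)
        else:
            self.members = np.asarray(self.members, float)
        if self.members.ndim < 2:
            raise ValueError("members must stack to (n, *grid_shape)")

    @property
    def n(self) -> int:
        return self.members.shape[0]


@dataclass
class ComparisonResult:
    """Pixelwise paired-comparison maps over a STAF grid."""

    t_map: np.ndarray
    p_map: np.ndarray
    q: float | None = None
    rejection_mask: np.ndarray | None = None

    def __post_init__(self):
        self.t_map = np.asarray(self.t_map, float)
        self.p_map = np.asarray(self.p_map, float)
        if self.t_map.shape != self.p_map.shape:
            raise ValueError("t_map and p_map must share a shape")
        if self.rejection_mask is not None:
            self.rejection_mask = np.asarray(self.rejection_mask, bool)
            if self.rejection_mask.shape != self.p_map.shape:
                raise ValueError("rejection_mask must match the map shape")


def _as_population(pop) -> StafPopulation:
    return pop if isinstance(pop, StafPopulation) else StafPopulation(pop)


def paired_t_map(pop_a, pop_b) -> ComparisonResult:
    """Per-pixel paired t statistics and two-tailed p-values.

    Members are paired by index (same individual under two treatments);
    df = n - 1.  Pixels with zero difference everywhere get t = 0, p = 1.
    """
    a, b = _as_population(pop_a), _as_population(pop_b)
    if a.n != b.n:
        raise ValueError(f"paired test needs equal n (got {a.n}, {b.n})")
    if a.n < 2:
        raise ValueError("paired test needs n >= 2")
    if a.members.shape != b.members.shape:
        raise ValueError("populations must share the grid shape")
    d = a.members - b.members
    n = a.n
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # sd == 0: +-inf keeps the sign of the mean; 0/0 (no difference) -> t=0
    t = np.where(np.isnan(t), 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    return ComparisonResult(t_map=t, p_map=p)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q.

    Sort the m p-values ascending, find the largest k with
    p_(k) <= k * q / m, and reject the k smallest (all values tied with the
    threshold p-value are rejected together).  Returns a boolean mask with
    the input's shape.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def compare_populations(pop_a, pop_b, q: float = 0.05) -> ComparisonResult:
    """Paired t-map with BH-corrected rejection mask at FDR level q."""
    res = paired_t_map(pop_a, pop_b)
    res.q = q
    res.rejection_mask = bh_fdr(res.p_map, q)
    return res


def staf_population_svd(population, center: bool = False):
    """Principal modes of a STAF population.

    Each member's grid is flattened, the (n, pixels) matrix decomposed by
    SVD, and the squared singular values normalized to variance fractions.
    Members are not mean-centered by default, so the leading component
    captures the shared mean STAF shape; pass ``center=True`` for variance
    about the population mean.

    Returns ``(components, variance_fractions)`` where ``components`` has
    one (grid-shaped) mode per row.
    """
    pop = _as_population(population)
    x = pop.members.reshape(pop.n, -1)
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("degenerate all-zero population")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    fractions = s**2 / np.sum(s**2)
    components = vt.reshape((-1,) + pop.members.shape[1:])
    return components, fractions
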