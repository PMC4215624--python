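"""Maximal-length shift-register sequences (m-sequences).

An m-sequence of order ``n`` is the output of an ``n``-stage linear-feedback
shift register (LFSR) whose feedback polynomial is primitive over GF(2).  Its
period is ``p = 2**n - 1`` and its circular autocorrelation is nearly a delta
function (``p`` at lag zero, ``-1`` everywhere else), which is what makes it
useful as a broadband probe for linear-system identification: cross-correlating
the system output with the driving sequence recovers the impulse response up to
a small dc error of order ``1/p``.

Conventions
-----------
* Fibonacci-style register; the output is the bit shifted out of the last
  stage.  A tap set is the set of nonzero exponents of the characteristic
  polynomial (the constant term is implicit), e.g. ``{1, 3}`` for
  ``x^3 + x + 1``.  The bit recurrence is
  ``a[t] = a[t-n] XOR (XOR over e in taps, e<n of a[t-(n-e)])``.
* Bits map to steps as ``1 -> +1`` and ``0 -> -1``.
* Primitivity is validated empirically: the register must return to its
  initial state after exactly ``2**n - 1`` shifts and no earlier.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "MSequence",
    "generate_msequence",
    "circular_autocorrelation",
    "circular_crosscorrelation",
    "displacement_statistics",
    "all_primitive_taps",
    "builtin_taps",
    "BUILTIN_TAPS",
]

#: Two known-primitive tap sets per degree (lexicographically first among all
#: primitive characteristic polynomials of that degree), so that a pair of
#: distinct sequences is always available without a search.
BUILTIN_TAPS: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    3: ((1, 3), (2, 3)),
    4: ((1, 4), (3, 4)),
    5: ((2, 5), (3, 5)),
    6: ((1, 6), (5, 6)),
    7: ((1, 7), (3, 7)),
    8: ((1, 2, 7, 8), (1, 3, 5, 8)),
    9: ((4, 9), (5, 9)),
    10: ((3, 10), (7, 10)),
}


def _feedback_lags(order: int, taps: tuple[int, ...]) -> list[int]:
    return sorted(order - e for e in taps if e < order) + [order]


def _lfsr_bits(order: int, taps: tuple[int, ...], init_bits: tuple[int, ...],
               n_bits: int) -> list[int]:
    lags = _feedback_lags(order, taps)
    bits = list(init_bits)
    for t in range(order, n_bits):
        b = 0
        for lag in lags:
            b ^= bits[t - lag]
        bits.append(b)
    return bits


def _lfsr_period(order: int, taps: tuple[int, ...]) -> int | None:
    """Number of shifts after which the register first revisits its start."""
    p = 2**order - 1
    bits = _lfsr_bits(order, taps, (1,) * order, p + order + 1)
    init = tuple(bits[:order])
    for t in range(1, p + 1):
        if tuple(bits[t:t + order]) == init:
            return t
    return None


def _normalize_taps(order: int, taps) -> tuple[int, ...]:
    taps = tuple(sorted(set(int(t) for t in taps)))
    if not taps or taps[-1] != order or taps[0] < 1:
        raise ValueError(
            f"tap set {taps} does not encode a degree-{order} polynomial "
            "(exponents must lie in 1..order and include the order)")
    return taps


@dataclass(frozen=True)
class MSequence:
    """A maximal-length ±1 sequence together with its generator metadata."""

    order: int
    polynomial_taps: tuple[int, ...]
    initial_state: tuple[int, ...]
    values: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        """Period length ``2**order - 1``."""
        return 2**self.order - 1

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=np.int8))
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if len(self.values) != self.p:
            raise ValueError(
                f"sequence length {len(self.values)} != 2**{self.order}-1")
        if not np.all(np.abs(self.values) == 1):
            raise ValueError("sequence entries must be +1 or -1")
        if abs(int(self.values.sum())) != 1:
            raise ValueError("sequence is not balanced (net sum must be +-1)")

    def __len__(self) -> int:
        return self.p


def generate_msequence(order: int, polynomial_taps=None,
                       initial_state=None) -> MSequence:
    """Generate an m-sequence from an LFSR.

    Parameters
    ----------
    order
        Register length ``n``; the sequence period is ``2**n - 1``.
    polynomial_taps
        Nonzero exponents of a primitive characteristic polynomial (constant
        term implicit).  Defaults to the first built-in tap set for ``order``.
    initial_state
        The first ``order`` register bits, any nonzero pattern.  Defaults to
        all ones.

    Raises
    ------
    ValueError
        If the initial state is zero, or if the tap set is not primitive
        (detected by the register period falling short of ``2**n - 1``).
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    if polynomial_taps is None:
        polynomial_taps = builtin_taps(order, 0)
    taps = _normalize_taps(order, polynomial_taps)
    if initial_state is None:
        initial_state = (1,) * order
    state = tuple(int(b) for b in initial_state)
    if len(state) != order or any(b not in (0, 1) for b in state):
        raise ValueError("initial_state must be `order` bits")
    if not any(state):
        raise ValueError("initial_state must be nonzero")
    if _lfsr_period(order, taps) != 2**order - 1:
        raise ValueError(
            f"tap set {taps} is not primitive for degree {order}: "
            f"LFSR period != 2**{order}-1")
    p = 2**order - 1
    bits = np.array(_lfsr_bits(order, taps, state, p), dtype=np.int8)
    values = np.where(bits == 1, 1, -1).astype(np.int8)
    return MSequence(order=order, polynomial_taps=taps,
                     initial_state=state, values=values)


def _as_values(seq) -> np.ndarray:
    if isinstance(seq, MSequence):
        return np.asarray(seq.values, dtype=float)
    return np.asarray(seq, dtype=float)


def circular_autocorrelation(seq, normalized: bool = False) -> np.ndarray:
    """Circular autocorrelation ``R[d] = sum_t x[t] * x[t+d]``.

    For an m-sequence this is ``p`` at lag 0 and ``-1`` at every nonzero lag;
    with ``normalized=True`` both are divided by ``p``.
    """
    x = _as_values(seq)
    p = len(x)
    if p < 3 or (p + 1) & p != 0:  # p+1 must be a power of two
        raise ValueError(f"length {p} is not of the form 2**n - 1")
    r = circular_crosscorrelation(x, x)
    return r / p if normalized else r


def circular_crosscorrelation(seq_a, seq_b) -> np.ndarray:
    """Circular cross-correlation ``C[d] = sum_t a[t] * b[t+d]``.

    ``C`` of a sequence with itself is its autocorrelation; for ``b`` equal to
    ``a`` cyclically shifted by ``d0`` (``b = roll(a, d0)``) the peak ``p``
    appears at lag ``d0``.
    """
    a = _as_values(seq_a)
    b = _as_values(seq_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} != {len(b)}")
    if len(a) == 0:
        raise ValueError("empty sequences")
    out = np.fft.ifft(np.conj(np.fft.fft(a)) * np.fft.fft(b)).real
    return out


def displacement_statistics(seq) -> dict:
    """Net step and excursion scale of the position trajectory of a ±1 drive.

    The figure position is the cumulative sum of the step sequence over one
    period, starting from 0 (the position *after* each step).  ``net_step`` is
    the absolute net displacement in pixels; ``excursion_std`` is the standard
    deviation of the position about its time mean.
    """
    x = _as_values(seq)
    if len(x) == 0:
        raise ValueError("empty sequence")
    pos = np.cumsum(x)
    return {
        "net_step": float(abs(x.sum())),
        "excursion_std": float(np.std(pos)),
    }


@lru_cache(maxsize=None)
def all_primitive_taps(degree: int) -> tuple[tuple[int, ...], ...]:
    """All primitive tap sets of the given degree, by exhaustive period check.

    At degree 7 this yields the full set of 18 primitive polynomials
    (``phi(127)/7``).  Intended for small degrees (<= 12 or so).
    """
    if degree < 2:
        raise ValueError("degree must be >= 2")
    found = []
    for r in range(0, degree):
        for mid in itertools.combinations(range(1, degree), r):
            taps = tuple(sorted(mid + (degree,)))
            if _lfsr_period(degree, taps) == 2**degree - 1:
                found.append(taps)
    return tuple(found)


def builtin_taps(degree: int, index: int = 0) -> tuple[int, ...]:
    """A known-primitive tap set from the built-in table (index 0 or 1)."""
    try:
        return BUILTIN_TAPS[degree][index]
    except KeyError:
        raise ValueError(
            f"no built-in primitive polynomial for degree {degree}; "
            f"available degrees: {sorted(BUILTIN_TAPS)}") from None
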