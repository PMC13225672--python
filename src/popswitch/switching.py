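"""Dwell sequences, strategy cycling, and switching-sequence update laws.

The supervisor accumulates a nonnegative scalar ``s`` (the switching
sequence) from measurement-driven increments.  A strictly increasing dwell
sequence ``tau`` with ``tau(0) = 0`` partitions the nonnegative half line
into intervals ``(tau(j-1), tau(j)]``; the cycling map assigns strategy
``((j-1) mod q) + 1`` to the j-th interval, so strategies are trialled
consecutively as ``s`` grows.  The dwell sequence must grow faster than
exponentially (``tau(j+1)/tau(j) -> infinity``): increments are bounded by
a decreasing function ``chi`` of the measurement, so ``s`` grows at most
exponentially and is eventually trapped inside the interval of a strategy
under which the measured population persists above the threshold ``M``.

Update-law variants: the original single-threshold law, a moving average
of the measured vectors (window ``ta``), a recent-trends law that only
charges increments while the measurement is falling, multiple thresholds
with progressively steeper penalty functions, and a minimum-component law
for multi-population models.  Two policy wrappers modify switching:
override (force a jump to the next dwell interval after ``t_o`` strictly
decreasing measurements within one strategy) and discard (skip strategies
already switched out of, with a full reset once all are rejected).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TauSequence",
    "StrategyCycler",
    "Chi",
    "UpdateLaw",
    "OverrideConfig",
    "ControllerConfig",
    "ControllerState",
    "tau_value",
    "interval_index",
    "strategy_of",
    "threshold_increment",
    "increment_original",
    "increment_recent_trends",
    "increment_multithreshold",
    "increment_multipopulation",
    "moving_average",
    "force_next_interval",
    "override_check",
    "discard_update",
    "NORMS",
]

#: Monotonic norms selectable in update laws (one-norm is the field default:
#: it is the total measured abundance).
NORMS: dict[str, Callable[[np.ndarray], float]] = {
    "l1": lambda v: float(np.sum(np.abs(v))),
    "l2": lambda v: float(np.sqrt(np.sum(np.square(v)))),
    "linf": lambda v: float(np.max(np.abs(v))),
}


@dataclass
class TauSequence:
    """Lazily cached dwell-interval boundary sequence.

    Kinds
    -----
    ``offset_recurrence``
        ``tau(j+1) = c + (j+2) tau(j)`` with ``tau(0) = 0``; the offset
        ``c > 0`` is the length of the first interval.  Satisfies the
        super-exponential growth requirement with ratio ``>= j + 2``.
    ``unit_recurrence``
        ``tau(j+1) = 1 + (j+1) tau(j)``.
    ``custom``
        user recurrence ``fn(j, tau_j) -> tau_{j+1}``; checked strictly
        increasing as values are generated.
    """

    kind: str = "offset_recurrence"
    c: float = 0.35
    fn: Callable[[int, float], float] | None = None
    _values: list = field(default_factory=lambda: [0.0], init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("offset_recurrence", "unit_recurrence", "custom"):
            raise ValueError(f"unknown tau kind {self.kind!r}")
        if self.kind == "offset_recurrence" and not self.c > 0:
            raise ValueError("offset c must be positive")
        if self.kind == "custom" and self.fn is None:
            raise ValueError("custom tau sequence requires fn")

    def _extend(self) -> None:
        j = len(self._values) - 1
        last = self._values[-1]
        if self.kind == "offset_recurrence":
            nxt = self.c + (j + 2) * last
        elif self.kind == "unit_recurrence":
            nxt = 1.0 + (j + 1) * last
        else:
            nxt = float(self.fn(j, last))
        if nxt <= last:
            raise ValueError("tau sequence must be strictly increasing")
        self._values.append(nxt)

    def value(self, j: int) -> float:
        """tau(j); values are cached."""
        if j < 0:
            raise ValueError("index must be nonnegative")
        while len(self._values) <= j:
            self._extend()
        return self._values[j]

    def interval_index(self, z: float) -> int:
        """Index j with ``tau(j-1) < z <= tau(j)``; 0 for ``z = 0``.

        Boundary values belong to the lower interval (intervals are
        half-open below, closed above).
        """
        if z < 0:
            raise ValueError("z must be nonnegative")
        if z == 0:
            return 0
        while self._values[-1] < z:
            self._extend()
        return bisect_left(self._values, z)


def tau_value(tau: TauSequence, j: int) -> float:
    """tau(j) of a dwell sequence."""
    return tau.value(j)


def interval_index(tau: TauSequence, z: float) -> int:
    """Dwell-interval index containing ``z`` (0 for ``z = 0``)."""
    return tau.interval_index(z)


@dataclass
class StrategyCycler:
    """Map switching-sequence values to strategy indices.

    Interval j carries strategy ``((j-1) mod q) + 1``, so the first
    interval (and ``z = 0``) maps to strategy 1 and successive intervals
    cycle ``1, 2, ..., q, 1, 2, ...``.
    """

    tau: TauSequence
    q: int

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("strategy count q must be >= 1")

    def strategy_of(self, z: float) -> int:
        j = self.tau.interval_index(z)
        if j == 0:
            return 1
        return ((j - 1) % self.q) + 1


def strategy_of(cycler: StrategyCycler, z: float) -> int:
    """Strategy index applied at switching-sequence value ``z``."""
    return cycler.strategy_of(z)


# ---------------------------------------------------------------------------
# Update laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chi:
    """Penalty function ``chi(z) = coeff / z**exponent``.

    Restricted to the reciprocal/polynomial family: chi is then decreasing
    and respects exponential growth (``chi(d1 d2^t)`` is itself bounded by
    an exponential in ``t``), the property the supervisor's convergence
    argument needs.
    """

    coeff: float = 1.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (self.coeff > 0 and self.exponent > 0):
            raise ValueError("Chi requires positive coeff and exponent")

    def __call__(self, z: float) -> float:
        if z <= 0:
            raise ValueError("chi is defined on (0, inf)")
        return self.coeff / z**self.exponent


_VARIANTS = (
    "original",
    "moving_average",
    "recent_trends",
    "multi_threshold",
    "multi_population_min",
)


@dataclass
class UpdateLaw:
    """Switching-sequence update law configuration.

    ``thresholds`` is the decreasing list ``M1 >= ... >= M_beta`` (a single
    entry gives the original two-level law); ``chis`` the matching
    pointwise-increasing penalty functions.  ``ta`` is the averaging window
    for the moving-average variant and ``norm`` the monotonic norm applied
    to measured vectors.  Increments are always nonnegative and vanish for
    measurements of zero or at/above the top threshold ``M1``.
    """

    variant: str = "original"
    thresholds: tuple = (1.0,)
    chis: tuple = (Chi(),)
    ta: int = 5
    norm: str = "l1"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown update-law variant {self.variant!r}")
        if isinstance(self.thresholds, (int, float)):
            self.thresholds = (float(self.thresholds),)
        self.thresholds = tuple(float(m) for m in self.thresholds)
        if isinstance(self.chis, Chi):
            self.chis = (self.chis,)
        self.chis = tuple(self.chis)
        if not self.thresholds or any(m <= 0 for m in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(
            self.thresholds[i] < self.thresholds[i + 1]
            for i in range(len(self.thresholds) - 1)
        ):
            raise ValueError("thresholds must be non-increasing: M1 >= ... >= M_beta")
        if len(self.chis) != len(self.thresholds):
            raise ValueError("need one chi per threshold")
        # chi_1 <= ... <= chi_beta pointwise, validated on a sample grid
        zs = np.logspace(-6, 2, 25)
        for i in range(len(self.chis) - 1):
            lo = np.array([self.chis[i](z) for z in zs])
            hi = np.array([self.chis[i + 1](z) for z in zs])
            if np.any(lo > hi * (1 + 1e-12)):
                raise ValueError("chi functions must be pointwise non-decreasing in i")
        if self.ta < 1:
            raise ValueError("averaging window ta must be >= 1")
        if self.norm not in NORMS:
            raise ValueError(f"unknown norm {self.norm!r}")

    @property
    def M(self) -> float:
        """Top switching threshold M1."""
        return self.thresholds[0]

    def norm_fn(self) -> Callable[[np.ndarray], float]:
        return NORMS[self.norm]


def threshold_increment(z: float, law: UpdateLaw) -> float:
    """Multi-threshold increment ``r(z; M, beta)``.

    0 when ``z = 0`` or ``z >= M1``; ``chi_i(z)`` on the band
    ``M_{i+1} <= z < M_i``; ``chi_beta(z)`` below the last threshold.
    Collapses to the original law for a single threshold.
    """
    if z < 0:
        raise ValueError("assessed value must be nonnegative")
    M = law.thresholds
    if z == 0.0 or z >= M[0]:
        return 0.0
    for i in range(len(M) - 1):
        if M[i + 1] <= z < M[i]:
            return float(law.chis[i](z))
    return float(law.chis[-1](z))


def increment_original(z_norm: float, law: UpdateLaw) -> float:
    """Original update law: ``chi(z)`` for ``0 < z < M``, else 0."""
    return threshold_increment(z_norm, law)


def increment_multithreshold(z_norm: float, law: UpdateLaw) -> float:
    """Multi-threshold update law (alias of the banded increment)."""
    return threshold_increment(z_norm, law)


def increment_recent_trends(y_now_norm: float, y_prev_norm: float, law: UpdateLaw) -> float:
    """Recent-trends increment: charge only while the measurement falls.

    ``chi(y_now)`` when ``0 < y_now < M`` and ``y_now < y_prev``, else 0.
    (At the very first time step the original law applies instead; the
    closed-loop engine handles that case.)
    """
    if y_now_norm < 0 or y_prev_norm < 0:
        raise ValueError("norms must be nonnegative")
    if y_now_norm < y_prev_norm:
        return threshold_increment(y_now_norm, law)
    return 0.0


def increment_multipopulation(components: Sequence[float], M: float, chi: Chi) -> float:
    """Minimum-component law for jointly managed populations.

    With ``m = min_i x_i``: 0 when ``m = 0`` or ``m >= M`` (every
    population at or above threshold), else ``chi(m)``.
    """
    comps = np.atleast_1d(np.asarray(components, dtype=float))
    if comps.size == 0:
        raise ValueError("component list must be non-empty")
    if np.any(comps < 0):
        raise ValueError("components must be nonnegative")
    m = float(np.min(comps))
    if m == 0.0 or m >= M:
        return 0.0
    return float(chi(m))


def moving_average(history: Sequence[np.ndarray], t: int, ta: int) -> np.ndarray:
    """Moving average ``a(t)`` of measured vectors ``y(0..t)``.

    The mean of all ``t + 1`` vectors while ``t < ta``, and of the last
    ``ta`` vectors afterwards; componentwise ``a(t) >= y(t) / ta``.
    """
    if len(history) == 0:
        raise ValueError("history must contain at least y(0)")
    if not (0 <= t < len(history)):
        raise ValueError("history must contain y(0..t)")
    if ta < 1:
        raise ValueError("ta must be >= 1")
    lo = 0 if t < ta else t - ta + 1
    block = np.asarray(history[lo : t + 1], dtype=float)
    return block.mean(axis=0)


# ---------------------------------------------------------------------------
# Policies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverrideConfig:
    """Override policy: force a switch after ``t_o`` strict decreases."""

    t_o: int = 10

    def __post_init__(self) -> None:
        if self.t_o < 1:
            raise ValueError("t_o must be >= 1")


def force_next_interval(tau: TauSequence, s: float, jump_offset: float = 0.01) -> float:
    """Jump the switching sequence just inside the next dwell interval.

    With ``j`` the largest index satisfying ``tau(j) < s``, returns
    ``tau(j+1) + jump_offset``; the result exceeds ``s`` and lands
    strictly in the interval after the one containing ``s``.
    """
    if s < 0:
        raise ValueError("s must be nonnegative")
    i = tau.interval_index(s)  # s in (tau(i-1), tau(i)]; largest tau(j) < s is j=i-1
    return tau.value(i) + jump_offset


def override_check(strategies: Sequence[int], norms: Sequence[float], t_o: int) -> bool:
    """Trigger test for the override policy at the current step.

    True iff the same strategy was applied over the last ``t_o`` steps and
    the recorded measurement norms are strictly decreasing over the run of
    ``t_o + 1`` most recent values (``t_o`` strict decreases).
    """
    if t_o < 1:
        raise ValueError("t_o must be >= 1")
    if len(norms) < t_o + 1 or len(strategies) < t_o:
        return False
    recent = strategies[-t_o:]
    if any(h != recent[-1] for h in recent):
        return False
    tail = norms[-(t_o + 1) :]
    return all(tail[i] > tail[i + 1] for i in range(t_o))


def discard_update(
    availability: np.ndarray,
    exited_strategy: int,
    s_new: float,
    cycler: StrategyCycler,
    jump_offset: float = 0.01,
):
    """Discard bookkeeping after a detected strategy change.

    Marks the exited strategy as discarded; when every strategy has been
    discarded, availability resets to all-available; otherwise the
    switching sequence is advanced through dwell intervals until the
    incoming strategy is available.  Returns ``(s, events)`` with the
    possibly advanced switching-sequence value.
    """
    events = ["discard"]
    availability[exited_strategy - 1] = False
    if not availability.any():
        availability[:] = True
        events.append("reset")
        return s_new, events
    while not availability[cycler.strategy_of(s_new) - 1]:
        s_new = force_next_interval(cycler.tau, s_new, jump_offset)
    return s_new, events


# ---------------------------------------------------------------------------
# Controller configuration / state
# ---------------------------------------------------------------------------


@dataclass
class ControllerConfig:
    """Full supervisor configuration: law, dwell sequence, and policies."""

    law: UpdateLaw
    tau: TauSequence = field(default_factory=TauSequence)
    override: bool = False
    t_o: int = 10
    discard: bool = False
    jump_offset: float = 0.01

    def __post_init__(self) -> None:
        if self.t_o < 1:
            raise ValueError("t_o must be >= 1")
        if self.jump_offset <= 0:
            raise ValueError("jump_offset must be positive")


@dataclass
class ControllerState:
    """Mutable supervisor state carried along a closed-loop run."""

    s: float
    availability: np.ndarray
    steps_in_current_strategy: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("switching sequence must start nonnegative")
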