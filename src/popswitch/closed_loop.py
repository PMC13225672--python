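"""Closed-loop engine: plant + measurement + switching supervisor.

Per time step, in order: the applied strategy is read off the current
switching-sequence value; the plant is observed and multiplicative
measurement noise applied; the law-specific assessed quantity (norm,
moving-average norm, or minimum component) is computed from the possibly
delayed measurement stream; the switching sequence is incremented; the
override and discard policies may then force the sequence into later dwell
intervals; finally the state advances under the strategy that was in force.
Runs are deterministic given a seed.

Convergence is assessed by the empirical proxy of a constant switching
sequence over a trailing window (default 100 steps): once the measured
population persists at or above the threshold under the current strategy,
increments vanish and the sequence freezes.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .switching import (
    ControllerConfig,
    StrategyCycler,
    force_next_interval,
    threshold_increment,
)

__all__ = [
    "NoiseSpec",
    "DelaySpec",
    "Trajectory",
    "Metrics",
    "ZeroStateWarning",
    "apply_noise",
    "run_closed_loop",
    "convergence_metrics",
    "fixed_strategy_tail_minimum",
]


class ZeroStateWarning(UserWarning):
    """The state hit exactly zero; the supervisor cannot rescue extinction."""


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative measurement noise ``y = (1 + xi) eta(x)``.

    ``xi`` is drawn i.i.d. uniform on ``[xi_min, xi_max]`` with
    ``-1 < xi_min <= 0 <= xi_max``: the lower bound preserves positivity
    of observations and rules out systematic over-counting.
    """

    xi_min: float = 0.0
    xi_max: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.xi_min <= 0.0):
            raise ValueError("xi_min must lie in (-1, 0]")
        if self.xi_max < 0.0:
            raise ValueError("xi_max must be >= 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.xi_min == self.xi_max:
            return np.full(size, self.xi_min)
        return rng.uniform(self.xi_min, self.xi_max, size)


@dataclass(frozen=True)
class DelaySpec:
    """Measurement delay: the law assesses ``y(t - sigma)``.

    While ``t < sigma`` no measurement is available and the switching
    sequence holds its initial value.  ``sigma = 0`` reproduces the
    undelayed scheme bit for bit.
    """

    sigma: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("delay sigma must be a nonnegative integer")


def apply_noise(clean: np.ndarray, noise: NoiseSpec, xi: float) -> np.ndarray:
    """Scale the whole clean output vector by ``1 + xi``."""
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean output must be nonnegative")
    if not (noise.xi_min <= xi <= noise.xi_max):
        raise ValueError("xi outside the declared noise bounds")
    return (1.0 + xi) * clean


@dataclass
class Trajectory:
    """Closed-loop record over a horizon of ``T`` steps.

    Arrays are indexed by step: ``x`` and ``s`` carry ``T + 1`` entries
    (including the final state), ``h``, ``y``, ``y_clean`` and the norm /
    assessed series carry ``T``.  ``events`` lists ``(t, tag)`` pairs with
    tags among switch / override / discard / reset, effective between
    steps ``t`` and ``t + 1``.
    """

    s: np.ndarray
    x: np.ndarray
    h: np.ndarray
    y: np.ndarray
    y_clean: np.ndarray
    y_norm: np.ndarray
    y_norm_clean: np.ndarray
    a_norm: np.ndarray | None
    assessed: np.ndarray
    events: list
    final_strategy: int
    seed: int | None = None

    @property
    def T(self) -> int:
        return self.h.size

    def to_frame(self) -> pd.DataFrame:
        """Flat per-step table (state columns ``x_1..x_n``)."""
        T = self.T
        ev = {t: [] for t in range(T)}
        for t, tag in self.events:
            ev.setdefault(t, []).append(tag)
        data = {
            "t": np.arange(T),
            "h": self.h,
            "s": self.s[:T],
            "y_norm": self.y_norm,
            "y_norm_clean": self.y_norm_clean,
            "a_norm": self.a_norm if self.a_norm is not None else np.full(T, np.nan),
        }
        for j in range(self.x.shape[1]):
            data[f"x_{j + 1}"] = self.x[:T, j]
        data["event"] = ["+".join(ev.get(t, [])) for t in range(T)]
        return pd.DataFrame(data)


def run_closed_loop(
    model,
    controller: ControllerConfig,
    x0,
    s0: float,
    T: int,
    noise: NoiseSpec | None = None,
    delay: DelaySpec | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate the adaptive switching feedback loop for ``T`` steps.

    Parameters
    ----------
    model:
        Plant with attributes ``q``/``n`` and methods ``step(h, x)`` and
        ``observe(x)``.
    controller:
        Supervisor configuration (update law, dwell sequence, policies).
    x0, s0:
        Nonnegative initial state and initial switching-sequence value.
    noise, delay:
        Optional measurement noise and delay specifications.
    seed, rng:
        Randomness for the noise draws; deterministic given either.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if np.any(x < 0):
        raise ValueError("x0 must be componentwise nonnegative")
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    if T < 1:
        raise ValueError("horizon T must be >= 1")

    law = controller.law
    norm = law.norm_fn()
    cycler = StrategyCycler(controller.tau, model.q)
    sigma = delay.sigma if delay is not None else 0
    if rng is None:
        rng = np.random.default_rng(seed)
    xi = noise.sample(rng, T) if noise is not None else np.zeros(T)

    p_dim = np.atleast_1d(model.observe(x)).size
    n = x.size
    s_arr = np.empty(T + 1)
    x_arr = np.empty((T + 1, n))
    h_arr = np.empty(T, dtype=int)
    y_arr = np.empty((T, p_dim))
    yc_arr = np.empty((T, p_dim))
    ynorm = np.empty(T)
    ynorm_clean = np.empty(T)
    assessed = np.empty(T)
    use_ma = law.variant == "moving_average"
    a_norm = np.empty(T) if use_ma else None
    events: list = []
    avail = np.ones(model.q, dtype=bool)
    ma_buf: deque = deque(maxlen=law.ta)
    warned_zero = False

    s = float(s0)
    s_arr[0] = s
    x_arr[0] = x
    for t in range(T):
        h = cycler.strategy_of(s)
        h_arr[t] = h
        clean = np.atleast_1d(model.observe(x))
        y = (1.0 + xi[t]) * clean
        yc_arr[t] = clean
        y_arr[t] = y
        ynorm[t] = norm(y)
        ynorm_clean[t] = norm(clean)

        if use_ma:
            ma_buf.append(y)
            a = np.mean(ma_buf, axis=0)
            a_norm[t] = norm(a)
            assessed[t] = a_norm[t]
        elif law.variant == "multi_population_min":
            assessed[t] = float(np.min(y))
        else:
            assessed[t] = ynorm[t]

        if not warned_zero and not np.any(x > 0):
            warnings.warn(
                "state reached exactly zero; the supervisor cannot recover "
                "an extinct population",
                ZeroStateWarning,
                stacklevel=2,
            )
            warned_zero = True

        td = t - sigma
        if td < 0:
            inc = 0.0
        elif law.variant == "recent_trends" and td >= 1:
            if assessed[td] < assessed[td - 1]:
                inc = threshold_increment(assessed[td], law)
            else:
                inc = 0.0
        else:
            # original / MA / multi-population / multi-threshold bands;
            # the recent-trends law falls back to this at its first step.
            inc = threshold_increment(assessed[td], law)
        s_next = s + inc

        if controller.override and t >= controller.t_o:
            t_o = controller.t_o
            same = np.all(h_arr[t - t_o + 1 : t + 1] == h)
            tail = ynorm[t - t_o : t + 1]
            decreasing = np.all(tail[:-1] > tail[1:])
            if same and decreasing:
                s_next = force_next_interval(controller.tau, s_next, controller.jump_offset)
                events.append((t, "override"))

        h_next = cycler.strategy_of(s_next)
        if h_next != h:
            events.append((t, "switch"))
            if controller.discard:
                avail[h - 1] = False
                events.append((t, "discard"))
                if not avail.any():
                    avail[:] = True
                    events.append((t, "reset"))
                else:
                    while not avail[cycler.strategy_of(s_next) - 1]:
                        s_next = force_next_interval(
                            controller.tau, s_next, controller.jump_offset
                        )

        x = model.step(h, x)
        s = s_next
        s_arr[t + 1] = s
        x_arr[t + 1] = x

    return Trajectory(
        s=s_arr,
        x=x_arr,
        h=h_arr,
        y=y_arr,
        y_clean=yc_arr,
        y_norm=ynorm,
        y_norm_clean=ynorm_clean,
        a_norm=a_norm,
        assessed=assessed,
        events=events,
        final_strategy=cycler.strategy_of(s),
        seed=seed,
    )


@dataclass(frozen=True)
class Metrics:
    """Convergence summary of a closed-loop run.

    ``converged`` uses the constant-tail proxy: the switching sequence is
    unchanged over the trailing window ``W``.  ``t_conv`` is the first
    step from which ``s`` never changes again within the horizon;
    ``min_obs`` the minimum measured norm up to ``t_conv``; ``n_switches``
    the number of strategy changes up to ``t_conv``.
    """

    converged: bool
    t_conv: int
    min_obs: float
    n_switches: int
    final_strategy: int
    W: int


def convergence_metrics(trajectory: Trajectory, W: int = 100) -> Metrics:
    """Convergence metrics of a trajectory with trailing window ``W``."""
    s = trajectory.s
    if s.size < W:
        raise ValueError("trajectory shorter than the convergence window")
    converged = bool(np.all(s[-W:] == s[-1]))
    changed = np.nonzero(s != s[-1])[0]
    t_conv = int(changed[-1]) + 1 if changed.size else 0
    T = trajectory.T
    t_cap = min(t_conv, T - 1)
    min_obs = float(np.min(trajectory.y_norm[: t_cap + 1]))
    h = trajectory.h
    n_switches = int(np.sum(h[1 : t_cap + 1] != h[:t_cap])) if t_cap >= 1 else 0
    return Metrics(
        converged=converged,
        t_conv=t_conv,
        min_obs=min_obs,
        n_switches=n_switches,
        final_strategy=trajectory.final_strategy,
        W=W,
    )


def fixed_strategy_tail_minimum(
    model, h: int, x0, T: int, burn_in: int, norm: str = "l1"
) -> float:
    """Empirical persistence floor of one fixed strategy.

    Runs the plant under strategy ``h`` alone and returns the minimum
    measured-output norm over steps ``burn_in..T`` -- an empirical probe of
    the long-run lower bound of the observed population, used e.g. to
    place switching thresholds as fractions of a persistent strategy's
    floor.
    """
    if T <= burn_in:
        raise ValueError("T must exceed burn_in")
    from .switching import NORMS

    nfn = NORMS[norm]
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    tail_min = np.inf
    for t in range(T + 1):
        if t >= burn_in:
            tail_min = min(tail_min, nfn(np.atleast_1d(model.observe(x))))
        if t < T:
            x = model.step(h, x)
    return float(tail_min)
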