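"""Positive difference-equation population models and persistence analysis.

Three built-in model families are provided, each indexed by a finite set of
management strategies ``h = 1..q``:

* stage-structured Lur'e models ``x(t+1) = A_h x + b_h g_h(f_h^T x)`` --
  a nonnegative survival/transition matrix plus a scalar density-dependent
  recruitment nonlinearity fed back through a stage-weighting vector;
* delayed Allen-Clark stock-recruitment models
  ``z(t+1) = alpha_h z(t) + beta_h g(z(t-k))`` together with their companion
  (augmented-state) form, which is again a Lur'e system;
* a two-species Pielou system with exponential interaction terms.

All step maps leave the nonnegative orthant invariant and fix the origin,
so the zero state (population absence) is always an equilibrium.

The module also houses the persistence analysis for the Lur'e families.
The critical quantity is the reciprocal steady-state gain

    p_h = 1 / (f_h^T (I - A_h)^{-1} b_h),

the per-capita recruitment slope separating extinction from persistence:
a strategy is extinct when ``sup_z g(z)/z < p``, persistent when the slope
of ``g`` at the origin exceeds ``p``, and all solutions are bounded when
the slope of ``g`` at infinity is below ``p``.  Numeric checkers for the
structural hypotheses used by the switching supervisor (a uniform affine
bound on the step maps, irreducible/primitive minorants, and a locally
unstable linearisation for some strategy) are provided as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RickerNonlinearity",
    "ExponentialRecruitment",
    "StageStructuredLureModel",
    "AllenClarkModel",
    "PielouModel",
    "StrategyClassification",
    "HypothesisReport",
    "spectral_radius",
    "lure_step",
    "pielou_step",
    "allen_clark_companion",
    "steady_state_gain_p",
    "classify_strategy",
    "lure_nonzero_equilibrium",
    "check_structural_hypotheses",
    "is_irreducible",
    "primitivity_exponent",
    "trout_cod_nonlinearities",
    "adult_observation_matrix",
    "trout_cod_initial_states",
    "allen_clark_demo",
    "allen_clark_initial_states",
    "pielou_demo",
    "pielou_initial_states",
]

#: Logarithmic probe grid used when a nonlinearity has no closed-form
#: slope information.  Grid-only verdicts are flagged as non-certified.
PROBE_GRID = np.logspace(-8.0, 4.0, 400)


def spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def _as_nonneg_vector(x, n: int | None = None, name: str = "x") -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if n is not None and v.size != n:
        raise ValueError(f"{name} must have length {n}, got {v.size}")
    if np.any(v < 0) or np.any(~np.isfinite(v)):
        raise ValueError(f"{name} must be componentwise nonnegative and finite")
    return v


# ---------------------------------------------------------------------------
# Scalar recruitment nonlinearities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RickerNonlinearity:
    """Ricker recruitment ``g(z) = sigma * z * exp(-z / rcc)``.

    Parameters
    ----------
    sigma:
        Per-capita recruitment slope at zero abundance (``sigma > 0``).
    rcc:
        Recruit carrying capacity (``rcc > 0``); ``g`` peaks at ``z = rcc``
        with maximum ``sigma * rcc / e``.
    """

    sigma: float
    rcc: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.rcc > 0):
            raise ValueError("RickerNonlinearity requires sigma > 0 and rcc > 0")

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        out = self.sigma * z * np.exp(-z / self.rcc)
        return float(out) if out.ndim == 0 else out

    # Closed-form slope data; g(z)/z = sigma * exp(-z/rcc) is decreasing.
    @property
    def slope_at_zero(self) -> float:
        return self.sigma

    @property
    def sup_slope(self) -> float:
        return self.sigma

    @property
    def limsup_slope(self) -> float:
        return 0.0

    @property
    def sup_value(self) -> float:
        """Global maximum of g, attained at z = rcc."""
        return self.sigma * self.rcc / math.e

    certified: bool = field(default=True, init=False, repr=False)


@dataclass(frozen=True)
class ExponentialRecruitment:
    """Allen-Clark recruitment ``g(w) = w * exp(-kappa * u * w)``.

    ``kappa`` is the density-dependent mortality parameter and ``u`` a fixed
    forcing (environmental variation or harvesting).  The per-capita slope
    at the origin equals one, so persistence under strategy ``h`` reduces to
    ``p_h = (1 - alpha_h) / beta_h < 1``.
    """

    kappa: float
    u: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.u > 0):
            raise ValueError("ExponentialRecruitment requires kappa > 0 and u > 0")

    def __call__(self, w):
        w = np.asarray(w, dtype=float)
        out = w * np.exp(-self.kappa * self.u * w)
        return float(out) if out.ndim == 0 else out

    @property
    def slope_at_zero(self) -> float:
        return 1.0

    @property
    def sup_slope(self) -> float:
        return 1.0

    @property
    def limsup_slope(self) -> float:
        return 0.0

    @property
    def sup_value(self) -> float:
        """Global maximum of g, attained at w = 1/(kappa*u)."""
        return 1.0 / (self.kappa * self.u * math.e)

    certified: bool = field(default=True, init=False, repr=False)


def _slope_profile(g: Callable, grid: np.ndarray):
    """Grid estimates of (slope at 0, sup slope, slope at infinity).

    Used as a fallback for user-supplied nonlinearities without closed-form
    slope attributes; estimates certify nothing (strict sup/liminf
    statements cannot be decided on a finite grid).
    """
    slopes = np.array([float(g(z)) / z for z in grid])
    if np.any(slopes < 0):
        raise ValueError("nonlinearity must be nonnegative on the probe grid")
    return float(slopes[0]), float(np.max(slopes)), float(np.max(slopes[-5:]))


def _slope_data(g: Callable, grid: np.ndarray):
    if hasattr(g, "slope_at_zero"):
        return g.slope_at_zero, g.sup_slope, g.limsup_slope, True
    s0, smax, sinf = _slope_profile(g, grid)
    return s0, smax, sinf, False


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------


@dataclass
class StageStructuredLureModel:
    """Stage-structured Lur'e plant ``x(t+1) = A_h x + b_h g_h(f_h^T x)``.

    Parameters
    ----------
    A:
        Per-strategy nonnegative transition matrices, shape ``(q, n, n)``.
    b:
        Per-strategy recruitment direction vectors, shape ``(q, n)``.
    f:
        Per-strategy density-feedback weighting vectors, shape ``(q, n)``.
    g:
        Per-strategy scalar recruitment nonlinearities with ``g(0) = 0``
        and ``g(z) > 0`` for ``z > 0``.
    C:
        Nonnegative observation matrix mapping states to the measured
        variable ``eta(x) = C x``, shape ``(p, n)``.
    """

    A: np.ndarray
    b: np.ndarray
    f: np.ndarray
    g: tuple
    C: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.g = tuple(self.g)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must have shape (q, n, n)")
        q, n, _ = self.A.shape
        if self.b.shape != (q, n) or self.f.shape != (q, n):
            raise ValueError("b and f must have shape (q, n)")
        if len(self.g) != q:
            raise ValueError("need one nonlinearity per strategy")
        if self.C.ndim != 2 or self.C.shape[1] != n:
            raise ValueError("C must have shape (p, n)")
        for arr, name in ((self.A, "A"), (self.b, "b"), (self.f, "f"), (self.C, "C")):
            if np.any(arr < 0):
                raise ValueError(f"{name} must be componentwise nonnegative")
        for gh in self.g:
            if abs(float(gh(0.0))) > 0.0:
                raise ValueError("nonlinearities must satisfy g(0) = 0")
            if float(gh(1.0)) <= 0.0:
                raise ValueError("nonlinearities must be positive for z > 0")

    @property
    def q(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> int:
        return self.C.shape[0]

    def _check_strategy(self, h: int) -> int:
        if not (1 <= h <= self.q):
            raise ValueError(f"strategy index {h} out of range 1..{self.q}")
        return h - 1

    def step(self, h: int, x) -> np.ndarray:
        """One application of ``F(h, x) = A_h x + b_h g_h(f_h^T x)``."""
        i = self._check_strategy(h)
        x = _as_nonneg_vector(x, self.n)
        z = float(self.f[i] @ x)
        return self.A[i] @ x + self.b[i] * float(self.g[i](z))

    def observe(self, x) -> np.ndarray:
        return self.C @ np.asarray(x, dtype=float)


def lure_step(model: StageStructuredLureModel, h: int, x) -> np.ndarray:
    """Advance a stage-structured Lur'e model one step under strategy ``h``."""
    return model.step(h, x)


@dataclass
class AllenClarkModel:
    """Delayed Allen-Clark model ``z(t+1) = a_h z(t) + b_h g(z(t-k))``.

    Per-strategy parameters: survival ``alpha_h in (0,1)``, maximum
    per-capita reproduction ``beta_h > 0``, density-dependent mortality
    ``kappa_h > 0`` and fixed forcing ``u_h > 0`` entering the recruitment
    ``g(w; u, kappa) = w exp(-kappa u w)``.  The delay ``k`` counts time
    steps between birth and recruitment; the companion form carries the
    history ``(z(t), z(t-1), ..., z(t-k))`` as the state vector.
    """

    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray
    u: np.ndarray
    k: int = 2

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        q = self.alpha.size
        if not (self.beta.size == self.kappa.size == self.u.size == q):
            raise ValueError("parameter vectors must share the strategy count")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha must lie in (0, 1)")
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive")
        if self.k < 0:
            raise ValueError("delay k must be a nonnegative integer")
        self.g = tuple(
            ExponentialRecruitment(float(kh), float(uh))
            for kh, uh in zip(self.kappa, self.u)
        )
        self._companions = tuple(allen_clark_companion(self, h) for h in range(1, q + 1))

    @property
    def q(self) -> int:
        return self.alpha.size

    @property
    def n(self) -> int:
        return self.k + 1

    def _check_strategy(self, h: int) -> int:
        if not (1 <= h <= self.q):
            raise ValueError(f"strategy index {h} out of range 1..{self.q}")
        return h - 1

    def step(self, h: int, x) -> np.ndarray:
        """Companion-form step; exactly reproduces the scalar recursion."""
        i = self._check_strategy(h)
        x = _as_nonneg_vector(x, self.n)
        A, b, _f, c = self._companions[i]
        return A @ x + b * float(self.g[i](float(c @ x)))

    def observe(self, x) -> np.ndarray:
        """Measured variable: the current population ``z(t)`` (first entry)."""
        return np.asarray(x, dtype=float)[:1].copy()


def allen_clark_companion(model: AllenClarkModel, h: int):
    """Companion-form triple-plus-measurement ``(A, b, f, c)`` for strategy h.

    ``A`` carries ``alpha_h`` in its top-left corner and ones on the
    subdiagonal; ``b = (beta_h, 0, ..., 0)``; ``c`` selects the delayed
    state ``z(t-k)`` feeding the recruitment; ``f`` selects the measured
    current population ``z(t)``.
    """
    i = model._check_strategy(h)
    n = model.n
    A = np.zeros((n, n))
    A[0, 0] = model.alpha[i]
    for j in range(1, n):
        A[j, j - 1] = 1.0
    b = np.zeros(n)
    b[0] = model.beta[i]
    f = np.zeros(n)
    f[0] = 1.0
    c = np.zeros(n)
    c[-1] = 1.0
    return A, b, f, c


@dataclass
class PielouModel:
    """Two-species Pielou system with exponential interaction terms.

    ``x1(t+1) = a_h x2 / (c_h + x2) * exp(-x1)`` and
    ``x2(t+1) = b_h x1 / (d_h + x1) * exp(-x2)``; each component is
    bounded by its leading coefficient and the origin is a fixed point.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        q = self.a.size
        if not (self.b.size == self.c.size == self.d.size == q):
            raise ValueError("parameter vectors must share the strategy count")
        for arr, name in ((self.a, "a"), (self.b, "b"), (self.c, "c"), (self.d, "d")):
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def q(self) -> int:
        return self.a.size

    @property
    def n(self) -> int:
        return 2

    def _check_strategy(self, h: int) -> int:
        if not (1 <= h <= self.q):
            raise ValueError(f"strategy index {h} out of range 1..{self.q}")
        return h - 1

    def step(self, h: int, x) -> np.ndarray:
        i = self._check_strategy(h)
        x = _as_nonneg_vector(x, 2)
        x1, x2 = x
        f1 = self.a[i] * x2 / (self.c[i] + x2) * math.exp(-x1)
        f2 = self.b[i] * x1 / (self.d[i] + x1) * math.exp(-x2)
        return np.array([f1, f2])

    def observe(self, x) -> np.ndarray:
        """Both populations are measured exactly: ``y = x``."""
        return np.asarray(x, dtype=float).copy()


def pielou_step(model: PielouModel, h: int, x1: float, x2: float):
    """One Pielou step; returns the pair of next population sizes."""
    out = model.step(h, np.array([x1, x2], dtype=float))
    return float(out[0]), float(out[1])


# ---------------------------------------------------------------------------
# Persistence analysis
# ---------------------------------------------------------------------------


def steady_state_gain_p(A, b, f) -> float:
    """Reciprocal steady-state gain ``p = 1 / (f^T (I - A)^{-1} b)``.

    Requires ``rho(A) < 1`` so that ``(I - A)^{-1}`` exists and is
    nonnegative, and a strictly positive gain (non-degenerate feedback).
    """
    A = np.asarray(A, dtype=float)
    b = _as_nonneg_vector(b, A.shape[0], "b")
    f = _as_nonneg_vector(f, A.shape[0], "f")
    if spectral_radius(A) >= 1.0:
        raise ValueError("steady-state gain requires rho(A) < 1")
    gain = float(f @ np.linalg.solve(np.eye(A.shape[0]) - A, b))
    if gain <= 0.0:
        raise ValueError("degenerate feedback: f^T (I - A)^{-1} b must be positive")
    return 1.0 / gain


@dataclass(frozen=True)
class StrategyClassification:
    """Asymptotic classification of a single fixed strategy.

    ``verdict`` is ``"persistent"`` when the slope of ``g`` at zero exceeds
    ``p``, ``"extinct"`` when the supremum slope is below ``p``, and
    ``"indeterminate"`` otherwise.  ``bounded`` records whether the slope of
    ``g`` at infinity is below ``p`` (all solutions bounded).  ``certified``
    is False when the slope data came from a finite probe grid only.
    """

    p: float
    slope_at_zero: float
    sup_slope: float
    limsup_slope: float
    verdict: str
    bounded: bool
    certified: bool


def _lure_data(model):
    """Per-strategy (A, b, feedback vector, nonlinearity) for Lur'e families."""
    if isinstance(model, StageStructuredLureModel):
        return model.A, model.b, model.f, model.g
    if isinstance(model, AllenClarkModel):
        comps = model._companions
        A = np.stack([c[0] for c in comps])
        b = np.stack([c[1] for c in comps])
        w = np.stack([c[3] for c in comps])  # feedback = delayed-state selector
        return A, b, w, model.g
    raise TypeError(f"not a Lur'e-type model: {type(model).__name__}")


def classify_strategy(model, h: int, grid: np.ndarray | None = None) -> StrategyClassification:
    """Classify strategy ``h`` of a Lur'e-type model as extinct/persistent.

    Uses closed-form slope data for the built-in Ricker and exponential
    recruitment families; otherwise slopes are estimated on a logarithmic
    probe grid and the verdict is flagged as non-certified.
    """
    A, b, w, g = _lure_data(model)
    i = model._check_strategy(h)
    p = steady_state_gain_p(A[i], b[i], w[i])
    s0, smax, sinf, certified = _slope_data(g[i], PROBE_GRID if grid is None else grid)
    if s0 > p:
        verdict = "persistent"
    elif smax < p:
        verdict = "extinct"
    else:
        verdict = "indeterminate"
    return StrategyClassification(
        p=p,
        slope_at_zero=s0,
        sup_slope=smax,
        limsup_slope=sinf,
        verdict=verdict,
        bounded=sinf < p,
        certified=certified,
    )


def lure_nonzero_equilibrium(model, h: int, tol: float = 1e-13):
    """Nonzero equilibrium of a persistent, bounded Lur'e strategy.

    Solves the secant equation ``g_h(z) = p_h z`` for ``z > 0`` (closed
    form for Ricker, ``z* = rcc * ln(sigma / p)``; bracketed root search
    otherwise) and returns ``(z*, x*)`` with
    ``x* = (I - A_h)^{-1} b_h g_h(z*)``, the fixed point of the step map:
    the feedback variable at equilibrium satisfies ``f_h^T x* = z*``.
    """
    A, b, w, g = _lure_data(model)
    i = model._check_strategy(h)
    cls = classify_strategy(model, h)
    if cls.verdict != "persistent":
        raise ValueError(
            f"strategy {h} is classified {cls.verdict!r}; no positive equilibrium"
        )
    p = cls.p
    gi = g[i]
    if isinstance(gi, RickerNonlinearity):
        z_star = gi.rcc * math.log(gi.sigma / p)
    else:
        phi = lambda z: float(gi(z)) - p * z
        z_hi = 1.0
        for _ in range(200):
            if phi(z_hi) < 0.0:
                break
            z_hi *= 10.0
        else:
            raise ValueError("no positive root bracketed for g(z) = p z")
        z_star = brentq(phi, 1e-12, z_hi, xtol=tol)
    if z_star <= 0.0:
        raise ValueError("equilibrium root is not positive")
    if abs(float(gi(z_star)) - p * z_star) > 1e-8 * max(1.0, p * z_star):
        raise ValueError("equilibrium residual too large")
    x_star = np.linalg.solve(np.eye(A.shape[1]) - A[i], b[i]) * float(gi(z_star))
    return float(z_star), x_star


# ---------------------------------------------------------------------------
# Structural hypothesis checks
# ---------------------------------------------------------------------------


def is_irreducible(A: np.ndarray) -> bool:
    """Strong connectivity of the directed adjacency pattern of ``A``."""
    pattern = csr_matrix(np.asarray(A) > 0)
    ncomp, _ = connected_components(pattern, directed=True, connection="strong")
    return bool(ncomp == 1)


def primitivity_exponent(A: np.ndarray) -> int | None:
    """Smallest ``nu`` with ``A^nu`` strictly positive, or None.

    Searches up to the Wielandt bound ``(n-1)^2 + 1``, which is attained
    by primitive matrices with the sparsest possible cycle structure.
    """
    P = np.asarray(A) > 0
    n = P.shape[0]
    Q = P.copy()
    bound = (n - 1) ** 2 + 1
    for nu in range(1, bound + 1):
        if Q.all():
            return nu
        Q = (Q @ P) > 0
    return None


@dataclass(frozen=True)
class HypothesisReport:
    """Numeric check of the supervisor's structural model hypotheses.

    ``X1``/``X2`` witness the uniform affine bound ``F(h, z) <= X1 z + X2``
    (reported only when ``rho(X1) < 1``); ``delta`` scales the rank-one
    recruitment minorant ``A_min + delta b_min w^T`` whose irreducibility
    and primitivity (exponent ``nu``) underpin the decay and coupling
    hypotheses; ``persistence_matrix_unstable`` records whether some
    strategy's minorant has spectral radius above one (a locally unstable
    zero equilibrium, the persistence ingredient).
    """

    X1: np.ndarray | None
    X2: np.ndarray | None
    rho_X1: float | None
    h1_bound: bool
    delta: float | None
    irreducible: bool | None
    primitive: bool | None
    primitivity_exponent: int | None
    persistence_matrix_unstable: bool | None
    certified: bool


def check_structural_hypotheses(model, ball_radius: float = 1.0) -> HypothesisReport:
    """Check the supervisor's structural hypotheses for a built-in family.

    For the Lur'e families: ``X1`` is the componentwise maximum of the
    ``A_h``, ``X2 = mu_max * max_h b_h`` with ``mu_max`` the uniform bound
    on the recruitment nonlinearities (closed form where available,
    probe-grid estimate flagged non-certified otherwise).  The minorant
    ``A_min + delta b_min w_min^T`` uses
    ``delta = min_h g_h(ball_radius) / ball_radius``, the smallest secant
    slope on the stated ball.  For the Pielou family, each component is
    uniformly bounded by its leading coefficient, so the affine bound holds
    with ``X1 = 0``; the matrix-minorant checks do not apply.
    """
    if isinstance(model, PielouModel):
        X2 = np.array([float(np.max(model.a)), float(np.max(model.b))])
        return HypothesisReport(
            X1=np.zeros((2, 2)),
            X2=X2,
            rho_X1=0.0,
            h1_bound=True,
            delta=None,
            irreducible=None,
            primitive=None,
            primitivity_exponent=None,
            persistence_matrix_unstable=None,
            certified=True,
        )
    A, b, w, g = _lure_data(model)
    certified = True
    mu_vals = []
    for gh in g:
        if hasattr(gh, "sup_value"):
            mu_vals.append(float(gh.sup_value))
        else:
            mu_vals.append(float(np.max([gh(z) for z in PROBE_GRID])))
            certified = False
    mu_max = max(mu_vals)
    X1 = A.max(axis=0)
    X2 = mu_max * b.max(axis=0)
    rho_X1 = spectral_radius(X1)
    h1 = rho_X1 < 1.0
    if ball_radius <= 0:
        raise ValueError("ball_radius must be positive")
    delta = min(float(gh(ball_radius)) / ball_radius for gh in g)
    minorant = A.min(axis=0) + delta * np.outer(b.min(axis=0), w.min(axis=0))
    irr = is_irreducible(minorant)
    nu = primitivity_exponent(minorant) if irr else None
    unstable = any(
        spectral_radius(A[i] + delta * np.outer(b[i], w[i])) > 1.0
        for i in range(A.shape[0])
    )
    return HypothesisReport(
        X1=X1 if h1 else None,
        X2=X2 if h1 else None,
        rho_X1=rho_X1,
        h1_bound=h1,
        delta=delta,
        irreducible=irr,
        primitive=nu is not None,
        primitivity_exponent=nu,
        persistence_matrix_unstable=unstable,
        certified=certified,
    )


# ---------------------------------------------------------------------------
# Built-in parameter sets
# ---------------------------------------------------------------------------


def trout_cod_nonlinearities() -> tuple[RickerNonlinearity, ...]:
    """Ricker recruitment triples for the three trout-cod strategies.

    Strategy 1 is no intervention (extinction); strategies 2 and 3 boost
    recruitment of one-year-old fish and are persistent against the
    critical slope p = 0.4792.  Units: thousands of female fish.
    """
    return (
        RickerNonlinearity(sigma=0.3257, rcc=22.834),
        RickerNonlinearity(sigma=1.3026, rcc=22.834),
        RickerNonlinearity(sigma=39.078, rcc=5.0742),
    )


def adult_observation_matrix(n: int = 7, observed: int = 3) -> np.ndarray:
    """Observation matrix selecting the last ``observed`` (adult) stages."""
    C = np.zeros((observed, n))
    for i in range(observed):
        C[i, n - observed + i] = 1.0
    return C


def trout_cod_initial_states() -> tuple[np.ndarray, ...]:
    """Seven-stage initial vectors for the three surveyed populations.

    Observed adult one-norms: 9.52, 0.88 and 0.03 thousand female fish
    (Murray River, Ovens River, Bendora Dam).
    """
    return (
        np.array([7.7601, 3.2057, 1.4681, 0.9816, 1.1582, 0.8896, 7.4739]),
        np.array([0.7519, 0.3413, 0.1658, 0.2467, 0.1122, 0.2308, 0.5395]),
        np.array([0.0274, 0.0154, 0.0105, 0.0055, 0.0037, 0.0034, 0.0234]),
    )


def allen_clark_demo() -> AllenClarkModel:
    """Three-strategy delayed Allen-Clark model (two-step delay).

    Strategy 1 is the unforced baseline; strategies 2 and 3 add fixed
    forcing.  Strategies 1 and 3 are persistent (p = 0.15, 0.075 below
    the unit slope at zero); strategy 2 is extinct (p = 1.2).
    """
    return AllenClarkModel(
        alpha=(0.1, 0.4, 0.1),
        beta=(6.0, 0.5, 12.0),
        kappa=(1.5, 2.0, 1.5),
        u=(1.0, 0.9, 1.5),
        k=2,
    )


def allen_clark_initial_states() -> tuple[np.ndarray, ...]:
    """Companion-form initial states ``(z(0), z(-1), z(-2))``."""
    return (
        np.array([0.2, 0.0, 0.0]),
        np.array([0.8, 0.0, 0.0]),
        np.array([1.5, 0.0, 0.0]),
    )


def pielou_demo() -> PielouModel:
    """Two-strategy Pielou system; strategy 1 persists, strategy 2 does not."""
    return PielouModel(a=(0.8, 0.6), b=(0.9, 0.5), c=(0.6, 0.8), d=(0.5, 0.9))


def pielou_initial_states() -> tuple[np.ndarray, ...]:
    """Three small two-species initial vectors for the Pielou example."""
    return (
        np.array([0.1530, 0.03942]),
        np.array([0.0449, 0.1188]),
        np.array([0.0586, 0.3024]),
    )
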