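"""Simulation studies: surrogate fixture, sweeps, and the 24-system study.

The published trout-cod vital-rate matrix is not available, so
``make_fixture`` synthesises a seven-stage surrogate constrained to the
printed summary quantities: spectral radius 0.8931 of the linear part and
critical recruitment slope p = 0.4792, shared by all strategies, with the
three Ricker recruitment strategies and adult-stage observation attached.
Quantities that depend on the exact matrix (convergence percentages, the
strategy-3 oscillation floor) are therefore reproduced directionally, not
numerically.

Sweeps: a noise-magnitude x switching-threshold grid of convergence rates;
randomized robustness sweeps over the first dwell-interval length, the
initial switching-sequence value, and perturbed initial stage vectors;
and a factorial comparison of 24 switching systems (three update laws x
multiple-threshold / override / discard flags) on a shared ensemble of
initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .closed_loop import (
    DelaySpec,
    NoiseSpec,
    convergence_metrics,
    fixed_strategy_tail_minimum,
    run_closed_loop,
)
from .models import (
    StageStructuredLureModel,
    adult_observation_matrix,
    classify_strategy,
    lure_nonzero_equilibrium,
    trout_cod_nonlinearities,
)
from .switching import Chi, ControllerConfig, TauSequence, UpdateLaw

__all__ = [
    "FixtureSpec",
    "SweepSpec",
    "SystemSpec",
    "make_fixture",
    "equilibrium_band_ics",
    "noise_threshold_grid",
    "randomized_robustness_sweep",
    "system_specs",
    "build_switching_system",
    "comparison_ensemble",
    "compare_systems",
]

#: Observed-adult-abundance bands (thousands of breeding females) from
#: which initial stage vectors are drawn: large, medium and near-critical
#: river populations.
DEFAULT_BANDS = ((5.0, 10.0), (0.5, 2.5), (0.025, 0.05))


def _child_seed(seed_seq: np.random.SeedSequence, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_seq.entropy, spawn_key=key))


@dataclass(frozen=True)
class FixtureSpec:
    """Constraints for the surrogate stage-structured fixture."""

    n: int = 7
    target_rho: float = 0.8931
    target_p: float = 0.4792
    observed: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.target_rho < 1):
            raise ValueError("target_rho must lie in (0, 1)")
        if self.target_p <= 0:
            raise ValueError("target_p must be positive")
        if not (1 <= self.observed <= self.n):
            raise ValueError("observed stage count out of range")


def make_fixture(
    spec: FixtureSpec = FixtureSpec(), nonlinearities=None
) -> StageStructuredLureModel:
    """Synthesise a surrogate stage-structured model hitting rho and p.

    A random survival-diagonal plus stage-progression-subdiagonal pattern
    is drawn and rescaled so its spectral radius (the largest survival
    entry, the matrix being lower triangular) equals ``target_rho``
    exactly.  Density feedback weights the observed adult stages with unit
    coefficients, so the feedback variable equals the observed abundance;
    recruitment enters stage one with ``b`` scaled through the gain
    formula so that ``1/(f^T (I-A)^{-1} b)`` equals ``target_p`` exactly.
    The recruitment term makes the strategy-independent linear pattern
    irreducible (adults feed back into stage one).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    surv = rng.uniform(0.3, 0.9, n)
    prog = rng.uniform(0.3, 0.9, n - 1)
    A1 = np.diag(surv) + np.diag(prog, k=-1)
    A1 *= spec.target_rho / float(np.max(surv))
    f1 = np.zeros(n)
    f1[n - spec.observed :] = 1.0
    e1 = np.zeros(n)
    e1[0] = 1.0
    gain_unit = float(f1 @ np.linalg.solve(np.eye(n) - A1, e1))
    b1 = e1 / (spec.target_p * gain_unit)
    g = tuple(nonlinearities) if nonlinearities is not None else trout_cod_nonlinearities()
    q = len(g)
    return StageStructuredLureModel(
        A=np.stack([A1] * q),
        b=np.stack([b1] * q),
        f=np.stack([f1] * q),
        g=g,
        C=adult_observation_matrix(n, spec.observed),
    )


def equilibrium_band_ics(
    model: StageStructuredLureModel,
    n_per_band: int,
    rng: np.random.Generator,
    bands=DEFAULT_BANDS,
    equilibrium_strategy: int = 2,
) -> list[np.ndarray]:
    """Initial stage vectors as equilibrium-scaled band perturbations.

    Each vector is the nonzero equilibrium of the reference persistent
    strategy, jittered componentwise (uniform factors in [0.5, 1.5]) and
    rescaled so its observed one-norm lands uniformly inside the band.
    """
    _, x_star = lure_nonzero_equilibrium(model, equilibrium_strategy)
    ics = []
    for lo, hi in bands:
        for _ in range(n_per_band):
            v = x_star * rng.uniform(0.5, 1.5, x_star.size)
            target = rng.uniform(lo, hi)
            obs = float(np.sum(model.observe(v)))
            ics.append(v * (target / obs))
    return ics


# ---------------------------------------------------------------------------
# Noise x threshold grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """Grid and replication settings for the noise/threshold sweep.

    Defaults run a reduced-scale study (5 x 5 grid, 10 initial conditions
    per abundance band, horizon 2,000); the full-scale study used a
    21 x 19 grid with 100 initial conditions per band and horizon 10,000.
    """

    xi_max_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    m_fractions: tuple = (0.05, 0.275, 0.5, 0.725, 0.95)
    n_ics_per_band: int = 10
    T: int = 2000
    W: int = 100
    s0: float = 7.0
    tau_c: float = 0.35
    bands: tuple = DEFAULT_BANDS
    seed: int = 0


def _persistence_floor(model, T: int = 3000, burn_in: int = 1500) -> float:
    """Largest empirical tail floor among persistent strategies."""
    best = 0.0
    for h in range(1, model.q + 1):
        if classify_strategy(model, h).verdict != "persistent":
            continue
        _, x_star = lure_nonzero_equilibrium(model, h)
        floor = fixed_strategy_tail_minimum(model, h, x_star, T, burn_in)
        best = max(best, floor)
    if best <= 0:
        raise ValueError("model supplies no persistent strategy with a positive floor")
    return best


def noise_threshold_grid(model, sweep: SweepSpec = SweepSpec()) -> pd.DataFrame:
    """Percent of runs converged per (noise magnitude, threshold) cell.

    Thresholds are fractions of the empirical persistence floor y*; every
    cell runs the identical initial-condition ensemble with the original
    one-norm reciprocal law.  Columns: ``xi_max, M, m_fraction,
    pct_converged, n``.
    """
    if sweep.n_ics_per_band < 1:
        raise ValueError("need at least one initial condition per band")
    y_star = _persistence_floor(model)
    ss = np.random.SeedSequence(sweep.seed)
    ics = equilibrium_band_ics(
        model, sweep.n_ics_per_band, _child_seed(ss, 0), sweep.bands
    )
    rows = []
    for i, xi_max in enumerate(sweep.xi_max_grid):
        for j, frac in enumerate(sweep.m_fractions):
            M = frac * y_star
            law = UpdateLaw(variant="original", thresholds=(M,), chis=(Chi(),))
            controller = ControllerConfig(law=law, tau=TauSequence(c=sweep.tau_c))
            # symmetric noise band; the lower bound is clamped just inside
            # the admissible open interval (-1, 0] when xi_max reaches 1
            xi_lo = max(-float(xi_max), -1.0 + 1e-12)
            noise = NoiseSpec(xi_min=xi_lo, xi_max=xi_max) if xi_max > 0 else None
            n_conv = 0
            for k, x0 in enumerate(ics):
                traj = run_closed_loop(
                    model,
                    controller,
                    x0,
                    sweep.s0,
                    sweep.T,
                    noise=noise,
                    rng=_child_seed(ss, 1, i, j, k),
                )
                if convergence_metrics(traj, sweep.W).converged:
                    n_conv += 1
            rows.append(
                {
                    "xi_max": xi_max,
                    "M": M,
                    "m_fraction": frac,
                    "pct_converged": 100.0 * n_conv / len(ics),
                    "n": len(ics),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Randomized robustness sweeps
# ---------------------------------------------------------------------------


def randomized_robustness_sweep(
    model,
    which: str,
    count: int,
    seed: int = 0,
    base_ics=None,
    s0: float = 7.0,
    M: float = 7.5,
    tau_c: float = 0.35,
    T: int = 2000,
    W: int = 100,
) -> pd.DataFrame:
    """Sweep one source of run-to-run variability and tabulate outcomes.

    ``which`` selects the randomized quantity: ``"tau1"`` draws the first
    dwell-interval length uniformly from (0, 8); ``"s0"`` draws the
    initial switching-sequence value from (0, 14); ``"x0"`` multiplies the
    base initial vectors componentwise by factors uniform on (0, M/2).
    Columns: ``which, value, ic, final_strategy, converged, t_conv``.
    """
    if which not in ("tau1", "s0", "x0"):
        raise ValueError(f"unknown sweep axis {which!r}")
    ss = np.random.SeedSequence(seed)
    rng = _child_seed(ss, 0)
    if base_ics is None:
        base_ics = equilibrium_band_ics(model, 1, _child_seed(ss, 1))
    law = UpdateLaw(variant="original", thresholds=(M,), chis=(Chi(),))
    rows = []
    for i in range(count):
        if which == "tau1":
            val = float(rng.uniform(0.0, 8.0))
            tau = TauSequence(c=val)
            runs = [(j, x0, s0) for j, x0 in enumerate(base_ics)]
        elif which == "s0":
            val = float(rng.uniform(0.0, 14.0))
            tau = TauSequence(c=tau_c)
            runs = [(j, x0, val) for j, x0 in enumerate(base_ics)]
        else:
            factors = rng.uniform(0.0, M / 2.0, model.n)
            val = float(np.mean(factors))
            tau = TauSequence(c=tau_c)
            runs = [(j, np.asarray(x0) * factors, s0) for j, x0 in enumerate(base_ics)]
        controller = ControllerConfig(law=law, tau=tau)
        for j, x0, s_init in runs:
            traj = run_closed_loop(model, controller, x0, s_init, T)
            met = convergence_metrics(traj, W)
            rows.append(
                {
                    "which": which,
                    "value": val,
                    "ic": j,
                    "final_strategy": met.final_strategy,
                    "converged": met.converged,
                    "t_conv": met.t_conv,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 24-system factorial comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SystemSpec:
    """One cell of the switching-system factorial design (id 1..24)."""

    id: int
    update_law: str
    mst: bool
    override: bool
    discard: bool


def system_specs() -> tuple[SystemSpec, ...]:
    """The 24-system factorial: {original, MA, RT} x MST x OR x DRS.

    Within each block of eight: 1 none, 2 MST, 3 OR, 4 DRS, 5 MST+OR,
    6 MST+DRS, 7 OR+DRS, 8 MST+OR+DRS.
    """
    laws = ("original", "moving_average", "recent_trends")
    flags = (
        (False, False, False),
        (True, False, False),
        (False, True, False),
        (False, False, True),
        (True, True, False),
        (True, False, True),
        (False, True, True),
        (True, True, True),
    )
    specs = []
    for li, law in enumerate(laws):
        for fi, (mst, orr, drs) in enumerate(flags):
            specs.append(
                SystemSpec(
                    id=li * 8 + fi + 1, update_law=law, mst=mst, override=orr, discard=drs
                )
            )
    return tuple(specs)


def build_switching_system(
    spec: SystemSpec,
    M: float = 7.5,
    tau: TauSequence | None = None,
    ta: int = 5,
    t_o: int = 10,
) -> ControllerConfig:
    """Controller configuration for one factorial cell.

    With MST, a second threshold at M/2 doubles the reciprocal penalty;
    override uses a ten-step decrease run; the moving average spans five
    steps.
    """
    if not 1 <= spec.id <= 24:
        raise ValueError("system id must lie in 1..24")
    if spec.mst:
        thresholds = (M, M / 2.0)
        chis = (Chi(coeff=1.0), Chi(coeff=2.0))
    else:
        thresholds = (M,)
        chis = (Chi(coeff=1.0),)
    law = UpdateLaw(variant=spec.update_law, thresholds=thresholds, chis=chis, ta=ta)
    return ControllerConfig(
        law=law,
        tau=tau if tau is not None else TauSequence(c=0.35),
        override=spec.override,
        t_o=t_o,
        discard=spec.discard,
    )


def comparison_ensemble(
    model, count: int, seed: int = 0, bands=DEFAULT_BANDS
) -> list[tuple[np.ndarray, float, float]]:
    """Shared ensemble of (x0, s0, tau1) triples for the comparison study.

    Initial vectors cycle through the abundance bands; s0 is uniform on
    (0, 14) and the first dwell-interval length uniform on (0, 8).
    """
    if count < 1:
        raise ValueError("ensemble must be non-empty")
    ss = np.random.SeedSequence(seed)
    rng = _child_seed(ss, 0)
    per_band = -(-count // len(bands))
    ics = equilibrium_band_ics(model, per_band, _child_seed(ss, 1), bands)
    # interleave bands so truncation keeps all bands represented
    order = np.arange(len(ics)).reshape(len(bands), per_band).T.ravel()
    ics = [ics[i] for i in order[:count]]
    s0s = rng.uniform(0.0, 14.0, count)
    tau1s = rng.uniform(0.0, 8.0, count)
    return [(ics[i], float(s0s[i]), float(tau1s[i])) for i in range(count)]


def compare_systems(
    model,
    ensemble,
    T: int = 2000,
    W: int = 100,
    M: float = 7.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all 24 switching systems on the identical ensemble.

    Returns ``(summary, runs)``: per-system aggregates (percent converged,
    percent per final strategy among converged runs, median/max
    convergence time, min/median minimum observed population, median/max
    switch count) and the per-run records.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    run_rows = []
    for spec in system_specs():
        for i, (x0, s0, tau1) in enumerate(ensemble):
            controller = build_switching_system(spec, M=M, tau=TauSequence(c=tau1))
            traj = run_closed_loop(model, controller, x0, s0, T)
            met = convergence_metrics(traj, W)
            run_rows.append(
                {
                    "system": spec.id,
                    "update_law": spec.update_law,
                    "mst": spec.mst,
                    "override": spec.override,
                    "discard": spec.discard,
                    "ic": i,
                    "s0": s0,
                    "tau1": tau1,
                    "converged": met.converged,
                    "t_conv": met.t_conv,
                    "min_obs": met.min_obs,
                    "n_switches": met.n_switches,
                    "final_strategy": met.final_strategy,
                }
            )
    runs = pd.DataFrame(run_rows)
    summaries = []
    for spec in system_specs():
        sub = runs[runs["system"] == spec.id]
        conv = sub[sub["converged"]]
        row = {
            "system": spec.id,
            "update_law": spec.update_law,
            "mst": spec.mst,
            "override": spec.override,
            "discard": spec.discard,
            "pct_converged": 100.0 * len(conv) / len(sub),
            "median_t_conv": float(conv["t_conv"].median()) if len(conv) else np.nan,
            "max_t_conv": float(conv["t_conv"].max()) if len(conv) else np.nan,
            "min_min_obs": float(sub["min_obs"].min()),
            "median_min_obs": float(sub["min_obs"].median()),
            "median_n_switches": float(conv["n_switches"].median()) if len(conv) else np.nan,
            "max_n_switches": float(conv["n_switches"].max()) if len(conv) else np.nan,
        }
        for h in range(1, model.q + 1):
            share = (
                100.0 * float((conv["final_strategy"] == h).sum()) / len(conv)
                if len(conv)
                else np.nan
            )
            row[f"pct_strategy_{h}"] = share
        summaries.append(row)
    return pd.DataFrame(summaries), runs
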