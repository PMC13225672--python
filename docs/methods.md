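# Methods

## Model families and their assumptions

All plants are positive difference equations: step maps send the
nonnegative orthant into itself and fix the origin, so population absence
is always an equilibrium and the supervisor's job is to destabilise it in
the direction of persistence.

**Stage-structured Lur'e models.** `x(t+1) = A_h x + b_h g_h(f_h' x)`
with nonnegative `A_h` (survival/transition), recruitment direction
`b_h`, density-feedback weights `f_h`, and a scalar nonlinearity `g_h`
with `g_h(0) = 0`, `g_h(z) > 0` for `z > 0`. The built-in recruitment
families are Ricker, `g(z) = sigma z exp(-z/rcc)` (parameters: slope at
zero `sigma`, recruit carrying capacity `rcc`; maximum `sigma rcc / e`),
and the exponential form `g(w) = w exp(-kappa u w)` (density-dependent
mortality `kappa`, fixed forcing `u`; unit slope at zero, maximum
`1/(kappa u e)`). Measurements are `y = C x` for a nonnegative `C`
(non-decreasing, as a measurement of abundances should be).

**Delayed Allen-Clark models.** The scalar recursion
`z(t+1) = alpha_h z(t) + beta_h g(z(t-k))` is carried in companion form:
the state is the history `(z(t), ..., z(t-k))`, the companion matrix has
`alpha_h` in its corner and ones on the subdiagonal, recruitment enters
the first component and is fed by the last (delayed) one, and the
measurement selects the current population. The companion step is
algebraically identical to the scalar recursion; the test suite checks
agreement against a directly iterated scalar oracle to 1e-12 relative
over 100 steps.

**Pielou two-species system.** `x1' = a x2/(c + x2) e^{-x1}`,
`x2' = b x1/(d + x1) e^{-x2}`: saturating-times-exponential coupling,
each component bounded by its leading coefficient, both populations
measured exactly.

## Persistence classification

For Lur'e-type strategies with `rho(A_h) < 1`, asymptotics are governed
by comparing secant slopes of `g_h` with the reciprocal steady-state gain
`p_h = 1/(f_h' (I - A_h)^{-1} b_h)` (for the Allen-Clark companion
triple this reduces to `(1 - alpha_h)/beta_h`, which the implementation
verifies against the resolvent formula). Verdicts are *persistent*
(slope at zero above `p`), *extinct* (supremum slope below `p`), else
*indeterminate*; boundedness needs the slope at infinity below `p`.
Slopes use closed forms for the built-in families; user-supplied
nonlinearities fall back to a logarithmic probe grid (1e-8 to 1e4, 400
points) and the verdict is flagged non-certified, since strict
sup/liminf inequalities cannot be decided on a finite grid.

The nonzero equilibrium solves the secant equation `g(z*) = p z*`
(closed form `z* = rcc ln(sigma/p)` for Ricker, bracketed Brent search
otherwise, tolerance 1e-13). The state-space fixed point is
`x* = (I - A)^{-1} b g(z*)`; note that at this fixed point the feedback
variable equals `z*` itself — scaling `(I - A)^{-1} b` by `z*` instead
produces a vector on the same ray but off the fixed point by the factor
`p`, an easy slip to make with this construction. Only the scale of
generated initial conditions depends on the choice; the implementation
uses the true fixed point.

## Structural hypothesis checks

The supervisor's convergence argument needs: (i) uniform boundedness of
solutions, witnessed by an affine bound `F(h, z) <= X1 z + X2` with
`rho(X1) < 1`, built from the componentwise maxima of `A_h` and `b_h` and
the uniform recruitment bound; (ii) at-worst-exponential decay and a
measurement/state coupling, witnessed by an irreducible and primitive
minorant `A_min + delta b_min w'` (with `w` the feedback selector and
`delta` the smallest secant slope of the recruitment on a probe ball,
radius 1 by default); and (iii) a strategy whose minorant has spectral
radius above one (locally unstable extinction equilibrium). These are
checked numerically: strong connectivity via the adjacency digraph,
primitivity by boolean matrix powers up to the Wielandt bound
`(n-1)^2 + 1` with the exponent reported. For the Pielou family the
affine bound holds trivially with `X1 = 0`; the matrix-minorant checks do
not apply to it.

## Supervisor parameters

* `tau_c` (default 0.35): first dwell-interval length in the offset
  recurrence `tau(j+1) = c + (j+2) tau(j)`. Longer intervals trial
  strategies longer ("sluggish"), shorter ones switch faster ("rapid").
* `M`: switching threshold, in measurement units (here thousands of
  individuals) — the abundance the manager deems acceptable. A list
  `M1 >= ... >= M_beta` activates the multi-threshold law with
  pointwise-increasing penalties `chi_1 <= ... <= chi_beta`.
* `chi` (default `1/z`): restricted to the reciprocal/polynomial family
  `coeff / z^exponent`, which is decreasing and maps exponentially
  decaying arguments to at-most-exponentially growing increments by
  construction — the growth-rate mismatch with `tau` that drives
  convergence. Arbitrary non-monotone penalty functions are out of scope.
* `ta` (default 5): moving-average window, in steps. The average of the
  measured vectors dominates `y(t)/ta` componentwise, so persistence of
  `y` above `M` implies the averaged law eventually freezes too.
* `t_o` (default 10): override run length — a forced switch after `t_o`
  consecutive strict decreases of the measured norm within one strategy.
  The trigger requires `t_o + 1` recorded values (`t_o` strict
  decreases); a run of `t_o + 2` values would be the other defensible
  convention and the shorter one is used here.
* `jump_offset` (default 0.01): forced switches set `s` to
  `tau(j+1) + 0.01` where `tau(j)` is the largest boundary below `s`;
  the jump always lands strictly in the next dwell interval.
* Boundary conventions: a value exactly on a dwell boundary belongs to
  the lower interval; a measurement exactly at `M` yields a zero
  increment; the recent-trends law applies the original law at its first
  assessed step; `s(0) = s0` and `z = 0` maps to strategy 1.
* Noise: one scalar factor `1 + xi(t)` per step applied to the whole
  output vector, `xi` uniform on `[xi_min, xi_max]` with
  `-1 < xi_min <= 0 <= xi_max`. Componentwise noise is out of scope.
  With noise the effective persistence requirement tightens to
  `(1 + xi_min) * floor > M`.
* Delay: the law assesses `y(t - sigma)`; while `t < sigma` the
  switching sequence holds `s0`.

Engine ordering within a step: read strategy, measure (noise), assess
(possibly delayed), increment `s`, apply override, then discard
bookkeeping whenever the mapped strategy changed (by accumulation or by
override), then advance the state. The switching sequence is
non-decreasing along every trajectory, including under both policies.

## Convergence metrics

Persistence of a run is judged by an empirical proxy: the switching
sequence unchanged over a trailing window `W` (default 100 steps).
`t_conv` is the first step after which `s` never changes within the
horizon, `min_obs` the minimum measured norm up to `t_conv`, and
`n_switches` the number of strategy changes up to `t_conv`. The proxy is
a finite-horizon stand-in for the asymptotic persistence definition
(uniform positive lower bounds on the measured output), which is not
computable from finite simulation; similarly `fixed_strategy_tail_minimum`
probes a strategy's long-run floor by the minimum observed norm after a
burn-in, not by a liminf.

## The surrogate fixture

The seven-stage fish example is driven by a vital-rate matrix published
only in earlier work, so `make_fixture` synthesises a surrogate
constrained to the reported summary quantities: a random
survival-diagonal plus progression-subdiagonal pattern rescaled so its
spectral radius equals 0.8931 exactly (the matrix is triangular, so the
radius is its largest survival entry), density feedback with unit
weights on the three observed adult stages, and recruitment into stage
one scaled through the gain formula so `p = 0.4792` exactly. All three
strategies share the linear data and differ only in their Ricker
recruitment, which classifies them (extinct, persistent, persistent).
Generated fixtures pass the structural checks (affine bound, irreducible
and primitive minorant).

What the surrogate does *not* emulate: the true matrix's transient
structure. In particular its triangular linear part has a real positive
spectrum, so fixed-strategy approaches to equilibrium are monotone
rather than damped-oscillatory; the override policy therefore fires
repeatedly during benign monotone approaches and during the long
monotone stretches of the strongly overcompensating third strategy's
oscillation, inflating switch counts and convergence times for
override-enabled systems relative to what an oscillatory matrix would
show. Matrix-specific reference figures (final-strategy percentages,
median convergence times, the ~9.5 oscillation floor) are accordingly
treated as directional, not numerical, targets.

## Simulation studies and problem sizes

Initial stage vectors are generated as equilibrium-scaled band
perturbations: the persistent reference strategy's fixed point, jittered
componentwise (uniform factors in [0.5, 1.5]) and rescaled so the
observed adult abundance lands uniformly in one of three bands — 5–10,
0.5–2.5, and 0.025–0.05 thousand breeding females, mirroring large,
medium and near-critical river populations.

The package's study defaults are reduced-scale versions of the full
designs, chosen to keep a complete run on a single CPU in minutes while
preserving the qualitative conclusions: the noise x threshold grid runs
5 x 5 cells (full design 21 x 19) with 10 initial conditions per band
(full: 100) and horizon 2,000 (full: 10,000); thresholds are fractions
of the empirical persistence floor `y*`, taken as the largest
fixed-strategy tail minimum among persistent strategies (for the
surrogate that is the second strategy's equilibrium; the full-scale
design took it from its matrix's oscillatory third strategy). The
symmetric noise
band is clamped just inside the admissible interval when `xi_max`
reaches 1. The randomized robustness sweeps draw the first dwell
interval from (0, 8), the initial switching value from (0, 14), or
componentwise initial-state factors from (0, M/2). The 24-system
factorial study (three update laws x multi-threshold x override x
discard; moving average `ta = 5`, second threshold `M/2` with doubled
penalty, `t_o = 10`) runs a shared seeded ensemble of (x0, s0, tau(1))
triples — identical across systems by construction — at ensemble size 20
and horizon 2,000 in the test suite.

Passing these studies shows that the supervisor's qualitative behaviour
(degradation with noise and with threshold height, universal convergence
to persistent strategies, the recent-trends law's faster convergence)
is reproduced on a constrained surrogate under deterministic seeds. It
does not validate the unpublished matrix's quantitative figures, nor
behaviour under process (dynamic) stochasticity, which is out of scope
along with continuous-time dynamics and state estimation.

## Degenerate and edge cases

A state that reaches exactly zero triggers a warning (not an error):
increments are zero there and the supervisor cannot rescue an extinct
population. A secant equation whose only solution is the origin (slope
at zero equal to `p`) raises rather than returning a spurious root.
Custom dwell recurrences are validated strictly increasing as values are
generated. User-supplied nonlinearities without a known uniform bound
have their affine-bound constant estimated on the probe grid and the
hypothesis report flagged non-certified.
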