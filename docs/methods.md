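# Methods

## Model and assumptions

The package integrates the forced love-affair system

    dR/dt = a R + b J (1 − |J|) + y(t),
    dJ/dt = c R (1 − |R|) + d J + f(t),      y(t) = A sin(ω π t) + B,

with `f ≡ 0` in the standard configuration (the advice enters Romeo's
equation only; `target` can route it to Juliet or both).  The saturating
factors `x(1 − |x|)` cap the effectiveness of very strong feelings and
make the vector field piecewise smooth: it is globally Lipschitz, C⁰ in
the state with a kink only in the second derivative, so a classical
explicit integrator applies without event handling.  The non-autonomous
sinusoidal term makes the effective phase space three-dimensional, the
minimum for chaos in a continuous flow.

A deliberate convention: `ω` multiplies `π t` inside the sine, so the
forcing period is `T = 2/ω`, not `2π/ω`.  All strobing, renormalization
and period bookkeeping is expressed in units of `T` to keep this
factor-of-π pitfall in one documented place.

Fixed-point analysis of the unforced linearization reports two labels.
The classical dichotomy for this model — saddle iff `ad < bc` — is the
criterion under which sustained dynamics occur (with `b=−2, c=1, d=1`
it reduces to `a < −2`, and the boundary `a = bc/d = −2` is exact in
floating point).  Because `ad > bc` alone does not imply asymptotic
stability (the trace must also be negative), a full spectral label
(stable/unstable node/spiral, center, degenerate, saddle) is computed
from the eigenvalues and reported alongside; neither label replaces the
other.  Relatedly, linear stability of the origin is local only: for
example at `a=−1.5, b=−2, c=1, d=1` the unforced nonlinear system has a
coexisting stable equilibrium near (1.93, 1.80) whose basin contains
(0.1, 0.1) — the tests pin both behaviors.

## Integration

Classical 4th-order Runge–Kutta with a fixed step, default
`dt = 0.001` (2000 steps per forcing period at `ω = 1`).  A fixed step
was chosen over an adaptive solver because it makes the forcing period
an exact integer number of steps — the stroboscopic section is read off
stored samples with no interpolation — and makes every run
bit-reproducible.  `RunSettings` rejects any `dt` that does not divide
the forcing period.  Observed convergence order on a one-period window
is ≥ 3.5 (Richardson step-halving; the kink in the derivative of the
vector field costs nothing observable at these tolerances).

Defaults: 500 transient forcing periods discarded, 200 recorded,
initial state (0.1, 0.1), start time 0.  The long transient is needed
because relaxation onto the attractor slows critically near the
period-doubling points (the measured λ at `a = −3.451`, equal advice,
is only −0.023 per unit time).  Regime labels were checked for
robustness across the initial-condition panel (0.1, 0.1), (1, 0),
(−0.5, 0.5).  A state excursion beyond |R| or |J| > 1e6 aborts with a
divergence error naming the step: the model is bounded in every regime
studied, so overflow always indicates a configuration error.

With `B = 0` the system is equivariant under (R, J, t) → (−R, −J,
t + T/2); RK4 preserves this exactly, and the trajectory tests verify
equivariance to 1e-9 (pure floating-point noise from `sin`).

## Poincaré sections and period detection

Sections are stroboscopic — the state sampled once per forcing period
at a configurable phase — because the system is periodically driven and
a period-n orbit then yields exactly n points.  Period detection
clusters the section with single linkage at radius
`rel_tol × diameter` (default `rel_tol = 1e-3`, diameter floored at
1e-9 for fully collapsed period-1 sections) and accepts n clusters only
if the strobe sequence visits them in a fixed cyclic order; the order
check rejects quasiperiodic loops and random scatter that merely
cluster.  A section with fewer than 4 visits per cluster is reported
aperiodic rather than over-interpreted, and fewer than 32 points is an
error.  The attractor classifier additionally requires the cluster
count to be stable across rel_tol ∈ {5e-4, 1e-3, 5e-3}; sensitivity in
that band yields `unresolved`.

A relative radius was chosen because attractor scale varies across
scenarios; its known limitation is that a *single* cluster whose
diameter is its own noise cannot be resolved — irrelevant for real
sections, where 500 transient periods collapse a period-1 orbit to
machine precision.

## Power spectrum

Mean-removed, Hann-windowed periodogram (`scipy.signal.periodogram`);
peaks are local maxima above 1% of the global maximum, zero frequency
excluded.  The Hann sidelobe level (≈ 0.08%) keeps leakage skirts below
the threshold.  A period-n orbit of the period-T drive carries
subharmonic lines at multiples of 1/(nT); the tests verify ≥ n−1 such
lines for the period-4 orbit.  Line *strengths* are attractor-dependent
— at `a = −3.406` the 1/8 line carries only 0.6% relative power and
falls below the default threshold — which is why the strobe-based
period is treated as authoritative and the spectrum as corroboration.

## Maximal Lyapunov exponent

Benettin's single-exponent method: the base state and one tangent
vector are co-integrated with the same RK4 stepping, the tangent
evolving under the variational equation with Jacobian
`[[a, b(1−2|J|)], [c(1−2|R|), d]]` (the additive forcing has no state
dependence; `d/dx x(1−|x|) = 1−2|x|` is two-sided everywhere, so no
event handling is needed on the axes).  The tangent is renormalized
once per forcing period — stretch factors stay far from floating-point
limits, and the estimate is provably invariant to the renormalization
interval up to rounding (verified: halving the interval moves λ by
< 1e-14).  The exponent is the time average of log stretch factors
after discarding the transient; the per-renormalization running
estimate is kept as a convergence history, and the estimate is declared
settled when its last quartile drifts by < 0.02.

The initial tangent is fixed at (1, 0) for determinism.  On the exactly
linear flow (zero forcing, base pinned at the origin) the estimate
reproduces the closed-form largest eigenvalue real part within 0.01
over 2000 time units, *provided* the tangent has a component along the
dominant eigenvector — an exactly eigen-aligned start (measure zero;
e.g. diagonal matrices) converges to the sub-dominant exponent, which
is inherent to the method and excluded from the property tests by a
genericity condition.

Verdict thresholds: λ > +0.01 per unit time supports chaos, λ < −0.01 a
stable periodic orbit, and the dead zone in between maps to
`unresolved` — near bifurcation points the true exponent passes through
zero and no finite run can resolve its sign honestly.

## Attractor classification and scroll count

`periodic` requires a tolerance-stable strobe period *and* λ < −0.01;
`chaotic` requires a tolerance-stable aperiodic strobe *and* λ > +0.01;
everything else is `unresolved`, never coerced.  For chaotic labels a
descriptive scroll count distinguishes the single-scroll (Rössler-type)
band from the symmetric double scroll: the phase-0 section is compared
with the negated phase-T/2 section (the image of the attractor under
the model's half-period symmetry) by symmetric Hausdorff distance
relative to the section diameter.  A symmetric double-scroll attractor
is invariant under that map (measured mismatch 0.06–0.21); a
symmetry-broken single band maps onto its distant mirror twin
(1.1–2.5).  The threshold 0.5 sits in the order-of-magnitude gap.
Sign-occupancy of R was rejected as a lobe criterion because the drive
swings R across zero on every attractor.  For `B ≠ 0` the symmetry is
only approximate and the count is reported as descriptive metadata
only.

## Bifurcation sweeps

Sweeps ascend a sorted grid of `a` (default: 400 uniform points on
[−6.0, −2.01], inside the saddle region), integrating, strobing,
period-detecting and estimating λ (default 400 periods per grid point)
at each value.  With continuation (default) the final recorded state at
one value seeds the next, following a branch with shorter effective
transients; cold-start and continuation sweeps give identical period
labels at the five reference values (no hysteresis detected there).
Divergent grid points are recorded as missing rather than aborting.
`doubling_points` extracts n → 2n transitions and entries into
aperiodic regimes between consecutive resolved grid values; under equal
advice the 2→4 doubling is bracketed by the tests inside
[−3.46, −3.44], immediately below a = −3.451 — which is why that
configuration strobes to 4 points (two tight pairs, separations 0.14
and 0.35 against a section diameter of ≈ 3) rather than 2, while the
mostly-positive and mostly-negative scenarios show the clean
1 → 2 → 4 sequence across a = −5.41, −3.451, −3.406.  The strobed R
(not J) is the plotted ordinate by default; switchable.

## Synthetic fixtures

`fixtures` generates seeded inputs that exercise the diagnostics
without integrating the model: cyclic cluster sequences (with optional
Gaussian jitter) for period detection, uniform scatter for the
aperiodic path, and closed-form 2×2 eigen-oracles for the Lyapunov
estimator.  They emulate the *geometry* of strobe sections — tight,
well-separated clusters visited in order — but none of the slow
critical relaxation, cluster-scale anisotropy or fractal scatter of
real sections, so passing fixture tests shows the detectors implement
their definitions, not that the thresholds suit every real attractor;
the end-to-end regime tests cover the latter.  All randomness in the
package lives here and is seed-driven; the scientific pipeline has no
randomness at all.

## Problem sizes

Library defaults are 500 + 200 forcing periods per run and 2000 periods
per Lyapunov estimate.  The test suite uses those defaults for the
regime checks and smaller windows (100–400 periods, 6–50-point grids)
for structural checks, sizes at which every regime label is already
stable; the acceptance script uses the full defaults.

## Known limitations

- Period detection presumes the strobe section has converged; arbitrarily
  close to a bifurcation the required transient diverges and the verdict
  degrades (honestly) to `unresolved` or aperiodic.
- The scroll count is meaningful only for the pure-sine (B = 0) symmetry;
  with offsets it is heuristic.
- No correlation dimension, 0–1 test, or full Lyapunov spectrum; the
  maximal exponent plus strobe periodicity carry all verdicts.
- Fixed-step RK4 is not A-stable; pathological parameter sets (far outside
  the studied region) may require a smaller `dt` and will otherwise fail
  loudly via the overflow guard.
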