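# Methods

## Threat process and hit likelihood

The simulated threat advances toward a target interval of half-width `w`
on an integer lateral grid `[-E, E]`: each second the lateral position
takes a uniform step in `{-v, …, +v}` (clamped at the grid edge) and the
forward distance decreases. In CertainTime runs the forward step is
always 1, so a 60-step approach resolves at exactly 60 s; in VariableTime
runs the step is 1 or 2 with fixed probability `p` (default 0.5), which
places the end time in [30, 60] by construction — no conditioning is
required. When the remaining distance reaches zero the run ends: Hit if
the lateral position lies within the target, Miss otherwise.

The exact hit likelihood for any state `(x, d)` is computed by backward
recursion over this process (`L(x, 0) = 1{|x| ≤ w}`; one lateral
averaging plus the forward-step mixture per second), cached as a table
per configuration. By construction `q(t) = L(x_t, d_t)` is the
conditional Hit probability given the current state, so the likelihood
series is a martingale of the outcome — the property the calibration
tests verify by Monte Carlo. Participants only ever see the *truncated*
value: `floor(q·10)/10`, chosen so the display never overstates the
likelihood; exact multiples map to themselves. The truncation convention
is a modelling choice (floored rather than rounded), as is the default
geometry (`v=1`, `w=4`, `E=40`): with these values a trajectory starting
near the target has an initial likelihood near 0.5, initial offsets in
the default pool (0 to ±8) spread initial likelihoods over roughly
0.1–0.6, and roughly a third to a half of runs end in a Hit — a mix of
easy and ambiguous scenarios. Volatility 0 is admitted as a degenerate
deterministic collision for testing.

## Synthetic experiments

A design is a deterministic nested crossing of shelter capacity
{50, 40, 30, 20, 10}, timing regime, loss matrix and network topology,
cycled to the requested number of runs, with trajectories drawn from a
per-regime pool smaller than the run count so that trajectories repeat
under different settings. Loss matrices respect the required orderings
(free AtHome-Miss; InTransit strictly between the extremes in both
columns) at three severity scales (1.0, 0.7, 0.4 of a base matrix with
Miss column (0, 20, 30) and Hit column (100, 60, 30)); the scales keep
every loss within the 100-point stake. Networks are three ring lattices
(neighbor distance 1–3) and five fixed-degree-sequence random graphs
(degree sequence 1×10 … 10×1; 100 edges, mean degree 4), generated with
networkx. Networks are assigned, logged and validated but do not enter
the decision law: the generator mirrors the empirical finding that
essentially all evacuation decisions are driven by the broadcast
information.

Within a run, every at-home agent evacuates each second with probability
`r(q_display[t]; B, T(t))` (independent Bernoulli draws; rates are
per-second probabilities, so no further mapping is needed for rates ≤ 1).
Evacuees claim beds in uniformly random within-second order until the
shelter fills; the remainder finish InTransit. Decisions never depend on
current occupancy — only bed assignment does — which is what makes the
estimation model well-specified on generated data.

## Rate estimation

Exposure counts the evacuation second itself (the at-home indicator is
read at the interval start), and intervals after a run's end contribute
nothing. Aggregation completes the full factor grid (all 11 display
levels crossed with observed capacity/window/participant levels); cells
with zero exposure carry the prior mean 1/2 and SD sqrt(1/12), are
flagged `unobserved`, and are excluded from every fit. The uniform-prior
Beta posterior (add-one smoothing) is used exactly as stated — no
alternative priors.

## Fitting

All fits maximize the Bernoulli-count log-likelihood with rates clamped
to [1e-9, 1 − 1e-9] inside the logarithms. The optimizer is a
deterministic multi-start lattice (27 starts for the three-parameter
model; a comparable lattice augmented with data-driven per-window rate
seeds for the extensions) refined by L-BFGS-B with tolerance 1e-12 on the
objective. The steepness exponent is bounded to [0.5, 40]: with only 11
likelihood levels, steeper curves are observationally equivalent to a
strict threshold and the parameter becomes unidentifiable. The threshold
slope is bounded to ±0.02/bed so θ(B) stays inside (0, 1) over B ∈
[10, 50]. Degenerate inputs (no evacuations anywhere, or a single
capacity level passed to the capacity model) are flagged or redirected
rather than silently fit.

Bootstrap SDs resample whole runs with replacement (preserving the
within-run dependence induced by shared trajectories), re-aggregate and
refit; replicates that fail outright are counted and skipped.
Leave-one-out cross-validation refits on every 46-of-47 subset and
forward-predicts the held-out run, reporting held-out, full-model and
observed curves per second. Per-participant fits use the by-(q,
participant) partition; Pearson correlations between fitted parameters
and cumulative scores are reported with two-sided p-values and no
multiple-testing correction (exploratory usage).

## Prediction and threshold payoff

The forward recursion `H_{t+1} = H_t (1 − r_t)` predicts expected
*decisions*; shelter capacity is deliberately not applied as a truncation
of the predicted counts (it enters only through the rate law's
threshold). The recursion is linear in `H_0`, so population rescaling is
exact. The strict-threshold payoff curve evaluates a solo player who
evacuates at the first second the displayed level strictly exceeds their
threshold, ignoring capacity and competition; because the display is
11-valued the curve is piecewise constant with breakpoints only at the
display levels, and on mixed designs an interior threshold is optimal
(too low buys erroneous evacuations on Misses, too high risks AtHome
Hits).

## Pipeline, seeds and problem sizes

Every random stage derives its generator from a single master seed via
named `SeedSequence` substreams, so run logs, fits, bootstrap replicates
and reports are bit-reproducible from (config, seed). Run logs round-trip
through a versioned tidy-CSV + JSON-manifest format whose reader
re-validates states, the per-second bookkeeping identity, and the
capacity bound.

The recovery study used for validation generates 188 runs × 50 agents per
repetition and averages 20 repetitions — about 560k decision-seconds per
repetition, enough that the count MLE recovers all six generating
parameters to within a few percent while the full study completes in
under a minute. The heavier validation checks (10^4-replicate Monte Carlo
against the forward recursion, exhaustive path enumeration of the threat
process at horizons ≤ 6, grid-search cross-checks of the optimizer) are
sized to run alongside the unit suite in a few minutes.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes:
truncated 11-level likelihood displays, per-second Bernoulli decisions
from the six-parameter law, shelter competition, nested designs.
Real participants additionally learn across runs, react to peers and to
being shut out of full shelters, and show reaction-time and attention
effects that this generator deliberately omits; parameter recovery on
synthetic data therefore validates the estimators and the pipeline, not
the behavioral model's adequacy for any particular human cohort. The
pooled single-Hill fit is a deliberately misspecified summary when
regimes are mixed (its threshold absorbs the spread in per-window maximum
rates), which is why its recovery guarantees are stated only for
single-regime data.

## Known limitations

- The backward-recursion likelihood clamps the lateral walk at the grid
  edge; with the default extent (40) the boundary is effectively never
  reached in 60-step runs.
- The capacity-linear threshold is a local description over B ∈ [10, 50];
  nothing constrains it outside that range.
- Individual fits inherit the sparsity of per-participant data; agents
  who rarely evacuate are flagged degenerate rather than given a
  meaningless point estimate.
- The strict-threshold payoff ignores shelter scarcity and time pressure
  by design; it is a reference curve, not an optimal policy.
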