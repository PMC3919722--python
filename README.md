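# evacdyn

Behavioral decision dynamics in collective evacuation: a tested pipeline
for simulating disaster-evacuation experiments, estimating per-second
evacuation rates, fitting Hill-function decision models, and predicting
collective evacuation curves.

## The problem

In laboratory evacuation experiments, ~50 networked participants each
watch the displayed likelihood `q(t)` that a simulated disaster will
strike their community (shown at 11 levels, 0.0–1.0 in steps of 0.1,
updated every second) and decide if and when to make a binding evacuation
to a shelter with limited capacity `B` (10–50 beds). Runs end in a Hit or
a Miss — at exactly 60 s ("CertainTime") or at an unpredictable moment in
30–60 s ("VariableTime") — and each participant's 100-point stake is
reduced by a loss matrix over (final state × outcome). Because such
experiments produce sparse, irregular panels of decisions, the analysis
centers on a discrete-time hazard-rate model rather than raw evacuation
times.

This package implements that analysis end to end, together with a
synthetic-experiment generator that reproduces the statistical structure
the analysis assumes, so every estimator can be validated by parameter
recovery.

## The model

For each one-second interval, indicator `H` marks a participant AtHome at
the interval start and `E` an evacuation during it (`H` drops by exactly
`E` each second). Pooling intervals within a partition cell `k` (by
likelihood level `q`, optionally capacity `B`, time window `T`, or
participant) gives exposure `n_k` and events `m_k`, and the per-second
rate is measured as the Beta-posterior mean with its SD:

    R_k = (m_k + 1) / (n_k + 2),
    sd_k = sqrt((m_k+1)(n_k−m_k+1) / ((n_k+2)^2 (n_k+3)))

Rates rise with `q` like a Hill function, and the full population model is

    r(q; B, T) = r_T · q^h / (q^h + θ(B)^h),   θ(B) = θ0 + c·B

with a shared steepness `h`, a capacity-linear threshold, and separate
maximum rates for the three time-urgency windows (T1: VariableTime before
30 s, T2: VariableTime at/after 30 s, T3: CertainTime). Fitting maximizes
the count-level log-likelihood

    ℓ = Σ_k [ m_k ln r_k + (n_k − m_k) ln(1 − r_k) ]

— a fit directly to the counts, not the measured rates. Expected
collective behavior follows the forward recursion `H_{t+1} = H_t (1 −
r(q_t; B, T(t)))` from `H_0 = 50`. Bootstrap (resampling whole runs) and
leave-one-out cross-validation quantify uncertainty and overfitting, and
per-participant Hill fits capture individual variation.

## Worked example

```python
import evacdyn as e

pool = e.default_trajectory_pool(seed=7)
design = e.make_design(n_runs=47, trajectory_pool=pool, seed=7)
logs, _ = e.generate_experiment(design, e.DEFAULT_POPULATION_MODEL, rng_seed=7)

cells = e.aggregate_counts(e.build_indicators(logs), "by_q_B_T")
fit = e.fit_six_param(cells)
print(fit.params.as_dict())
```

prints (47 runs of 50 agents generated at the default model
`h=9.3, r_T1=0.07, r_T2=0.37, r_T3=0.13, θ0=0.60, c=0.002`):

```
{'h': 9.3307, 'r_t1': 0.0702, 'r_t2': 0.4095, 'r_t3': 0.1311,
 'theta0': 0.5989, 'c': 0.0023}
```

i.e. a single experiment's worth of data already recovers the generating
decision law well; bootstrap SDs from `e.bootstrap_params(logs)` for this
dataset are `h: 0.51, r_t1: 0.006, r_t2: 0.019, r_t3: 0.010,
theta0: 0.014, c: 0.0002`. One aggregated cell, e.g. `q=0.7, B=50, T=3`,
holds `n=552` at-home seconds with `m=29` evacuations, a measured rate
`R=0.054 ± 0.010`/s. Forward prediction for the first run (a CertainTime
Hit) tracks the realized at-home counts:

```
t               0     15    30    45    60
expected H_t    50.0  48.3  46.1  26.5  4.6
observed        50    48    48    29    6
```

The same steps are scriptable from the shell:

```
evacdyn generate --runs 47 --seed 7 --out logs/
evacdyn estimate --logs logs/ --scheme by_q_B_T --out rates.csv
evacdyn fit --rates rates.csv --model six --logs logs/ --boot 200
evacdyn pipeline --seed 7 --out report/
```

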