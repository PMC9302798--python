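# Methods

## Model

`liferisk` works on a discrete-time four-state illness–death chain with a
one-year cycle and age as the clock: normoglycemia (N), prediabetes (P),
diabetes (D), death. Allowed one-year moves are N→{N,P,D,death},
P→{P,D,death}, D→{D,death}; severity never decreases and death is absorbing.
The no-reversion convention mirrors how interval-censored registry data are
usually read: an apparent P→N reversal cannot be distinguished from a
measurement taken on the way back up, so the first qualifying measurement
fixes the state permanently. Transition probabilities are indexed by integer
age 0–110 and sex; above 110 survivorship is negligible and trajectories are
truncated.

## Classification

Measurements classify by the ADA bands (FPG ≥ 5.6 / ≥ 7.0 mmol/L; HbA1c
≥ 39 / ≥ 48 mmol/mol; 2-h OGTT ≥ 7.8 / ≥ 11.1 mmol/L). Diabetes is also
established by a clinician diagnosis code, a non-insulin glucose-lowering
prescription, or one insulin episode of ≥ 28 continuous days (episode
consolidation is the data producer's job; no gap-joining rule is applied).
Random plasma glucose is ingested for entry/censoring purposes but never
classifies on its own. Inpatient FPG and any glycemic measurement in
gestational weeks 24–40 are excluded before resolution (stress and
gestational hyperglycemia). Onsets carry the right-endpoint convention —
dated at the first qualifying record — and are binned to the integer age
containing them, matching the annual cycle. Severity ties at one age resolve
to the more severe state. The prediabetes definition can be restricted to
FPG-only or HbA1c-only (sensitivity analyses); this never moves the diabetes
onset.

## Transition estimation

For each age *a*, origin *s*, and destination *s′*, the estimator is
occurrence/exposure on annual cycles, in two parts:

- **Death.** q(a,s) = deaths in (a, a+1] among persons known to be in *s* at
  *a* whose vital-status linkage covers a+1. Linkage is derived from the
  registry closing year (`linkage_end_age = closing_year − birth_year`, a
  conservative whole-years bound) and is independent of how often a person
  was tested.
- **Living split.** Destination shares among survivors are estimated on the
  person-years whose glycemic state at a+1 is known — within measurement
  coverage, or deduced (diabetes is absorbing among the living) — and scaled
  by 1 − q.

A single exposure set for both parts would include a dying person's final
year while excluding the matching survivor time after the last encounter,
inflating mortality; the two-part split removes that asymmetry. Between the
first and last encounter the no-reversion convention makes every interior
year deducible from the surrounding measurements. Ages with no exposure for
an origin borrow the nearest populated age's finished row. Pooled tables are
exact count recombinations of the sex-specific tables. The estimator assumes
complete death linkage within the registry window; the generator's
loss-to-follow-up rate therefore defaults to zero (net migration in the
emulated setting is negligible), and a positive rate is a sensitivity knob
that deliberately violates the assumption.

Calendar-period splits attribute the person-year at age *a* to the year
`birth_year + a` and keep only years inside the window.

Known behaviour under the default *opportunistic* observation process:
onsets are detected late (first test after the latent onset), so estimated
progression hazards at a given age mix person-time of earlier latent onset.
The observed-versus-predicted validation stage surfaces exactly this
(discrepancies of 0.03–0.09 under sparse testing, ≤ 0.02 under dense
testing); that is its diagnostic purpose, and it reproduces the usual
finding that such models fit worst where testing is sparsest (youth).

## Simulation and oracles

Cohorts are propagated by annual multinomial draws; trajectories are stored
as onset ages. Every reported quantity has an exact counterpart from
iterating the distribution vector on a five-state expansion that splits
death by whether diabetes came first: lifetime risk is the terminal mass in
{D, death-after-D}; years without (with) diabetes are the sums of N+P (D)
occupancies from the index age to 109 — an exact identity with the
simulation's whole-year accounting, used throughout the tests. The
proportion of remaining life with diabetes is the mean of per-individual
fractions with zeros included; it is *not* the ratio of mean durations (the
two differ whenever onset timing and longevity covary), and only the
per-individual convention keeps the reported proportion below the
duration-ratio when long survivors dominate the diabetic years.

Confidence intervals propagate estimation uncertainty by a parametric
bootstrap: each replicate redraws every estimated row's transition counts
from a multinomial at the observed at-risk size, rebuilds the table, and
recomputes the quantities (reduced simulation or exact propagation). The
default is 200 replicates; tests use fewer.

## Competing-risk survival

Short-term progression is summarized by the Aalen–Johansen cumulative
incidence function, CIF(t) = Σ_{u≤t} S(u−) d_event(u)/n(u), with all-cause
event-free survival S, delayed entry supported, ties processed events before
deaths before censorings, and pointwise intervals from the
Marubini–Valsecchi variance on the log(−log) scale (stable near 0 and 1).

The modified Kaplan–Meier lifetime risk uses age as the timescale: persons
enter the risk set at the later of the index age and their entry into the
origin state, and the diabetes hazard is accumulated against the probability
of remaining alive and diabetes-free to 110, with the same dual exposure
sets as the transition estimator. Fed complete discrete trajectories it
equals the chain's absorption probability exactly for the prediabetes origin
(prediabetes can only be left for diabetes or death, so the risk-set hazard
is the state's own hazard). For the normoglycemia origin the two methods
genuinely diverge: late entrants keep refreshing the risk set with
still-normoglycemic people, so the at-risk normo/pre mixture is "younger in
state" than a cohort conditioned at the index age, and the modified KM sits
several points lower. This mirrors the behaviour of the method in the
literature that introduced it and is reported as a property, not hidden:
cross-method agreement is asserted for the prediabetes origin (within 0.03
here).

## Sullivan life table

The Sullivan partition uses l(x+1) = l(x)(1 − q(x)), person-years
L(x) = l(x+1) + a(x)·d(x) with a(x) = 0.5 at all ages (adult-disease
application; the closing interval uses L = 0.5·l), and
e_with(x) = Σ_{y≥x} prevalence(y)·L(y)/l(x). Missing prevalence at sparse
old ages is forward-filled. The identity e_with + e_without = e holds to
machine precision by construction. When Sullivan inputs are read off the
same simulated trajectories (`sullivan_from_cohort`), the difference from
the simulation's whole-year accounting is exactly the half-year convention,
−0.5 × P(die while diabetic) plus a negligible closure term — bounded below
0.5 years in magnitude, which is the cross-method tolerance used.

## Age–period–cohort extrapolation

Rates observed on a bounded calendar window are modelled as log-linear in
natural cubic spline effects of age, period, and cohort (Poisson likelihood,
person-years exposure; dimensions affinely rescaled to [0,1] for
conditioning). The exact collinearity cohort = period − age is resolved by
residualizing the period basis against an intercept and linear trend, so all
drift is carried by age and cohort — the natural allocation when the target
is cohort-indexed lifetime risk; users wanting a different allocation can
refit with their own bases. Natural splines are linear beyond their boundary
knots, so age and cohort effects extrapolate their boundary trends; the
drift-free period effect is held at its boundary value outside the observed
window (extrapolating curvature-only effects over decades would reintroduce
arbitrary drift). Knots default to the data extremes plus three evenly
spaced interior knots per dimension; a manually chosen placement can be
supplied. Extrapolated rates convert to annual probabilities by
p = 1 − exp(−rate) and accumulate through the modified KM sum with death
competing. On registries with thin young-age exposure from prediabetes the
extrapolation is weak at those ages; the pipeline stage is off by default
and intended for dense cell tables.

## Synthetic registry: what it emulates and what it does not

The generator separates a latent process (exact simulation from the truth
tables) from an observation process. Defaults are the study conditions:
54.2% women; entry ages uniform on [0, 90], drawn independently of the
latent trajectory (persons dying before their would-be entry never appear —
entry must not be informative about survival); calendar window 2001–2019
with administrative censoring; 21.2% of persons with exactly one glycemic
measurement and otherwise about 0.9 tests/year; measurement mix with 1.4%
OGTT; 3% inpatient FPG and 2% gestational contamination; diagnosis-code,
drug, and insulin-episode flags for a fraction of diabetic person-time, plus
sub-threshold insulin episodes as noise. Measurement values are drawn
uniformly inside the ADA band of the latent state, so classification
recovers the latent state without misclassification — estimator tests are
thereby isolated from measurement error (a config hook exists but defaults
off). A `dense_testing` mode places one measurement at every integer age
under observation, removing detection delay; parameter-recovery checks use
it, everything else uses the opportunistic default.

The default truth schedule (`default_truth_table`) is a plausible urban
East-Asian profile chosen once: Gompertz–Makeham mortality
(q = 3×10⁻⁴ + 2×10⁻⁵·e^{0.09·age}, ×0.78 women / ×1.22 men, ×1.1 from
prediabetes, ×1.8 from diabetes; period life expectancy ≈ 83 years),
progression N→P rising from ~0.005/yr at 20 to ~0.03/yr at 80, N→D
0.002–0.006/yr, P→D ~0.02/yr at 20 rising to ~0.045/yr at 80. It implies
lifetime risks from prediabetes at 20 of ≈ 0.85 and from normoglycemia
≈ 0.56, declining with index age, higher in women. Passing tests demonstrate
correctness of the estimators under these conditions, not the absolute risks
of any real population; real data add state-dependent testing intensity
(knob provided, no default claimed), measurement error, reversion, and
secular trends the generator does not produce by default.

## Numerical conventions

Onsets bin to floor(age); death enters the state path at ceil(death age);
a person's annual state sequence runs from floor(entry) to the last
determinable age. Zero-exposure rows borrow the nearest populated age.
Rows are validated to sum to 1 within 1e-6 and structural zeros are exact.
Simulation, generation, and bootstrap all run off seeded numpy Generators;
identical configuration and seed give byte-identical CSV outputs.

## Problem sizes

Default problem sizes — 50,000–100,000 synthetic persons, 200,000 simulated
trajectories, 200 bootstrap replicates — were chosen so that Monte Carlo
error is comfortably below every tolerance asserted in the test suite
(binomial/3-SE bounds, the 0.03 cross-method band, the 0.5-year Sullivan
band); larger runs only tighten them. The cohort size used in large
published analyses of this kind (millions of trajectories) is supported and
configurable (`simulation_n`, `liferisk simulate --n`).
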