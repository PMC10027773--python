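# Methods

`singlecase` is a Monte Carlo laboratory for one question from single-case
(n-of-1) methodology: does waiting for a stable baseline before starting
treatment change the error rates of the analyses applied afterwards?  This
note records the generating model, the decision rules, the design choices
made where conventions were genuinely open, and what the simulations do and
do not show about real data.

## Generating model

Each latent series has exactly 30 observations,

```
y_t = x_t + 10,        x_t = a · x_{t-1} + ε_t,        x_0 = 0,
```

with lag-1 autocorrelation `a ∈ {0, 0.4}` (0.4 is a typical mean estimate
for single-case graphs) and innovations `ε_t`:

* **trend experiment** — standard normal, so the innovation SD is 1 and raw
  units are directly comparable to session counts;
* **variability experiment** — Uniform(−3, 3), SD √3 ≈ 1.73, producing
  visibly noisier series.

The recursion starts from `x_0 = 0` with no burn-in, so the first point is
`ε_1 + 10` and the process variance grows toward its stationary value over
the first few sessions when `a = 0.4`.  A stationary initialisation would
be equally defensible; the literal recursion was chosen because it is the
plainest reading of the generating formula, and the reproduced error rates
support it.

### Instability screening

The study needs *initially unstable* baselines, produced by rejection
sampling.  A candidate series is kept only if, at exactly the minimum
phase-A length `min_a ∈ {3, 5}`:

* trend experiment — the angle of the OLS trend over the first `min_a`
  points, `arctan(slope)·180/π` with unit session spacing, exceeds the
  maximum allowable trend (15° or 30°) in absolute value;
* variability experiment — the sample SD (n−1 denominator) of the last
  three of those points exceeds the maximum allowable SD (1.0 or 1.5).

The angle convention is meaningful because the innovation SD is 1, making
the two axes commensurate.  Screening is evaluated only at `min_a`, not at
every earlier point.  A safety cap of 10⁶ attempts per series turns an
impossible screening request into an error rather than an infinite loop.

## Three matched baselines per series

Every screened series yields three AB graphs sharing the same latent data,
so any difference in error rates is attributable to the baseline-length
rule alone:

* **fixed** — phase A is exactly `min_a` points;
* **response-guided** — phase A extends to the first `t > min_a` at which
  the stability statistic (trend angle over all `t` points, or SD of the
  last three) is at or below the threshold.  If stability never arrives
  before phase B must start, the length is capped at `30 − n_b` and the
  series is flagged `rg_capped` but retained — discarding it would break
  the matched-triplet design;
* **random** — phase-A lengths drawn without replacement (a permutation)
  from the response-guided lengths *within the same factorial cell*, so
  both schemes have identical length distributions while the factorial
  factors stay balanced.  The stratum of the permutation is a design
  choice; within-cell permutation is the narrowest stratum that preserves
  counterbalancing.

Phase B always has `n_b ∈ {5, 10}` points.  An effect is injected by adding
the standardized mean difference (SMD, integers 0–5) to every phase-B
point — multiplied by 1.73 in the variability experiment so effects are
expressed in innovation-SD units in both experiments.  Effects are always
increases, and both analyzers test for an increase.  Phase A is never
altered.

The full factorial design crosses `min_a × n_b × a × threshold` (16 cells).
At full design scale each cell holds 5,000 null series and 1,000 per SMD value
1–5: 160,000 series and 480,000 graphs per experiment.  A `scale` knob
shrinks every cell proportionally, preserving the 50/50 null/effect split
and the uniform SMD allocation.

## Conservative dual-criteria (CDC) rule

For a graph with baseline of length `L`:

1. fit the OLS trend line to phase A on sessions `0..L−1` and extrapolate
   it over sessions `L..L+n_b−1` (a continuous session axis — the
   alternative of restarting the axis would drop the line back to baseline
   level and is not a "continuation");
2. draw the flat line at the phase-A mean;
3. raise both lines by `0.25 · SD(phase A)` (sample SD, n−1; a zero-SD
   baseline gives a zero shift, a valid degenerate case);
4. count phase-B points strictly above *both* lines (points exactly on a
   line do not count — the conservative reading, immaterial for continuous
   data);
5. declare an effect when the count reaches the binomial criterion.

Two criterion variants are implemented.  The default, `"published"`, is
the field's criterion table, generated by the one-sided normal
approximation to the Binomial(n_b, ½) test, `ceil(n/2 + z₀.₉₅·√n/2)`:
5 of 5 and 8 of 10 points for the phase-B lengths used here.  The
`"exact"` variant takes the smallest count whose exact binomial tail is
below α and is stricter at 10 points (9 of 10).  The published table is
the default because the reproduced type I error rates for 10-point
treatment phases are consistent with 8 and clearly inconsistent with 9;
both variants are exposed and tested.  With fewer than five treatment
points no count is significant and the rule raises an explicit error.

## Support-vector classifier

The classifier judges a graph from eight features computed after the whole
graph (both phases pooled) is transformed to z scores: per-phase mean,
sample SD, and OLS intercept and slope.  Feature extraction is therefore
exactly invariant to affine transforms of the raw values.  Two conventions
were open and are exposed as flags: z-scoring pools the phases (default)
or standardises each phase separately, and the phase-B regression restarts
its session index at 0 (default) or continues the global index.

The published model this method descends from is an external artifact, so
the package trains a **surrogate**: an RBF-kernel SVC fit on a corpus from
the package's own simulator (protocol size 40,000 graphs, balanced null
vs. effect, all cells and all three schemes represented), on a random
substream independent of any evaluation data.  Hyperparameters (C and a
class weight on the no-effect class) are chosen on a 25% held-out split by
maximising detection rate subject to a held-out false-positive rate of at
most 0.05 — mirroring how such classifiers are tuned for this field, where
type I control is the binding constraint.  Training is deterministic given
corpus and seed.  The surrogate reproduces the *qualitative* published
behaviour (conservative type I, higher power than the CDC for SMD ≥ 3,
near-identical rates across the three baseline schemes); its table cells
are not expected to match the original model's numerically.

## Rate estimation

Type I error is the exact proportion of SMD = 0 graphs flagged; power is
the exact proportion of SMD ≥ 1 graphs flagged — no smoothing, denominators
carried with every rate.  Reports stratify by each design factor, by SMD
value 1–5 (power only), and — in the trend experiment — by the sign of the
initial baseline trend over the first `min_a` points.  Written tables round
to three decimals; in-memory values are exact.  Wilson intervals are
available as a diagnostic but not part of the core tables.

## Reproducibility and problem sizes

A master seed spawns named substreams: one generation stream and one
permutation stream per factorial cell, plus one for surrogate training, so
components are independently reproducible and rescaling one cell does not
perturb another.  Everything downstream is a pure function of
(config, seed); rerunning a config yields byte-identical tables.

Problem sizes used by the shipped checks are the package's own choices:
the test suite replicates both experiments at scale 0.1 (16,000 series
each, ≥ 4,000 graphs per single-factor stratum), judging reproduced CDC
cells within three Monte Carlo standard errors floored at ±0.02;
`scripts/acceptance.py` runs both experiments at full scale (160,000
series, a few seconds each).  The surrogate used in tests trains on a
4,000-graph corpus for speed; the full 40,000-graph protocol is the
documented default of `train_default_surrogate`.

## Limitations

The generator emulates the study's stylised world, not real clinical data:
parameters are constant within a series (no drifting trend, variance, or
autocorrelation), innovations are homoscedastic, effects are abrupt level
shifts only, and series are exactly 30 points.  Passing tests demonstrate
fidelity to that model — not that either analyzer performs equally well on
graphs whose parameters change over time, on bounded count outcomes, or on
designs beyond the AB unit (reversal, multiple-baseline,
changing-criterion).  Visual inspection, randomization tests and masked
visual analysis are outside the package's scope.
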