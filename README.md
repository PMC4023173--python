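# splitmeta

Do split-mouth trials and parallel-arm trials give the same answer?

In dentistry, a *split-mouth* randomized trial assigns the experimental
and control interventions to different sites in the same mouth, so each
patient acts as their own control. The design buys precision, but sites
in one mouth are not independent: interventions can "carry across", and
the paired structure changes every variance formula. `splitmeta` is a
meta-epidemiological toolkit for quantifying, across many meta-analyses
that contain both designs, whether split-mouth trials systematically
yield larger or smaller intervention effect estimates than parallel-arm
trials.

## The method

The analysis is a two-step contrast on trial-level summary data.

**Per-trial effects.** Binary outcomes are summarized as log odds
ratios: the ordinary 2×2 log OR for parallel trials (0.5 continuity
correction when any cell is zero; trials with no events in either arm
excluded), and for split-mouth trials the *marginal* log OR of the
paired 2×2 table with the Becker–Balagtas delta-method variance

&nbsp;&nbsp;Var(log OR) = (1/n) [ 1/(p₁q₁) + 1/(p₂q₂) − 2(π₁₁π₀₀ − π₁₀π₀₁)/(p₁q₁p₂q₂) ],

which subtracts the within-patient covariance of the two site margins.
When only marginal counts are reported, the joint cells are
reconstructed from an assumed within-patient correlation ρ (default
0.5, sensitivity 0 and 0.25), clamped to the Fréchet bounds. Continuous
outcomes are Cohen's d: the usual independent-groups form for parallel
trials, and for split-mouth trials the matched-groups form standardized
by the single-site SD, with variance [1/n + d²/(2n)]·2(1−ρ); the
Follmann imputation √(s₁² + s₂² − 2ρs₁s₂) recovers the SD of
within-patient differences when it is not reported. Effects are coded
so OR < 1 / SMD < 0 means benefit.

**Step one.** Within each meta-analysis, the split-mouth and
parallel-arm subgroups are pooled separately (fixed-effect by default,
REML random-effects as sensitivity) and contrasted:

&nbsp;&nbsp;log ROR = log OR(split) − log OR(parallel),&nbsp;&nbsp;ΔSMD = SMD(split) − SMD(parallel),

with variance the sum of the subgroup variances. Meta-analyses sharing
trials are de-overlapped by keeping the one with more trials.

**Step two.** Contrasts are pooled across meta-analyses with a REML
random-effects model, giving a combined ROR or ΔSMD with a normal 95%
CI, a two-tailed z test, between-meta-analysis τ² and I², and a
z-method 95% prediction interval ±1.96·√(τ² + Var) for the contrast in
a new meta-analysis.

Because no public trial-level dataset accompanies this literature, the
package includes a synthetic-data generator with the matching
hierarchical structure (per-meta-analysis true effects, an additive
design effect with its own heterogeneity, multinomial paired tables,
bivariate-normal paired outcomes), so calibration and consistency are
testable end to end.

## Worked example

Simulate 15 meta-analyses with binary outcomes and a true design effect
of log ROR = −0.2 (split-mouth trials exaggerate benefit by ~18%), then
run the two-step analysis:

```bash
splitmeta simulate --out trials.csv --outcome-type binary \
    --delta -0.2 --tau2-delta 0.05 --seed 7
splitmeta metaepi --input trials.csv --outdir results
```

which prints

```
wrote 88 trials (15 meta-analyses) to trials.csv
binary: combined ROR = 0.886 (95% CI 0.681 to 1.153, p = 0.369, tau2 = 0.000,
I2 = 0.0%, 95% PI 0.681 to 1.153) over 15 meta-analyses
```

The combined ROR of 0.886 estimates the true exp(−0.2) ≈ 0.82:
split-mouth trials in this simulated collection yield ~11% larger
effect estimates, but with 15 meta-analyses of 2–4 small trials per
design the CI spans 1, so a collection of this size cannot distinguish
the design effect from noise — the central empirical point of this kind
of analysis. `results/` contains `summary.json` (log- and ratio-scale
results), `contrasts.csv` (one row per meta-analysis), forest-plot
tables with inverse-variance weights, and an exclusion log with reason
codes. `splitmeta sensitivity` re-runs the grid over ρ ∈ {0, 0.25, 0.5}
and both within-pooling methods; `splitmeta effects` exports per-trial
estimates. Everything is also available as a library
(`import splitmeta`).

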