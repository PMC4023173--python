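# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices a maintainer would
want to know about.

## Effect measures and the paired structure

All effects live on an additive scale — log odds ratio for binary
outcomes, standardized mean difference (Cohen's d) for continuous ones
— and are oriented so that negative values indicate benefit of the
experimental intervention.

**Parallel binary.** log OR = log(ad/bc) with variance
1/a + 1/b + 1/c + 1/d. When any cell is zero, 0.5 is added to all four
cells. A trial with no events in either arm carries no information
about the OR and is flagged excluded rather than corrected; a table in
which every patient in both arms had the event is rejected as invalid
input.

**Split-mouth binary.** The estimand is the *marginal*
(population-averaged) odds ratio of the two site margins p₁, p₂ — not
the conditional (subject-specific) OR of the discordant pairs, which
answers a different question and is out of scope. The point estimate is
logit(p̂₁) − logit(p̂₂); its delta-method variance (Becker–Balagtas)
subtracts twice the within-patient covariance term
(π₁₁π₀₀ − π₁₀π₀₁)/n = Cov(p̂₁, p̂₂), so positively dependent sites give
smaller variances than two independent binomials. The identity
π₁₁π₀₀ − π₁₀π₀₁ = π₁₁ − p₁p₂ makes this exactly the bivariate delta
method; it is nevertheless validated against a brute-force multinomial
resampling oracle in the acceptance suite (worst observed relative
error ~2% at n ≥ 200 over randomized non-degenerate tables, against a
5% tolerance).

Degenerate paired tables get the same 0.5-per-joint-cell continuity
correction in two situations: a zero *marginal* cell (infinite log
odds), and zero *discordant* cells n₁₀ = n₀₁ = 0, where the
delta-method variance is exactly zero and would otherwise produce an
infinite pooling weight. Tables with events at neither site, or at both
sites of every patient, are excluded, extending the double-zero rule to
the paired design.

**Reconstructing joint cells.** Reports often give only per-site event
counts. With an assumed within-patient correlation ρ the concordant
cell is π₁₁ = p₁p₂ + ρ√(p₁q₁p₂q₂), clamped to the Fréchet bounds
[max(0, p₁+p₂−1), min(p₁, p₂)] with a `FeasibilityWarning` when ρ is
infeasible for the margins (clamping rather than erroring keeps
sensitivity grids total). Reconstructed cells stay fractional: they
only feed proportion-based formulas, and rounding would add error for
nothing. The default ρ = 0.5 with sensitivity values {0, 0.25} follows
standard practice in this literature; a per-trial `rho` column
overrides the global default, since individual reviews have assumed
anything from 0 to 0.75.

**Continuous outcomes.** Parallel trials use Cohen's d with the
df-weighted pooled SD and variance (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)).
No Hedges small-sample correction is applied — the estimand is d, and
the consistency analysis (below) accounts for the resulting O(1/n)
bias. Split-mouth trials standardize the mean within-patient difference
by the *single-site* SD so the SMD is comparable across designs; when
only the SD of differences is available it is converted via
s_within = s_diff/√(2(1−ρ)), and the variance [1/n + d²/(2n)]·2(1−ρ)
is the independent-groups form shrunk by the pairing factor, strictly
decreasing in ρ. When a record carries both ρ and s_diff, s_diff drives
the variance and ρ only performs the conversion (a warning is logged).
The Follmann imputation √(s₁² + s₂² − 2ρs₁s₂) fills in s_diff from
per-site SDs.

## Pooling

Within-meta-analysis pooling is inverse-variance. The primary analysis
uses the fixed-effect model within meta-analyses, with REML
random-effects as a sensitivity setting — within one meta-analysis the
trials address one clinical question, and the design contrast should
not be diluted by within-design heterogeneity by default. A single
trial is its own summary.

Across meta-analyses the contrasts (log ROR or ΔSMD, variance = sum of
the two subgroup variances) are always pooled by REML random-effects:
collections of meta-analyses spanning different interventions cannot
plausibly share one true design effect. τ² solves the restricted-
likelihood score equation by the standard fixed-point iteration

&nbsp;&nbsp;τ² ← Σwᵢ²[(yᵢ−μ̂)² − vᵢ]/Σwᵢ² + 1/Σwᵢ,&nbsp;&nbsp;wᵢ = 1/(vᵢ+τ²),

started at the DerSimonian–Laird moment estimate, floored at 0, and
declared converged when successive iterates differ by < 1e-8 (failure
after 100 iterations raises an error carrying the last iterate; not
observed in ~2000 fits across the test and acceptance runs). The
implementation reproduces metafor's REML fits to ~8 decimals on frozen
reference datasets. A coarse grid search over the restricted likelihood
serves as the independent test-time oracle. DerSimonian–Laird τ² is
reported only as a diagnostic.

Confidence intervals are normal-approximation (no Knapp–Hartung), the
test of the combined contrast is a two-tailed z test, I² =
max(0, (Q−(k−1))/Q)·100 with fixed-effect weights, and the 95%
prediction interval defaults to the z form value ± 1.96·√(τ² + Var).
The z form is the one that reproduces published interval arithmetic in
this literature; a t_{k−2} variant is available and requires k ≥ 3. No
confidence interval for I² is computed — the methods behind published
I² intervals vary and none is implemented here.

Overlapping meta-analyses (sharing any trial) are resolved iteratively
by dropping the member with fewer trials until all surviving trial-id
sets are pairwise disjoint. Ties keep the earlier-listed meta-analysis
— an arbitrary but deterministic rule, logged in the exclusion file.

## The synthetic-data generator

`SimulationConfig` encodes the hierarchical structure the two-step
analysis assumes: per-meta-analysis true effect θₘ ~ N(μ, τ²_effect), an
additive design offset δₘ ~ N(δ, τ²_δ) applied to split-mouth trials
only, binary trials drawn binomially (parallel) or multinomially over
joint cells (split-mouth) around a control risk, and continuous trials
drawn as unit-SD normals, bivariate with correlation ρ for split-mouth.
The additive-offset model is the minimal structure under which the
ROR/ΔSMD estimator is consistent for δ, which is what makes parameter
recovery a meaningful test.

Defaults mirror the descriptive scale of published dental
meta-analysis collections: 15 meta-analyses, 2–4 trials per design,
~20 patients per split-mouth trial, ~40 (total, two arms) per
parallel-arm trial, ρ = 0.5, control risk 0.3, a modest beneficial mean
effect μ = −0.3, τ²_effect = 0.1, and a null design effect
(δ = 0, τ²_δ = 0). At this scale the per-proportion sample sizes of the
two designs coincide (≈20), so the O(1/n) logit biases cancel between
designs under the null — the coverage experiment is calibrated by
design, not by luck.

**What the generator does not emulate:** carry-across contamination
between sites (no accepted statistical model exists for it), period
effects, selective reporting, risk-of-bias gradients, correlation
between trial size and effect, or non-normal outcome distributions.
Passing calibration and recovery tests therefore show the *estimator
chain* is correct under the assumed model, not that real split-mouth
literatures are free of such biases.

## Monte-Carlo experiments and problem sizes

Two canned experiments in `splitmeta.experiments` back the package's
empirical claims; both derive per-replicate seeds from one master seed.

*Null calibration* runs 500 collections per outcome type at the
descriptive scale above and asks how often the combined contrast's 95%
CI covers zero (observed ≈95–97% for both outcome types across seeds;
the z-based REML interval is known to drift slightly conservative or
anticonservative at k = 15).

*Design-effect recovery* runs 200 collections of 200 meta-analyses with
δ = log 0.7 (binary) or δ = 0.2 (continuous) and compares the mean
combined estimate to δ against Monte-Carlo noise. Recovery is a
*consistency* check, so it runs in a regime where first-order
asymptotics hold: split-mouth n ≈ 400, parallel ≈ 800, control risk
0.4, μ = 0, τ²_δ = 0.1. At the small descriptive trial sizes the known
O(1/n) small-sample bias of log-odds estimators (~0.03 at n ≈ 20) is an
order of magnitude larger than the Monte-Carlo resolution of a 200-
replicate mean and would be mistaken for inconsistency; the bias was
verified to shrink as 1/n (halving from split n 100→200→400), which is
the signature of the estimator's asymptotics rather than an
implementation defect. Typical recovered values: ROR ≈ 0.699–0.702
against a true 0.7; ΔSMD ≈ 0.198–0.199 against a true 0.2.

## Known limitations

* The marginal-OR variance is a delta-method approximation; below
  n ≈ 50, or with margins near 0/1, it can deviate noticeably from the
  true sampling variance (the oracle tolerance is specified for
  n ≥ 200).
* Continuity-corrected log ORs from very small trials are biased;
  within-meta-analysis fixed-effect pooling inherits that bias. The
  package reproduces standard practice rather than correcting it.
* The two-step procedure treats subgroup summaries as independent
  normal — exact for the simulated generator, approximate for small
  real trials.
* Reconstructed joint cells assume exchangeable within-patient
  correlation across trials unless a per-trial ρ is supplied.
* The CSV reader accepts one flat schema (version "1") and deliberately
  rejects unknown columns rather than guessing at dialects.
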