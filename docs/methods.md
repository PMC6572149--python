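# Methods

## Scope and data flow

`minerisk` quantifies the gas-explosion risk contributed by coded unsafe
behaviors of four key underground working types (ventilation; gas
prevention and fire extinguishing; blasting; electrician). The pipeline
is: coded accident table → per-cell occurrence probability P′ →
condition-corrected probability P = P′·F → hazard index I per cell →
Monte Carlo risk R = P·I → per-type totals → contribution-to-variance
sensitivity. Two further working types (mining, transport) are part of
the vocabulary but carry no behavior data in the reference study;
operations on them return zeros rather than errors.

The packaged reference study (`minerisk/data/study.yaml`) encodes a
200-accident sample (2001–2015) in which each accident is coded to
exactly one key working type and one of the 13 standard behavior classes;
the record model nevertheless supports multi-citation accidents, whose
counts aggregate citation multiplicity.

## Correction model

F(x) = intercept − slope·[(0.2a+0.6b+0.2c) + (d+e+f)/3 + (g+h)/2], with
defaults slope = 0.0167, intercept = 1.5. The bracket groups the three
factor families (organizational a–c with weights 0.2/0.6/0.2,
human-machine d–f and personal g–h as unweighted means); this grouping is
the only parse of the source model that reproduces the published factors
(1.376, 1.391, 1.376) exactly, and it is adopted throughout. The
coefficients are taken from prior human-factors work and are not
re-derived here.

Factors are dimensionless scores on [0, 10], elicited as ranges from the
bands [0, 1], [1, 3], [3, 10] and treated as triangular random variables.
The triangular mode is not specified by the elicitation; the default is
the midpoint (symmetric triangular), which makes each factor's mean equal
its midpoint and, because F is linear, makes E[F] equal F at the
midpoints. The mode is configurable per factor (`[lower, mode, upper]`).

Two published values are treated as typographical errors, on the evidence
of the publication's own downstream numbers:

- the blasting correction factor prints as 1.78, but the blasting revised
  probabilities require ≈ 1.378, which is what the formula gives;
- the electrician total risk SD prints as 5.74 × 10⁻¹, tenfold the sum of
  its component SDs; the engine reports ≈ 5.7 × 10⁻².

A third ambiguity — the corrupted hazard SD entry "0.2 ± 0.0.135" for
gas-prevention UUD — is resolved to sd = 0.0135, the only encoding
consistent with that cell's published risk SD (1.62 × 10⁻³); the
alternative 0.135 remains expressible in configuration.

Revised probabilities are carried unrounded internally; 2-d.p. rounding
is applied only when rendering tables. P is clamped at 1 with a warning
if P′·F exceeds 1 (cannot happen with the reference inputs).

## Hazard index

I = B·C with B ∈ {1, 0.5, 0.1, 0.05, 0.01} and C ∈ {1..5}; the 25 grade
pairs span [0.01, 5] with 19 distinct products. Per cell, I is elicited
directly as a normal (mean, sd); the grade tables are shipped so users
can construct specs, but no attempt is made to reverse-engineer per-cell
(B, C) grades. Sampling supports three truncation policies: `none`
(default — the published risk moments match untruncated propagation),
`resample` (all draws > 0, mean shifted up by the analytic truncation
bias) and `clip` (negatives set to 0).

## Monte Carlo engine

Per iteration, one factor realization per working type is shared by all
its behavior classes (F describes the role's working conditions, not an
individual behavior); hazard draws are per-behavior from independently
spawned streams (`numpy` `SeedSequence.spawn`). Samples are generated as
inverse-CDF transforms of uniforms (factors) and affine transforms of
standard normals (hazard), so results are independent of internal
batching, bitwise reproducible by seed, and exactly equivariant under
scaling of a hazard distribution.

Summaries report arithmetic sample mean and SD (matching how the source
reports its distributions), a five-number summary plus a central
confidence interval (default 95%, i.e. the 2.5–97.5 percentile band), and
a best-fit family. Family selection moment-matches each candidate
(normal, lognormal, triangular, uniform) and picks the smallest
Kolmogorov–Smirnov statistic; positive-support families are skipped when
samples contain non-positive values. The published "LN" designation of
the risk distributions is *not* reproduced by this procedure: with
untruncated hazard draws the risk samples contain negatives (lognormal
inapplicable), and even truncated samples have mild skewness (≈ 0.35)
that a moment-matched lognormal overshoots, so normal or triangular wins
the KS ranking. The moments themselves are unaffected.

Totals couple the per-behavior marginals either comonotonically (sorted
alignment — perfect rank correlation, total SD = Σ component SDs) or
independently (seeded permutation — total variance = Σ variances). The
comonotonic mode is the default because only it reproduces the published
total SDs, which equal the sums of the component SDs; both modes preserve
every marginal and hence the total mean. Independent-mode SD never
exceeds comonotonic-mode SD (rearrangement inequality).

Known distortion in the published comparison table: its risk values were
evidently computed from the 2-d.p. *rounded* revised probabilities, which
biases cells with small P by up to ~40% (e.g. P = 0.0139 entering as
0.01). The engine's unrounded results therefore agree with the published
table only on cells where that rounding is immaterial; the acceptance
tests compare exactly those cells and validate every cell against the
closed-form moment-propagation oracle instead
(E[R] = P′·F̄·μ_I, Var R = E[P]²σ_I² + Var(P)(σ_I² + μ_I²)).

## Sensitivity

Contribution-to-variance: for input i, contribution_i =
sign(ρ_i)·ρ_i²/Σ_j ρ_j² × 100 with ρ the Spearman rank correlation to the
output — the convention of spreadsheet risk tools. Zero-variance inputs
contribute 0 with a warning; if nothing correlates, there is no
attributable variance and an error is raised. Rankings break ties
alphabetically.

The pooled decomposition sums all per-behavior risks of the four key
types per iteration. Each factor is one pooled input: a single uniform
stream per factor is pushed through each type's triangular inverse CDF,
preserving per-type marginals while defining one rank sequence per
factor. The hazard index is one pooled input: a single standard-normal
stream drives every cell's normal (comonotonic coupling), reported as
`I`.

Because the correction slope is 0.0167, F's variance is ~10⁻⁴ of the
output's, so the population rank correlations of the factors are tiny
(f ≈ −0.011, d ≈ −0.0087, g ≈ −0.0083, …, a ≈ −0.0010) while I's is
≈ +1. Consequences made explicit:

- recovering even the *signs* of the weak factors requires ~9 × 10⁶
  iterations (|ρ| ≥ 3·SE = 3/√n); the acceptance test runs exactly that,
  with the study's default seed;
- d and g are a population near-tie (≈ 1.5% apart), so their relative
  order is not resolvable at any practical sample size;
- no output of this model can give factors contributions of the order of
  tens of percent; published sensitivity magnitudes of that size cannot
  arise from these equations and are not targets. Green sensitivity tests
  establish the sign/rank structure only.

## Synthetic data

`generate_accident_records` emits tables with a stated count structure:
`exact` mode reproduces target counts identically under tabulation
(tabulate ∘ generate = identity, property-tested); `multinomial` mode
draws cell counts once from Multinomial(n, p). Accident ids are
sequential `ACC-0001`-style; ordering is a seeded shuffle. The generator
does not synthesize narratives, dates or per-accident severities — none
enter any computation — so green tests establish the count algebra and
the downstream propagation, not fidelity to real accident text.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| iterations | 10,000 | the reference study's simulation size |
| confidence | 0.95 | reported as the central percentile interval |
| truncation | `none` | published moments match untruncated propagation |
| total_mode | `comonotonic` | reproduces published total SDs |
| slope / intercept | 0.0167 / 1.5 | source correction model |
| org weights | 0.2 / 0.6 / 0.2 | source correction model |
| triangular mode | midpoint | unspecified by elicitation; symmetric default |

## Limitations

- The factor elicitation and the per-cell hazard normals are expert
  judgments; the package propagates them but cannot validate them.
- The hazard normals admit negative draws for high-CV cells under the
  default policy; use `resample` when strictly positive risks are needed,
  at the cost of a known upward mean bias.
- Risk distribution *family* labels are heuristic (KS on moment-matched
  candidates); moments and quantiles are the robust outputs.
- Single-citation coding is assumed by the reference counts; multi-coded
  accidents are representable but untested against any published total.
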