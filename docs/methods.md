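# Methods

## Model and estimands

Time after stimulus onset is partitioned into K contiguous half-open bins
(a, b] covering (0, c], where c is the fixed response deadline (censoring
time). For a discrete random variable T (the rank of the bin containing the
response), the package estimates, per participant × condition stratum:

- hazard h(t) = P(T = t | T ≥ t) = E(t)/RS(t), where E(t) is the number of
  responses in bin t and RS(t) the risk set — trials still response-free
  (and uncensored) at the start of bin t;
- survivor S(t) = P(T > t) = ∏_{i≤t}(1 − h(i)), F(t) = 1 − S(t);
- probability mass P(t) = h(t)·S(t−1), which with censoring only in the
  final bin also equals E(t)/RS(1) exactly;
- conditional accuracy ca(t) = n_correct(t)/E(t).

Trials without a response by the deadline are right-censored: they
contribute to every risk set but to no event count. This is the
"singly Type I" censoring pattern of a fixed-deadline design, the setting
the package treats as standard. Interior censoring (e.g. equipment
failure) is supported by attaching an explicit censor time to a trial; such
trials leave the risk set after the bin containing that time.

### Standard errors

h, P and ca use the binomial formula √(p(1−p)/N) with N = RS(t), RS(1) and
E(t) respectively. For S we use Greenwood's formula,
se_S(t) = S(t)·√(Σ_{i≤t} E(i)/[RS(i)(RS(i)−E(i))]). Published worked
examples of this life table sometimes use an unspecified recurrence for
se_S whose values differ from Greenwood's in later bins (e.g. 0.030 vs
0.033 where the risk set has shrunk to 174); since that recurrence is not
reproducible, we document Greenwood as this package's definition and do not
treat external se_S columns as reference values. All other printed columns
of the bundled worked example are reproduced exactly at their printed
rounding.

### Conventions and degenerate inputs

- Bins are right-closed: an RT exactly on an edge belongs to the bin ending
  there (rt = 400 → bin (360, 400]).
- RTs above the deadline and missing responses are both ingested as
  censored-at-K; ingestion logs how many late responses were converted.
- h(t) is NA (not 0) when RS(t) = 0; S then propagates NA. A bin with
  E = RS gives h = 1, S = 0, and NA estimates thereafter.
- ca(t) is NA exactly when E(t) = 0.
- Estimates are kept at full precision internally; rounding (3 decimals,
  2 for ca, matching reporting convention) happens only at export.
- Strata are participant × condition cells; pooling across participants is
  an explicit choice, never implicit.

## Hazard regression

Trials are expanded to person-trial-bin format: a trial with its event in
bin t contributes t Bernoulli rows (event = 1 only in the last), a trial
censored in bin c contributes c rows of zeros. A binomial GLM on the event
indicator with the complementary log-log link,

    cloglog[h(t)] = α₀ + α₁(TIME−c) + … + α_d(TIME−c)^d + Σᵢ βᵢxᵢ(t),

is then the discrete-time hazard model; exp(β) is a hazard ratio. The
cloglog link is the default because events occur in continuous time and are
only recorded in intervals; the logit link is available. The time basis is
a polynomial of configurable degree d in TIME − c (centering c defaults to
1, so α₀ is the cloglog-hazard of the first bin at covariates zero) or
saturated bin indicators. With the saturated basis and no covariates, the
MLE of each bin's hazard equals the life-table estimate E/RS exactly — the
regression and descriptive layers agree by construction, which the test
suite asserts to 1e-6.

Estimation is single-level maximum likelihood via iteratively reweighted
least squares (statsmodels GLM). Clustered-data extensions (GEE, mixed
models, Bayesian) are out of scope; the CLI warns when multiple
participants are pooled into one fit. Rank-deficient designs, perfect
separation and non-convergence raise diagnostic errors rather than
returning a fit. Wald z intervals on the link scale, exponentiated, are
used for hazard ratios — the standard practice for this quantity.
Conditional accuracy is described and modeled separately from hazard, not
in a joint likelihood.

## Conditional-accuracy transition coding

For two conditions A and B (e.g. congruent vs incongruent primes), each
participant × bin cell is labeled by comparing ca_A and ca_B: exact-extreme
codes P (ca_A = 1, ca_B = 0) and N (the reverse); threshold codes p/n
(|ca_A − ca_B| ≥ 0.2, signed); "all" when both exceed 0.8 (strict);
single-condition codes cc/ic (only A responds, all-correct / all-error) and
ci/ii (only B); x when neither responds; ? otherwise. Rules are applied in
that order — the caption-style rule list is ambiguous for ca_A = 1,
ca_B = 0, which satisfies both P and p, and precedence keeps the most
specific label. Codes map to evidence classes (positive-effect, negative-
effect, no-evidence, other); the class of the single-condition codes
follows the sign of the effect they imply (cc/ii positive, ic/ci negative)
and is configurable, since reasonable analysts could classify these
differently. Thresholds 0.2 and 0.8 are defaults, not constants.

## Jackknife inference

Given N participant curves, subsample i is the bin-wise mean of all curves
except participant i (NaN wherever any retained curve is NaN). Features —
an extremum or a threshold crossing inside a region of interest — are
extracted per subsample; ties between equal extrema break to the earliest
bin (temporal priority). A one-way ANOVA on the N feature values per
condition (repeated-measures by default: condition effect over the
condition × subsample residual; a between-groups variant is available) is
then corrected by dividing F by (N−1)², with p recomputed at unchanged
degrees of freedom. For any statistic linear in the curves the correction
is exact: subsample deviations are individual deviations shrunk by
−1/(N−1), so the corrected F equals the individual-participant F to
machine precision (asserted at 1e-9 in tests). With N = 2 the correction
is the identity. Degenerate case: identical condition means give F = 0,
p = 1 (avoiding 0/0 when the residual is also zero).

## Synthetic generator

`sample_discrete` draws trials bin by bin from a specified discrete hazard
profile h_true (optionally with ca_true for correctness), placing event
times uniformly inside their bin so records re-bin exactly; trials
surviving all K bins are censored. It errors if ca_true is NA in a
reachable bin with positive hazard. `sample_continuous` draws exact times
from exponential, Weibull, gamma or log-normal families (scipy frozen
distributions) and censors beyond the deadline — emulating the
fixed-deadline design. `discretize_true_hazard` supplies the implied true
discrete hazard h(t) = 1 − S(b)/S(a) per bin (a, b], computed from
log-survivor differences; for the exponential with equal widths Δ this is
the constant 1 − e^(−rΔ), flat to machine precision. One seeded NumPy
generator drives each call; trial order carries no information.

What the generator emulates: right-censored RT-like waiting times with
arbitrary discrete hazard shapes, covariate-dependent hazards (via a
per-trial hazard-matrix primitive), and bin-wise accuracy profiles. What it
does not: sequential effects across trials, participant heterogeneity
within a sample, response-channel competition, or time-varying physiology —
so passing recovery tests shows estimator correctness under independent
trials, not robustness to those real-data features.

### Simulation study conditions used in the test suite

Parameter-recovery tests for the regression layer simulate from the model
itself with a cubic time baseline α = (−4.0, 0.8, −0.05, 0.001) on the
cloglog scale over K = 15 bins, a binary covariate X₁ ~ Bernoulli(0.5) with
β₁ = 0.5, a continuous covariate X₂ ~ N(0, 1) with β₂ = 0.3, and an
X₂ × time interaction β₃ = −0.02 — a rising, RT-like hazard reaching ≈ 0.6
by the late bins. Recovery runs use 5,000 trials per replicate (20
replicates), descriptive-recovery runs 10,000–20,000 trials; these sizes
make binomial error small relative to the effects while keeping the whole
suite fast.

## Numerical choices and known limitations

- Link functions are evaluated via log1p/expm1; discretization uses logsf
  differences, stable far into the tail. scipy's gamma logsf underflows to
  −∞ for extreme arguments (rate·t ≳ 1400), capping how far the gamma
  hazard asymptote can be evaluated; the other three families are stable
  much further out.
- Life-table CSVs are written with %.17g and read with round-trip float
  parsing, so write → read is lossless; rounding exists only in the
  explicit formatted export.
- Stochastic tests compare estimates to truth in units of binomial SEs:
  single-quantity checks use 3 SEs; per-bin sweeps over all 15 bins use up
  to 4 SEs so the familywise false-alarm rate of the simultaneous
  comparisons stays negligible.
- The (N−1)² correction is claimed (and tested) for one-way designs only;
  its per-effect use in factorial designs is not implemented.
- No smoothing, no continuous-time estimators (Kaplan–Meier, Cox), no
  plotting beyond data export.
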