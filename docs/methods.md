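# Methods

`predfr` implements the statistical pipeline used in stage-specific
predation studies of a predator (here a phytoseiid mite) offered larval
prey (greenhouse thrips instars) in depleting 24 h laboratory arenas. This
note records the models, the conventions chosen where the workflow is
genuinely open, and what the synthetic generators do and do not emulate.

## Functional response

### Model

In a non-replacement trial, consumed prey are not replaced, so prey density
falls as predation proceeds and the Holling disc equation overestimates
consumption. The Rogers random-predator equation gives the expected number
eaten `Ne` out of `N0` offered over duration `T` implicitly:

    Ne = N0 * (1 - exp(a * (h * Ne - T)))

with attack rate `a` (per day) and handling time `h` (days; handling caps
consumption at `T/h`). The unique physical root is computed in closed form
on the principal branch of the Lambert W function,

    Ne = N0 - W(a*h*N0 * exp(a*h*N0 - a*T)) / (a*h),

with the pure-death closed form `Ne = N0*(1 - exp(-a*T))` at `h = 0`.
Because the W argument is `exp(y)` with `y = ln(a*h*N0) + a*h*N0 - a*T`,
`y > 500` switches to a Newton iteration on `w + ln w = y` started at the
asymptotic value `y - ln y`; the two branches agree to 1e-10 against a
bracketed Brent solution of the implicit equation across
`a ∈ [0.01, 20] × h ∈ [0, 0.5] × N0 ∈ [1, 50]`.

### Estimation

Each replicate's consumed count is modelled as
`Binomial(N0, Ne(N0; a, h, T)/N0)` and the likelihood is maximised over
`(ln a, ln h)` — the log scale enforces positivity without a constrained
optimiser and tames the flat likelihood when consumption is sparse.
Nelder–Mead is restarted from five coarse-grid points
(`a ∈ {0.5, 2, 8}`, `h ∈ {0.05, 0.1, 0.3}` combinations) and the best
optimum is kept. Standard errors come from the central finite-difference
Hessian of the negative log-likelihood in log coordinates, inverted and
mapped back by the delta method; confidence intervals for positive
parameters are built on the log scale and exponentiated (better small-sample
coverage for positive parameters than symmetric Wald intervals — measured
coverage for 95% intervals over 200 replicates of the 6-density × 10-rep
design is ~96% for `a` and ~92% for `h`). A dataset with zero consumption
everywhere is reported as non-converged (`a` at the zero boundary), never
as a silent estimate.

The flexible-exponent generalisation replaces the constant attack rate by
a density-dependent `a(N0) = b * N0**q`, the one standard generalisation in
which `q = 0` reduces *exactly* to the Type II model (so the two fits are
nested). `fit(fix_q=0)` reproduces the Type II likelihood to optimiser
tolerance. Model comparison uses `ΔAIC = AIC(q free) − AIC(q = 0)`; with
correct optimisation the nesting bound `ΔAIC ≤ 2` always holds, so the
decision rule is *deviation from Type II iff `ΔAIC < −2`* (the free model
must beat its own 2-point parameter penalty); the raw `ΔAIC` is always
reported alongside the verdict.

### Type determination

The shape of the response is screened before fitting by binomial logistic
regression of consumed/remaining on initial density with linear and
quadratic terms (`statsmodels` GLM, logit link). The classification reads:

* **Type II** — linear coefficient significantly negative and the
  quadratic *not significantly negative*;
* **Type III** — linear significantly positive followed by a significantly
  negative quadratic (the sigmoidal rise-then-fall signature);
* **indeterminate** — anything else, including non-convergence or complete
  separation.

A deliberate nuance: the exact Rogers logit is not a straight line in
density — it carries mild *positive* curvature (about +0.04 per density²
at `a ≈ 4`, `h ≈ 0.2` over densities 1–10). Small experiments never detect
it, but large simulated samples always do. A significantly positive
quadratic merely flattens a monotone decline and is therefore not allowed
to overturn a Type II reading; only the Type III signature does. At the
reference design size (60 observations) the quadratic is non-significant
and the rule behaves identically to the textbook "negative linear,
non-significant quadratic" screen. When the quadratic is non-significant a
reduced linear-only model is refitted and reported too, since published
coefficients are sometimes quoted from the reduced model. Significance
threshold: 0.05 throughout.

## Manly's preference index

For a two-prey choice trial without replacement, raw consumption ratios
are biased by depletion. The log-survival form corrects for it: with
survival proportions `p_s = (n_s0 - r_s)/n_s0`,

    alpha_I = ln(p_I) / (ln(p_I) + ln(p_II)),    alpha_II = 1 - alpha_I.

`alpha = 0.5` is indifference; 1 is complete preference. Conventions at the
boundary: a replicate with no predation at all is *undefined* (the index
conditions on at least one capture); exactly one stage fully consumed takes
the limiting value `alpha = 1` for that stage — no continuity correction
(no +0.5), so a clean complete-preference outcome reports exactly
1.00/0.00; both stages fully consumed is undefined. The index is computed
per replicate and then averaged (mean ± SEM over defined replicates), not
pooled across replicates; undefined replicates are counted and excluded.
The variant tag is recorded in every output because the simple-ratio
variant is indistinguishable from the log-survival one on
complete-preference data.

## Aligned-rank-transform ANOVA

Consumption counts out of five offered prey are bounded, heavily tied and
strongly non-normal, so the factorial analysis (predator species × prey
stage) uses the aligned rank transform. For each effect the response is
aligned — residual from the cell mean plus the target effect's estimate,
with effect estimates formed from unweighted marginals of cell means —
then mid-ranked over the whole sample, and a conventional two-way
fixed-effects ANOVA is run on the ranks; only the target effect's F test
is read from each aligned analysis. Balanced designs use closed-form sums
of squares (this makes 1,000-dataset calibration simulations cheap);
unbalanced data fall back to type-III partitioning with sum-to-zero
contrasts via `statsmodels`, and the output notes which path ran only via
the degrees of freedom. Two standard diagnostics are always computed:
aligned responses must sum to ~0, and a plain (unranked) ANOVA on each
aligned response must give F ≈ 0 for every non-target effect.

Degenerate inputs follow a reporting convention rather than erroring:
all-tied responses after ranking (e.g. every treatment consumed nothing)
give F = 0, p = 1.

Post hoc contrasts are pairwise differences of estimated marginal means on
the effect-aligned ranked response, using the rank ANOVA's residual mean
square and degrees of freedom; the default adjustment is Tukey (studentized
range), with Holm available. The newer ART-C contrast procedure is noted
but not implemented.

Calibration: on null 4 × 2 × 10 binomial(5, 0.3) data the measured
type-I error at the 5% level is close to nominal (≈ 0.05–0.07 across the
three effects over 10,000 simulations). The mild liberal drift on the 1-df
main effect is a known property of rank procedures at this extreme level
of discreteness; it disappears as the response becomes less tied.

## Synthetic generators

The generators provide data with exactly the structure each analysis
assumes, not a full behavioural simulation:

* **Functional response.** `binomial` mode draws
  `consumed ~ Binomial(N0, Ne/N0)` around the Rogers expectation — the
  fitting likelihood itself, which makes parameter recovery a test of the
  estimator rather than of model adequacy. `mechanistic` mode simulates
  the renewal process (exponential search at rate `a·n`, fixed handling
  `h`, non-replacement; captures count at the capture instant even when
  handling crosses `T`, since an eaten prey is missing at scoring time
  regardless of digestion state). The mechanistic mean matches the
  deterministic Rogers curve only approximately at small `N0` — the
  implicit equation describes the mean-field process — which is exactly
  why it is kept separate from estimator tests.
* **Choice.** A competing-risks extension of the mechanistic process with
  stage-specific rates and handling times. With one stage inert it reduces
  to the single-stage process.
* **No-choice.** `consumed ~ Binomial(offered, p)` per treatment; the
  packaged default `p` map (0.62, 0.12, 0.02, 0, 0.08, 0, 0.02, 0 over the
  4 species × 2 stages) reproduces the reference study's treatment means
  (mean = 5p), including the all-zero treatments.

Default design sizes are the study's own: densities 1, 2, 4, 6, 8, 10 with
10 replicates each (60 trials); 5 + 5 prey and 10 replicates in choice
trials; 8 treatments × 10 replicates in the no-choice factorial.
Seeding uses one master `SeedSequence` that spawns an independent stream
per trial in replicate order, so identical configs are bit-stable and
adding replicates never perturbs earlier ones.

What passing tests on these generators show — and what they do not: they
verify the estimators, the index conventions and the test calibration
under the assumed observation models; they cannot detect behaviours the
generators omit (predator satiation dynamics, prey defensive secretions,
arena edge effects, multi-predator interference), so agreement here is a
statement about the statistics, not about mite biology.

## Numerical conventions

* Binomial likelihood probabilities clipped to `[1e-12, 1 - 1e-12]`.
* Optimiser tolerances `xatol = 1e-8`, `fatol = 1e-10`; the flexible fit
  is additionally seeded from the nested Type II optimum so the nesting
  bound `logL(free) ≥ logL(q=0)` holds in practice.
* Ties in ranking handled by mid-ranks (inevitable with counts 0–5).
* `ΔAIC` and fit comparisons require byte-identical input arrays; mixing
  fits from different datasets is an error.

## Problem sizes used in the checks

Parameter-recovery checks refit data simulated at the published estimates
(`a = 4.05` per day, `h = 0.218` days) with 1,000 replicates per density
(6,000 trials), where the Monte-Carlo spread of the recovered attack rate
is a few percent. Recovery-distribution and coverage properties use 200
replicates of the study-sized design (60 trials). Type-determination
classification uses 200 replicates per density, where the logistic screen
has essentially full power. ART calibration uses 1,000 simulated null
datasets of the 80-observation design.

## Known limitations

* Two prey stages only; more general multi-prey Manly indices and
  switching models are out of scope.
* Fixed-effects, two-factor ART only; no repeated measures.
* The flexible-exponent model parameterises density dependence through the
  *initial* density, as is conventional; within-trial density change is
  already absorbed by the Rogers integral.
* Bootstrap confidence intervals for the functional-response parameters
  are not implemented; SEs are asymptotic (delta method).
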