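# Methods

## The clock construction

The clock treats all-cause mortality risk as the measurable proxy of
biological age.  Two Gompertz proportional-hazards models are fitted on
the same training rows by maximizing the censored-data log likelihood

    l(a, b0, β) = Σᵢ dᵢ·(b0 + a·tᵢ + xᵢβ) − e^{b0 + xᵢβ}·(e^{a·tᵢ} − 1)/a

(tᵢ years since baseline, dᵢ the death indicator): a *full* model on
chronological age plus the LASSO-selected proteins, and an *age-only*
reference.  The proteomic age of a participant with full-model k-year
cumulative risk M is the age at which the reference model's k-year risk
equals M.  Because the Gompertz cumulative hazard factorizes as
e^{b0+xβ}·g(k;a) with g(k;a) = (e^{ak}−1)/a, the inversion is closed-form:

    A = [ log(−log(1−M)) − log g(k;a⁰) − b0⁰ ] / β⁰_age.

This is the generic risk-matching construction used by mortality-trained
clocks; published clocks vary in their intercept and rate conventions and
rarely state the horizon, so the closed form above should be read as the
standard construction, with the horizon k (default **10 years**, following
the phenotypic-age lineage of such clocks) as a free parameter.  A is exactly the
chronological age when the two models share parameters, is strictly
increasing in every positively weighted protein, and is invariant to
protein column order.  The closed form is verified against numerical
root-finding (bisection to 1e−8 years) in the tests.

Time runs since baseline with baseline age as a covariate (age-as-timescale
is a possible alternative; the baseline-time convention matches training a
time-to-death model with age as an input).  Chronological age is penalized
together with the proteins by default; `unpenalized_age` exempts it.

## Penalized Cox selection

Coordinate descent on the quadratic approximation of the Breslow partial
likelihood (score residuals g and diagonal curvature w recomputed each
outer iteration), soft-thresholding with λ on glmnet's −(1/n)·loglik +
λ‖β‖₁ scale, covariates standardized internally, warm starts along a
log-spaced path from λ_max (the smallest λ whose penalized solution is the
zero vector, computed from the null-model score) down to λ_max/100
(λ_max/20 when p ≥ n).  Convergence: max |Δβ| < 1e−7 per sweep, with
KKT screening over all coordinates via one matrix-vector product per
restart.  KKT residuals on the standardized scale are below 1e−5 at every
path point in the test suites; λ = 0 reproduces the unpenalized
Newton-Raphson solution to 1e−4.  λ is chosen by k-fold (default 10)
cross-validated Verweij–van Houwelingen partial-likelihood deviance, folds
stratified by event status, or fixed by the user.

Ties use Breslow inside the penalized fit (the coordinate-descent
standard); the unpenalized validation Cox models use Efron (lifelines).
On tie-free data the two coincide, which anchors the cross-checks.

## Gompertz fitting

L-BFGS-B with the analytic gradient from a = 0.05, b0 = log(crude event
rate), β = 0, followed by Newton polishing with step halving until
max |∇l| < 1e−6 (perturbed restarts on failure).  Covariates are centered
for conditioning and the intercept de-centered afterwards; standard errors
come from the finite-difference Hessian of the analytic gradient, with the
delta method for the de-centered intercept.  g(t;a) switches to its series
expansion for |a| < 1e−9 so the exponential (a→0) limit is smooth.
Recovery at the default generator conditions (a = 0.09, β_age = 0.08,
n = 20,000, 50 replicates) is unbiased within Monte-Carlo error.

## Fine–Gray estimation

Subdistribution-hazard coefficients are estimated as a weighted Cox
partial likelihood on the Fine–Gray risk set: a participant with a
competing event (death before the disease) at s remains at risk afterwards
with weight G(t−)/G(s−), where G is the Kaplan–Meier estimator of the
censoring distribution (Geskus weighting).  The weighted risk-set sums are
computed analytically — S₀(t) = A(t) + G(t−)·B(t) with A a reverse
cumulative sum over the natural risk set and B a forward cumulative sum of
r/G(s−) over past competing events, and likewise for the first and second
moments — so no expanded counting-process dataset is materialized and the
fit is O(events · p²).  Newton iteration runs to a 1e−10 step norm.
Standard errors are model-based (inverse weighted information), not the
robust sandwich some reference implementations report; with purely
administrative censoring the weights are exactly 1 and the two coincide
with ordinary Cox inference.  With zero competing events the estimator
reduces to Breslow Cox exactly (tested to 1e−6 against lifelines on
tie-free data).

## Preprocessing

- **Missingness filter**: proteins missing in more than 50% of
  participants are dropped.  The 0.5 threshold is a package default: it
  removes assays that are majority-missing (in practice a handful of
  proteins with 60–99% missingness) while leaving ordinarily sparse assays
  to the imputer.
- **k-NN imputation** (k = 10): Euclidean distance over co-observed
  proteins scaled by the number of shared dimensions, missing cells
  replaced by the inverse-distance-weighted mean of the k nearest
  participants (scikit-learn's `KNNImputer`, which implements exactly this
  metric).  Observed cells are never altered.
- **Inverse-normal transform**: z = Φ⁻¹((r − 3/8)/(n + 1/4)) with average
  ranks for ties.  The Blom offset is a convention choice; the transform
  itself is what matters for putting different biological-age measures on
  a common per-SD scale.
- Age adjustment is by OLS residualization on age with intercept;
  telomere-length-like measures are sign-reversed so that "higher = older"
  holds across measures.

## The synthetic-data generator

The generator emulates the statistical skeleton of a large middle-aged
biobank proteomics cohort: ages Uniform(39, 70); protein j =
slope_j·(age − 54.5) + N(0, 1) with slopes ~ N(0, 0.03) per year (age
correlations up to ~0.5, typical of plasma proteins); mortality from the
Gompertz law with shape 0.09/yr and age log-HR 0.08/yr, the log baseline
rate −9.9425 calibrated so the marginal 13-year mortality is 10.9%; 128 of
2,923 proteins causal at the full scale (log-HR magnitudes 0.1–0.35 per
expression unit); administrative censoring at 13 years with optional
uniform dropout; incident diseases as constant cause-specific hazards
racing against death; MCAR missingness plus a designated-column mechanism
for exercising the filter.  Covariates (sex, education, deprivation,
smoking, BMI) are drawn inert — they exist so adjustment tiers have
realistic columns, and the null behaviour of the tiers is itself tested.
Death times come from exact inverse-CDF sampling
(T = log(1 + a·E/B)/a, E ~ Exp(1)); one integer seed spawns independent
sub-streams per component, so outputs are byte-reproducible.

What the generator does **not** emulate: assay batch/plate structure,
non-linear protein-age trajectories, informative (health-driven) dropout,
registry-specific censoring dates, and correlated protein blocks.
Passing tests therefore demonstrate the correctness of the estimators and
the construction under the model's own assumptions, not robustness to
those real-data features.

Desk-scale runs use thousands of participants and hundreds of proteins;
the structural parameters (age range, hazard parameters, effect-size
distribution, censoring horizon) stay at the cohort-scale values above.
A note on the null-identity check: with all protein effects zero, the
fitted clock's mean |proteomic age − chronological age| reflects pure
fitting noise and scales roughly as √p/(β_age·√events); at n = 20,000 a
10-protein null panel sits near 0.5 years and the check's 1-year bound,
which the suite enforces, corresponds to that panel size.

## Multiple testing and discrimination

BH-FDR is applied across all tests of one association suite (all outcomes
× all adjustment tiers pooled into one family — the conservative pooling
convention); Bonferroni is used for per-protein association and
within each gene-set collection (over all sets in the collection, not just
those passing the ≥5-overlap filter).  Harrell's C counts risk ties as
1/2 over comparable pairs (shorter time is an event) and is cross-checked
against O(n²) enumeration; model comparisons are run on the shared
complete-case rows so every score faces the same pairs.

## Numerical and degenerate-input policy

Empty matrices, constant covariates, rate ≥ 1 missingness, all-censored
outcomes, all-identical values into the inverse-normal transform,
inconsistent hypergeometric counts, and configs pointing at absent files
all raise immediately with the offending field named.  Risks of exactly 0
or 1 abort proteomic-age inversion rather than returning ±∞ years.  Every
table is tab-delimited UTF-8 with missing values as empty strings and
floats in shortest-roundtrip form, which is what makes identical
config+seed runs byte-identical.
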