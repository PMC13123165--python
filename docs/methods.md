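# Methods

## The problem

An area-based programme (extended home visiting delivered through child
health centres, CHCs) directs extra service intensity to small statistical
areas of high socioeconomic need — proportionate universalism.  The package
asks the evaluation questions such a programme raises: did resources go to
the right places (targeting accuracy), did they reach enough places
(coverage), and does area-level targeting reach vulnerable households
within areas?  Because the underlying register micro-data are confidential,
the package pairs the analysis pipeline with a synthetic register generator
whose targeting strength is known exactly, so every estimator can be
validated by parameter recovery rather than against unavailable data.

## Measures

**Relative CNI.**  Area need is a weighted composite of four component
proportions — single parenthood, low maternal education, foreign-born
status, unemployment — divided by the population-weighted national mean
composite, so 1.0 is average need.  The component weights of the
four-component adaptation are not published; they are therefore an explicit
input (`CniWeights`), equal weights (0.25 each) by default.  The
normalising mean may be supplied as a fixed constant
(`normalization_mean`), or is computed household-weighted over the
reference panel; per-year renormalisation versus a fixed baseline mean is a
caller choice, not hard-coded.

**HVI.**  The Household Vulnerability Index counts five binary family risk
indicators (low education, foreign-born, unemployed, single parent,
parental common mental disorder).  Area aggregates are the mean, the
within-area standard deviation (population divisor *n*; a single household
has SD 0; the *n−1* divisor is available via `divisor="sample"`), and the
share of households with HVI ≥ 2.

**Dosage.**  The probability-weighted programme exposure of an area-year:
the child-weighted share of the area's registered children aged 0–5 whose
CHC is funded to deliver the programme.  Children without a registration
are excluded from numerator and denominator; an area-year with no
registered children has undefined dosage and is dropped with a logged
warning.

## Regression layer

All fits are least squares (optionally weighted by households per area)
with year fixed effects entered as dummies (first level reference) and
standard errors clustered at the area level:

    dosage_it = b0 + b1 · relative_cni_it + gamma_t + eps_it

The clustered covariance uses the CR1 small-sample factor
G/(G−1)·(N−1)/(N−K); coefficient tests use t with G−1 degrees of freedom;
joint tests are chi-squared Wald tests on the clustered covariance.  The
point estimates and covariance come from statsmodels
(`cov_type="cluster"`), which implements exactly this correction; the test
suite checks both against an independently coded normal-equations +
sandwich oracle at 1e-10.

Stage B stratifies the fit by region and tests slope equality with a
pooled region-by-need interaction model (df = regions − 1).  The quadratic
specification adds a squared need term; the turning point is −b1/(2·b2),
with the share of observations above it reported, and a numerically zero
quadratic coefficient (|b2| < 1e-12) raises an error rather than returning
an unstable ratio.  The two-part model splits the zero-heavy outcome into a
logit of any presence (cluster-robust, reported as odds ratios; year fixed
effects included by default, switchable because the original specification
is ambiguous) and a least-squares fit on the non-zero subset.  Perfect
separation is detected (non-convergence or |log-odds| > 25) and raised
explicitly.  VIFs are 1/(1−R²) from regressing each predictor on the
others with intercept; perfect collinearity reports +inf instead of
raising.

The empirical rollout year of a region is the first year in which at least
a threshold share (default 10%) of its areas has any dosage; threshold 0
means the first year with any strictly positive share.

## Equity benchmarks

**Concentration index.**  Areas are ranked by ascending need with
population-weighted fractional mid-ranks (ties share the average rank of
their group); CI = 2·cov_w(dosage, rank)/mean_w(dosage), positive when
dosage concentrates among high-need areas.  Under this rank convention the
covariance formula equals 1 − 2 × (trapezoid area under the concentration
curve) exactly, which the tests assert to 1e-6 on random instances; the
curve merges tie groups so its points are order-invariant.  Weighting is
off by default (every area-year counts once) with the household-weighted
variant available.  Bounded-outcome corrections (Wagstaff, Erreygers) and
CI decompositions are out of scope.

**Proportional benchmark.**  benchmark_i = (need_i / mean need) × mean
dosage, computed on the analysed sample.  Residuals (actual − benchmark)
sum to zero algebraically, but — unlike least-squares residuals — the
*share* of areas below benchmark is unconstrained: with 70% of area-years
at zero dosage the benchmark marks well over 70% of rows as
under-allocated while least-squares residual classification stays near
half.  The four-way classification crosses need ≥ 1.0 with residual sign;
a residual of exactly zero counts as below-or-at benchmark (conservative
tie rule, measure-zero in practice).

**Scorecard.**  Proportionality ratio = fitted slope / (mean dosage /
mean need), 1.0 under exact proportionality; high-need coverage = share of
areas at or above each need threshold (1.0, 1.5, 2.0) with any programme
presence, counted per area over the period by default (per area-year
optionally); equity gap ratio = mean dosage in the top need quartile over
the bottom (sample quantiles, linear interpolation, lower-closed cuts; a
zero denominator reports +inf).

## The synthetic register

The generator emulates the study conditions of a four-region staged
rollout: one region starts a year before the other three; the full default
panel is 4 regions × 125 areas × 6 years = 3,000 area-years (about 2,100
post-rollout); areas hold 40–100 families with children 0–5.  Its
calibration targets are the printed descriptive moments of that setting:
relative CNI mean ≈ 1.10 and SD ≈ 0.8 with a right-skewed tail, roughly
73% of post-rollout area-years at zero dosage with mean dosage ≈ 0.3 among
served area-years, and an area-level correlation of ≈ 0.86 between the CNI
and the area-mean HVI.

Mechanism, in generation order:

1. **Latent need.**  One Gaussian deprivation factor per area: a smooth
   spatial field (squared-exponential kernel, length scale 0.30 on the unit
   square, 60% of variance, standardised within region) plus idiosyncratic
   noise.  Spatial clustering matters: funding whole high-need
   neighbourhoods is what produces steep area-level dosage gradients; with
   spatially unclustered need the maximal attainable targeting slope falls
   below the emulated value.  The field is standardised within region so
   regions share comparable need profiles, as the emulated regions do.
2. **Area composition and households.**  CNI component proportions and
   household indicator probabilities are logistic in the latent factor
   (slopes fixed by calibration, intercepts root-solved so realised
   marginals match the configured prevalences exactly).  The fifth HVI
   indicator (parental common mental disorder) has no printed prevalence;
   0.15 is used as a typical register prevalence.  The coupling-noise scale
   is root-solved per realisation so the predicted CNI/HVI-mean correlation
   (including within-area binomial sampling noise) hits its target.
3. **Registration.**  Families choose among the nearest `choice_set_size`
   (5) CHCs in their region: the nearest receives `choice_concentration`
   (0.25), the rest exponential distance-decayed shares.  The decay rule is
   truncated at the choice set because an untruncated tail leaks a
   household or two per area to distant CHCs and makes a 73% zero-dosage
   share unattainable.  CHCs sit at jittered area locations (centres are
   where families live).
4. **Funding.**  The probability a CHC is funded by year *t* is linear in
   its catchment mean need, clipped to [0, 1], with a per-region-year
   intercept solved so the expected funded share follows the coverage path,
   and a tilt *g* solved by bisection so that the population projection of
   expected dosage on relative CNI — with year fixed effects, over the
   post-rollout sample, i.e. the Stage A estimand — equals `beta_true`
   exactly for the realised geography and registration.  This makes the
   Stage A estimator unbiased for `beta_true` by construction, clipping
   included.  `beta_true` may be a per-region map, in which case each
   region's own projection is calibrated (Stage B experiments).
5. **Realisation.**  Funding paths are monotone (a funded CHC stays
   funded).  Increments are drawn each year by systematic PPS sampling in a
   random CHC order with the conditional probabilities that restore the
   exact marginals, so the funded count per region-year matches its target
   to within one CHC — the funding body spends its budget — and the
   region-level common shock that plain Bernoulli draws would inject is
   removed.  With that common shock present, area-clustered standard errors
   (which cannot see cross-area funding correlation) undercover; with
   balanced draws the 95% interval covers the true slope at close to
   nominal rate in the recovery experiment.
6. **Coverage path.**  When not supplied, a linear ramp per region (85% to
   115% of its mean) is derived from `zero_share_target`: an area-year is
   zero-dosage when its local CHCs are all unfunded, and with households
   spread over about `k_eff = 3.6` effectively independent local CHCs the
   mean post-rollout funded share is set to `1 − zero_share^(1/k_eff)`.
   `k_eff` was calibrated once against the realised zero share and frozen.

All randomness flows from named substreams (population, households,
choice, funding) of one seed; identical configurations give byte-identical
tables.

### What the generator does not emulate

No residential mobility, no entry/exit of families or CHCs, no COVID-era
service disruption, no real geography or real regional differences in mean
need, and components/indicators are conditionally independent given the
latent factor (the true joint distribution of the five indicators is
unknown; only marginals and the area-level coupling are matched).  The
within-area HVI SD implied by the calibrated marginals is ≈ 0.65 rather
than the ≈ 0.80 of the emulated setting, and the simulated concentration
index is larger than the real-data value because simulated dosage is less
noisy than measured dosage.  Passing tests therefore demonstrate that the
estimators recover known targeting structure under realistic skew, zero
inflation and clustering — not that any real programme had these values.

## Numerical choices

Bisection tolerances: link intercepts 60 iterations on [−20, 20]; coverage
intercepts 50 iterations; the targeting tilt 50 iterations with bracket
expansion up to 128 and an explicit warning (maximal tilt used) if the
target slope exceeds what the configured coverage can deliver.  Design
ranks are checked by matrix rank with pivoted-QR identification of
collinear columns.  The HVI standard deviation uses the E[x²]−mean²
identity clipped at zero against round-off.  Quantile cuts use linear
interpolation with lower-closed intervals.  Degenerate inputs raise typed
exceptions (`equitarget.exceptions`) rather than propagating NaNs.

## Problem sizes

The default panel (3,000 area-years, ~30k households) simulates in about
1.5 s; the recovery experiment runs 200 replicates in about 3 minutes.
These sizes were chosen so that distributional claims (coverage between 90
and 99%, unbiasedness within Monte-Carlo error) are sharp at desk scale.
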