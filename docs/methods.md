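# Methods

`camcom` implements the analysis chain used for baseline camera-trap
assessments of tropical-forest mammal communities: raw image records are
collapsed to independent passage events; event-based abundance indices
and randomized species-accumulation curves summarize the raw data;
single-season occupancy models with imperfect detection estimate
species- and community-level occupancy and detection; a data-augmented
hierarchical Bayesian model estimates total species richness including
never-detected species; and fitted models are projected onto covariate
grids for spatially explicit occupancy maps.

## Event filtering and raw indices

Camera traps fire repeatedly while an animal lingers, so raw image
counts overstate activity.  Images of one species at one camera are
collapsed into events by a gap rule: a new event starts when the gap to
the previous image strictly exceeds a window (default 60 minutes).  The
gap rule, rather than fixed clock-hour bins, is used because it is
invariant to row order and to where a passage falls relative to an hour
boundary; the window is configurable.  Collapsing is idempotent, and
shrinking the window can only increase the event count.

The relative abundance index is RAI = 100 x events / effort, with
effort in camera-days summed over functioning cameras (a deployment's
days are `end - start` with `end` exclusive).  Naive occupancy is the
fraction of sampled sites with at least one detection; it ignores
imperfect detection and is reported for comparability only.

## Detection histories

Per-species detection matrices are sites x occasions with entries 1
(detected), 0 (surveyed, undetected) and missing (camera inactive all
occasion).  The occasion length is 5 days by default.  Occasions are
indexed from each site's own deployment start rather than on a shared
calendar: deployments are staggered across consecutive arrays, and the
single-season model treats occasions as within-site replicates, so
calendar alignment would only create mostly-missing columns (it remains
available as `align="calendar"`).  A trailing partial occasion is kept
and scored from its active days, since dropping it discards data; a
`keep_partial=False` switch supports sensitivity checks.  Site
covariates are z-scored (sample SD, n-1) before fitting and the
means/SDs are stored on the fit so prediction grids reuse the same
scale.  The three-class habitat field (regenerating / deciduous /
montane) is collapsed to a montane-vs-lowland dummy for modelling, the
contrast the analysis is designed around; the three-class field is
preserved in the I/O tables.

## Species accumulation

The sample unit is one camera-day — a (site, date) pair with its
detected-species set — pooled over cameras, so the x-axis is cumulative
effort in camera-days.  Sample order is randomized (default 1000
permutations); the curve reports the mean cumulative richness and an
empirical 2.5/97.5-percentile band, with a normal-approximation band as
an option since the randomization literature uses both.  In strongly
skewed step distributions an empirical percentile can cross the mean;
the band is clipped to bracket the mean so the reported interval always
contains the curve.  The final point equals the observed richness under
every permutation.

## Single-season occupancy likelihood

For sites i with detection history y_ij over surveyed occasions,

    L_i = psi_i * prod_j p_i^y_ij (1-p_i)^(1-y_ij)        if sum_j y_ij > 0
    L_i = psi_i * prod_j (1-p_i) + (1-psi_i)              otherwise

with logit links psi_i = logistic(x_i' beta), p_i = logistic(w_i'
alpha).  Missing occasions contribute nothing.  Detection covariates
are site-level (distances, traits), so p is constant across occasions
within a unit and the per-unit sufficient statistics are the detection
count and the number of surveyed occasions.

Maximization uses L-BFGS-B from multiple starts (zeros plus random
N(0,1) vectors, 5 starts by default) with an objective tolerance of
1e-12; restarts guard against the flat likelihoods that make sparse
species unfittable.  Standard errors come from the inverse of a
central-difference Hessian at the optimum.  A fit is flagged
non-converged when the optimizer fails or the Hessian is near-singular,
and flagged boundary when any coefficient exceeds 10 on the logit scale
(probability within 5e-5 of 0 or 1).  Units whose history is entirely
missing are excluded with a warning; a species with zero detections is
rejected as unfittable.

## Model selection and averaging

Candidate models are ranked by AIC = -2 logL + 2k; Akaike weights are
exp(-Delta_i/2) normalized.  For species-specific fits the default
candidate set crosses p options {constant, border, edge} with psi
options {constant, each of border/edge/river/habitat, all pairwise
combinations}; the exact published candidate list is rarely stated in
field studies, so the set is configuration-driven with this default.
Species enter the species-specific analysis when they have at least 10
events or naive occupancy of at least 0.1, and non-converged fits are
dropped.

Models with weight above 0.01 are averaged with renormalized weights.
Full-model averaging is the default — a coefficient absent from a model
counts as 0 with zero variance — because averaged tables in this
literature report rows for terms that appear only in a subset of
models; natural averaging (per-term renormalization over the models
containing the term) is available.  Per-coefficient unconditional SEs
use the classic formula sum_i w_i sqrt(var_i + (theta_i - theta_bar)^2).
For delta-method prediction SEs a full averaged covariance
sum_i w_i (V_i + d_i d_i') is carried, whose diagonal differs slightly
from the squared classic unconditional SE; the classic form is what the
summary tables print.  A term's relative importance is the summed
weight of the models containing it.

## Stacked multi-species model

To relate relative species richness to habitat and detection to trophic
guild and body mass, the detection histories of all retained species
are stacked: each (species, site) pair is one occupancy unit, site
covariates act on psi, and species traits (guild as a categorical with
carnivore reference, standardized body mass) act on p.  Units are
treated as independent given covariates — no per-species random effect
— which keeps parameter counts at 2-7 and matches how this analysis is
done with standard occupancy software; the community model below is
the hierarchical counterpart.  Outlier species (e.g. very large-bodied
herbivores that range in and out of the survey area, or atypically
detectable members of a guild) can be excluded by name to keep guilds
homogeneous.  Body mass enters as standardized raw mass by default with
a log-mass option, since either convention appears in practice.
Per-guild detection is back-transformed at the reference of the other
p covariates with delta-method SEs; per-site expected richness is the
summed fitted psi of the best-supported model.

## Data-augmented community model

Total richness N is estimated by embedding the observed species list in
an augmented list of size M (default 100) with inclusion indicators
w_k ~ Bernoulli(Omega).  Species effects (u_k, v_k) — logit occupancy
and logit per-occasion detection — are bivariate normal with means
(mu_u, mu_v), SDs (sigma_u, sigma_v) and correlation rho.  Occupancy is
z_ik ~ Bernoulli(w_k psi_k) and detections are binomial over surveyed
occasions.  Detection is constant within species (no site covariates):
the model is used solely for richness, and this matches the cited
community-model structure.  Priors: Omega ~ U(0,1), mu_u and mu_v ~
N(0, 1.81^2), sigma ~ U(0,10), rho ~ U(-1,1).  The 1.81 is pi/sqrt(3):
a normal with that SD matches the standard logistic, so the community
*mean* occupancy and detection are approximately uniform on the
probability scale.  This matters: a nominally "vague" N(0, 10^2) prior
on a logit-scale mean concentrates almost all of its mass at
probabilities indistinguishable from 0 or 1, which makes communities of
effectively invisible species cheap a priori and visibly inflates the
richness posterior; data-augmentation richness estimators are known to
be sensitive to exactly this choice.  The prior SD remains a config
field for sensitivity analysis.

The sampler is Metropolis-within-Gibbs: exact Bernoulli/Beta updates
for z, w and Omega (w is updated with z marginalized out for unobserved
species, which detections force to w=1 otherwise); an exact bivariate-
normal draw of (u_k, v_k) for currently excluded species; joint
random-walk Metropolis for included species' effects and for
(sigma_u, sigma_v, rho); and a conjugate normal draw for (mu_u, mu_v).
Random-walk scales adapt toward ~0.3 acceptance during burn-in only, so
the retained chain is a valid fixed-kernel Markov chain.  The default
schedule is desk-scale (3 chains x 6,000 iterations, burn-in 1,000,
thinning 10); the full published-scale schedule (5 chains x 55,000,
burn-in 5,000, thinning 50, giving 5,000 retained draws) is available
as a preset.  Convergence is monitored with the classic Gelman-Rubin
potential scale reduction factor.

Known behaviour: the posterior of N is right-skewed, and when the
observed community contains several very rarely detected species the
model places substantial mass on large N; with broader hyperpriors this
effect grows sharply.  Credible intervals are wide accordingly; the
augmentation size M only truncates the upper tail and doubling it
leaves the posterior median essentially unchanged (checked in the test
suite).  In every draw N is at least the number of detected species.
Even with calibrated priors, a replicate in which nearly every true
species happens to be detected can yield an interval lying wholly above
the truth — a fixed-parameter frequentist-coverage gap that is a
property of the model, not of the sampler.

## Spatial prediction

Occupancy from a fitted or model-averaged species model is projected
onto a covariate grid (100 m cells in the intended use).  Grid
covariates are standardized with the stored fit-time means/SDs; psi =
logistic(x'beta) with delta-method SEs computed on the logit scale and
back-transformed, so intervals respect [0,1].  Cells missing any model
covariate get missing predictions.  Output is plain CSV plus an
optional ESRI ASCII raster, leaving map rendering to GIS consumers.
One-covariate response curves with Wald bands use the same machinery
and flag extrapolation beyond the observed covariate span.

## Synthetic survey generator

The generator emulates the survey design this pipeline targets: 60
sites on a ~2 km^2 grid along an east-west gradient, with distance to
the eastern border strongly correlated with elevation (target Pearson
r = 0.8, achieved by giving elevation a linear trend in border distance
plus calibrated Gaussian noise); habitat assigned by thresholding
border distance into regenerating / deciduous / montane; three
consecutive arrays of 20 cameras, each run ~30 days, with a 2/60 chance
of total camera malfunction (a failed camera contributes no records and
no effort).

The community is hierarchical: ~30 true species draw (u_k, v_k) from a
bivariate normal (defaults mu_u = -1.0, sigma_u = 1.5, mu_v = -4.6,
sigma_v = 1.0, rho = 0.5, with v on the *daily* detection scale), plus
guild offsets on detection (herbivore +2.8, omnivore +1.5, insectivore
+0.7 over the carnivore reference) and a weak negative standardized
log-mass effect (-0.1).  These defaults were calibrated once so that a
default survey detects ~26-27 of 30 species and the implied 5-day-
occasion detection by guild is approximately 0.53 / 0.20 / 0.10 / 0.05
(herbivore / omnivore / insectivore / carnivore) — the regime of a
real tropical-forest camera-trap baseline, where a handful of rare,
poorly detectable species are missed entirely.

Detection is simulated at daily resolution — one Bernoulli passage per
occupied camera-day — and aggregated to 5-day occasions downstream, so
one dataset serves both the accumulation curve (day resolution) and
occupancy models (occasion resolution).  Latent occupancy is drawn once
per species-site and held for the season (closure).  An event emits
1 + Poisson(2) images at distinct minute offsets within an hour, so
event collapsing is exercised non-trivially; event start times are
restricted to 00:00-22:00, which keeps clusters from straddling
midnight into the next day's window (the daily-resolution bookkeeping
would otherwise not be exactly recoverable).  The image-count
distribution is a free choice — nothing downstream depends on it beyond
exercising the collapser.

What the generator does *not* emulate: animal movement and home ranges
(no spatial autocorrelation of occupancy beyond covariate effects),
temporal activity cycles, partial camera failures (failures are
all-or-nothing), misidentification, and unmodelled detection
heterogeneity within species.  Passing parameter-recovery tests
therefore show the estimators are correct under their assumed model,
not that those assumptions hold in any particular field dataset.

## Verification experiment design

The test suite verifies each stage against independent oracles (gap-scan
and 2^S latent-state enumeration), and the statistical machinery by
parameter recovery at these problem sizes, chosen to mirror a realistic
single-season baseline while keeping the default suite fast:

- MLE recovery: 100 datasets of 58 sites x 6 occasions at psi = 0.6,
  p = 0.3 (constant model); 95% Wald intervals and median bias.
- Guild detection: 50 surveys of 24 species (balanced guilds) with
  guild-determined detection (within-guild SD 0); the stacked model
  must recover herbivore > omnivore > {insectivore, carnivore}.
  Detection is made guild-determined here because the quantity under
  test is the ordering of guild effects, not robustness to within-guild
  heterogeneity.
- Community-size coverage: 20 default-condition surveys (true N = 30,
  ~3-4 species undetected), desk-scale MCMC schedule, M = 100; the 95%
  CRI should cover 30 in at least 17 of 20 replicates.  Because the
  posterior is heavy-tailed under vague hyperpriors (see above),
  replicates where nearly all species are detected can still produce
  intervals lying above the truth; this is a property of the model, not
  of the sampler, and is documented by the experiment rather than
  hidden by tighter priors.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage child seeds from one master seed via a seed sequence, so a
full run is reproducible bit-identically for deterministic stages and
draw-identically for MCMC.  The run manifest records the package
version, stage seeds, input digests, stage timings and all warnings.
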