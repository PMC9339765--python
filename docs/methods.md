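# Methods

## Problem and approach

Classical removal and closed-population capture-mark-recapture (CMR)
estimators assume that marked and unmarked individuals mix at random between
capture occasions. Immobile organisms — here overwintering butterfly larvae,
each occupying one leaf shelter ("hibernaculum") — cannot mix. The design
implemented in this package substitutes surveyor movement for organism
movement: several surveyors independently search the same plot, one after
the other, each without knowledge of earlier finds. Each surveyor's search
is one *occasion*, and the occasion axis is indexed by surveyor identity
rather than time.

Three estimators share a common data model (per-plot binary detection
matrices D[i, t] with surveyor, plot and individual metadata):

1. the **minimum larva number (MLN)** — distinct individuals ever detected,
   a direct lower bound;
2. a **permutation removal estimate** — depletion regression over random
   surveyor orders;
3. a **Huggins closed-population CMR fit** — conditional maximum likelihood
   with surveyor- or experience-structured detection and Horvitz–Thompson
   abundance per plot.

Closure is enforced by removing individuals whose shelters disappeared
during the study (`filter_closure`); they stay in the files so mortality
summaries can still count them.

## Permutation removal

Under a constant per-occasion detection probability p, the expected number
of *new* detections at a pass is p·(N − x), linear in the number x already
found, so the x-axis intercept of an ordinary least-squares fit of new
detections on prior detections estimates N (the Leslie–Davis depletion
regression). Because surveyors worked independently and uninformed, their
order is exchangeable: the estimator resamples 10,000 uniformly random
occasion orders (with replacement from the T! orderings, keeping the
resample count fixed regardless of T), refits each, and reports the median
and the 2.5/97.5 percentiles (linear interpolation between order
statistics) of the finite x-intercepts.

Orderings whose fitted slope is ≥ 0, or whose x values are all equal, admit
no finite abundance; they are excluded from the summaries and reported as
`n_degenerate` so the exclusion is auditable. A point estimate below the
MLN is possible (the regression can undershoot) and is flagged rather than
clamped. The OLS inside the permutation loop is the closed-form
normal-equations solution, vectorised across permutations; an independent
OLS implementation serves as the oracle in the test suite.

A note on two-occasion algebra: the two-point depletion regression gives
x-intercept n1²/(n1 + m2 − n2), which coincides with the Lincoln–Petersen
estimate n1·n2/m2 exactly when the two occasions detect equally many
individuals (n1 = n2). The Lincoln–Petersen identity holds unconditionally
for the two-occasion *occasion-dependent* Huggins fit (below), where the
conditional MLEs are p̂1 = m2/n2, p̂2 = m2/n1.

## Huggins conditional likelihood

The likelihood conditions on detection at least once, so abundance cancels
and only detection parameters remain:

    log L(β) = Σ_i Σ_t [ D_it·log p_t + (1 − D_it)·log(1 − p_t) ] − Σ_i log p*_i
    p*_i = 1 − Π_t (1 − p_t)   over the occasions of individual i's plot.

Capture and recapture probabilities are fixed equal (p = c): an immobile,
unmarked-again individual cannot respond to having been found. Detection
structures:

* **constant** (M0): one p;
* **occasion** (Mt): one p per *surveyor*, shared across the plots that
  surveyor searched — the only structure consistent with reporting
  surveyor-specific probabilities pooled across plots;
* **experience**: logit p = β0 + β1·[expert], a two-level occasion covariate.

All parameters are estimated on the logit scale, which keeps p in (0, 1).
Because individuals within a plot share an occasion set, the likelihood
reduces to per-plot sufficient statistics (per-occasion detection totals
and the group size M), and its gradient is analytic:

    ∂logL/∂η_t = n_t(1 − p_t) − (M − n_t)·p_t − M·(1 − p*)·p_t / p*.

Optimisation is BFGS with this gradient, restarted from logit p ∈
{−2, −1, 0}, followed by damped Newton polishing with a finite-difference
Hessian (BFGS alone occasionally stalls on precision loss just short of the
convergence criterion, a gradient infinity-norm below 1e-6). Standard
errors come from the inverse of the finite-difference observed information
(central differences of the analytic gradient, relative step 1e-5).
Estimates with |logit p| > 10 are boundary cases (p numerically 0 or 1) and
produce no abundance interval.

Abundance per plot is Horvitz–Thompson over the observed individuals,
N̂ = Σ_i 1/p*_i = M/p*. Its variance is the Huggins two-term estimator: a
binomial part M(1 − p*)/p*² plus a delta-method part J^T V J, where V is
the parameter covariance and J = ∂N̂/∂β is computed analytically through
∂p*/∂η_t = (1 − p*)·p_t. The 95% interval is the MARK-convention log-normal
interval on f0 = N̂ − M:

    C = exp(1.96·sqrt(log(1 + var(N̂)/f0²))),  CI = (M + f0/C,  M + f0·C),

bounded below by the individuals actually observed; f0 ≤ 0 collapses the
interval to (M, M). In recovery simulations at the package's test design
point (N = 200, six occasions, p = 0.3) the estimator is unbiased to within
a fraction of a percent and the interval covers at ~94%, typical of Wald-
type intervals at this sample size.

## Reduced-effort evaluation

For each plot and each subset of k of its expert surveyors (k = 2…6), the
matrix is restricted to those occasions, individuals no longer detected are
dropped, and the model is refit — constant p for k = 2 (two survey rounds
cannot support occasion-specific p stably), occasion-specific otherwise.
Each refit is scored against the full-effort (all-surveyor) estimate N̂_f
of the same plot:

* relative error = |N̂_i − N̂_f| / N̂_f  (accuracy),
* relative CI width = (upper − lower) / N̂_i  (precision).

A refit is *reliable* when the optimizer converged, no parameter sits on
the boundary, the abundance variance is finite, and the CI upper bound is
below 50·N̂ — an explicit operationalisation, reported with every scan so
the reliable/unreliable split is auditable. Summary means are arithmetic
means over reliable subset×plot results. Subsets are unordered; the shared
p = c likelihood is order-invariant.

A single expert's count can also be scaled into an abundance estimate by
dividing by a detection probability (the surveyor's own estimate or the
expert-group mean from the full-effort fit); `single_surveyor_errors`
scores these the same way.

## Equal-detectability check

The models assume all individuals are equally detectable. With the
full-effort abundance estimate N̂ (rounded to an integer) taken as truth
and surveyor j's haul fixed at the n_j individuals they actually found,
each simulation replicate draws, per occasion, a uniform simple random
sample of size n_j *without replacement* from the N individuals — surveyor
j found exactly n_j distinct shelters — and tallies per-individual
detection counts into a frequency table over k = 0…T. 10,000 replicates
give per-k medians and 2.5/97.5 percentile envelopes. The observed table
(with the k = 0 bin set to N̂ − MLN) is then flagged per bin as inside or
outside the envelope. Heterogeneous detectability shows up as excess mass
in the never/rarely-found and often-found tails. The check is deliberately
visual/structural; no goodness-of-fit p-value is attached.

## Synthetic surveys

The generator draws D[i, t] ~ Bernoulli(p_t·h_i) independently, with h_i ≡ 1
by default (equal detectability) or a Beta(a, a) multiplier rescaled to
mean 1 and the product clipped to [0, 1] when heterogeneity is requested —
the simplest violation generator for the detectability check. Species,
occupancy and loss labels are drawn per config; individuals never detected
are excluded from the observed view (as in real field data) but kept in the
attached ground truth. A single root seed feeds a named substream per plot
(SHA-256 of the plot id mixed into the seed sequence), so one plot's draws
do not change when another plot's configuration does.

The default configuration reproduces the geometry of a three-plot winter
survey on a spruce clear-cut: plots of 916/807/2952 m² with true abundances
32/18/28, searched by 10/9/10 of 13 surveyors; 6 experts with detection
probabilities 0.51…0.23 (mean 0.35) and 7 novices 0.25…0.10 (mean 0.16);
~45% empty shelters, a 95% focal-species share among occupied ones and a
~4% loss rate. The expert roster covers the plots 6/6/5, which makes the
2–6-expert scan yield exactly 140 reduced-effort models. Under these
settings the expected MLN per plot is within one individual of the true
abundance, matching the regime the estimators are meant for (near-exhaustive
combined effort).

What the generator does **not** emulate: spatial structure (host-plant
positions, within-plot detectability gradients), surveyor fatigue or
learning, inter-surveyor correlation in which individuals are hard to find,
and seasonal change in detectability. Passing tests therefore demonstrate
correctness of the estimators under the stated sampling model, not
robustness to every field complication.

## Problem sizes and numerical choices

* Removal permutations default to 10,000; recovery simulations in the test
  suite use 2,000 per dataset (point-estimate medians are stable well below
  the default) across 200 datasets.
* Huggins recovery uses 500 replicates at N = 200, 6 occasions, p = 0.3;
  detectability calibration 200 seeds with 2,000 band replicates each.
* Percentiles everywhere use linear interpolation between order statistics.
* Ties in `argpartition`-based sampling are broken by continuous uniforms,
  so without-replacement draws are exactly uniform.
* Degenerate inputs: empty matrices give MLN 0; all-detected matrices give
  boundary fits with N̂ = M; disjoint two-occasion detections give fully
  degenerate removal results, reported as explicit failures.

## Known limitations

* The experience model treats all experts as exchangeable; with strongly
  heterogeneous surveyor skill its group probabilities are detection-
  weighted averages, not simple means of surveyor-specific rates.
* The log-normal f0 interval mildly undercovers (~94%) at moderate sample
  sizes, as is typical for Wald-type intervals.
* MARK .inp export with group columns requires equal occasion counts across
  plots; unequal designs are written one file per plot.
* Individual heterogeneity is modelled only as a multiplicative Beta
  factor; it is a diagnostic device, not a fitted mixture model.
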