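# Methods

## Data model

Ratings are integers on the 9-point SAM scale, one per
(worker, picture, dimension). The long CSV form
(`worker,picture,dimension,rating,population,batch`) is pivoted into
items × raters matrices per dimension and population slice; cells a
worker did not fill are explicit missing values (never imputed at the
I/O layer). Gold labels are per (picture, dimension) mean/SD/n
triples, the form in which normative lab studies publish reference
values.

## Intraclass correlations

Both ICC definitions come from the exact two-way crossed ANOVA without
interaction replicates:

    SSR = k Σᵢ (r̄ᵢ − m)²,  SSC = n Σⱼ (c̄ⱼ − m)²,
    SSE = Σᵢⱼ (xᵢⱼ − r̄ᵢ − c̄ⱼ + m)²,

with MSR = SSR/(n−1), MSC = SSC/(k−1), MSE = SSE/((n−1)(k−1)).
Single-measurement forms only:

* consistency = (MSR − MSE) / (MSR + (k−1) MSE) — invariant to adding
  a constant to any column, confined to (−1/(k−1), 1];
* agreement = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)) —
  penalizes rater shifts. Note the estimator is only bounded above:
  on small pathological matrices it can fall below −1, and when
  MSR < MSE (negative numerator) adding rater variance moves the
  estimate *toward* zero. No clamping is applied; consumers see the
  raw estimate together with the mean squares it came from.

Missing cells are handled by complete-case row deletion (the count of
dropped rows is part of the result); a strict mode errors instead.
Average-measure forms, confidence intervals and F tests are
deliberately out of scope. Band labels default to ≥ .75 "excellent",
≥ .4 "fair", else "poor".

## Reliability simulation

A simulated run of size k draws, for each picture, k ratings uniformly
without replacement from that picture's pool; 30 independent runs per
k (k = 1…15 by default). Runs necessarily overlap in sampled ratings —
a pool of 30–50 cannot support 30 disjoint runs of up to 15. The
across-run ICC(consistency) of the pictures × runs grid of run means,
per k, is the reliability curve; `min_ratings` reports the first k at
or above a threshold (default .75). The per-k dispersion is the SD of
the ICC over `n_dispersion` (default 10) independently re-drawn run
sets.

The sampling unit is ratings-per-picture, which guarantees exactly k
ratings everywhere; a `per_run_workers` mode (sample k whole raters,
average what they provided) exists for sensitivity analysis, since
page-structured coverage cannot guarantee per-picture counts.

Under the additive homoscedastic model (rating = μ_p + ε,
ε ~ N(0, σ_w²), Var(μ) = σ_p²) the curve converges to
σ_p²/(σ_p² + σ_w²/k). Two finite-sample effects move the estimate
slightly above the closed form: sampling without replacement from a
finite pool shrinks the within-run variance by (1 − k/N), and the
run means target the pool means, whose variance is σ_p² + σ_w²/N.
Closed-form recovery tests therefore use pools of 500 ratings where
crossing positions matter (both effects < 0.01 there) and tolerate the
documented bias at pool 50.

## Dip test

`dip_statistic` implements the greatest-convex-minorant /
least-concave-majorant interval-shrinking algorithm. Conventions: the
dip is floored at 1/(2n) (a single observation has dip 0.5, n tied
observations 1/(2n)); the implicit unimodal class is continuous
between data points with an atom permitted only at a data-point mode
(tied jumps can be hugged exactly, gaps cannot). The test suite checks
the implementation against an independent linear-programming oracle
that minimizes the sup-norm distance over exactly this class,
enumerating continuous-mode and atom-mode placements at every unique
point (gap modes are provably subsumed by the adjacent point modes).

p-values are Monte-Carlo: B samples (default 2000) of size n from the
uniform distribution — the asymptotically least favourable unimodal
null — with the add-one estimator p = (1 + #{dip_null ≥ dip}) / (B+1),
so p is never zero and the α = .05 rejection rate under the uniform
null is calibrated to Monte-Carlo accuracy. Discrete 9-point ratings
are heavily tied; the default `jitter` policy adds uniform (−0.5, 0.5)
noise (seeded, reproducible) before the dip, with a `raw` mode
available. The unimodal/multimodal call compares p to α = 0.05 by
default. Numba compiles the inner loops; the first call per process
pays a one-off JIT cost.

Power caveat: at n = 40 the dip test only reliably detects two-group
structure when the subgroup means sit ≳ 5 residual-SDs apart
(half-separation δ ≳ 2.5σ). At δ = 2σ its power is ≈ 0.48, and a
random (binomial) split of raters between opinions costs further
power relative to an even split.

## Synthetic campaign generator

The generator emulates the campaign design end to end: pages of 20
pictures, workers rating whole pages, two populations with a noise
multiplier (specialized 1.0, general 1.3), per-page worker counts
drawn from the target pool range 30–50. One rating is

    round(clip(μ_pd + s·δ·[divisive] + b_w + ε, 1, 9)),

with per-worker bias b_w ~ N(0, 0.25), residual
ε ~ N(0, σ(μ)·multiplier) and the noise profile
σ(μ) = σ_min + (σ_max − σ_min)(1 − |μ−5|/4), peaking at the neutral
midpoint (σ_max = 0.6) and shrinking toward the extremes
(σ_min = 0.4). True means are uniform on [2, 8] (so the SD-extremity
profile is exercised across the scale). A configured fraction
(default 25%) of pictures is divisive: each belongs to a theme, every
worker carries one opinion sign per theme, and the rating location
shifts by ±δ (default 2). Rounding is half-to-even; values clipped at
the scale ends are counted (≈1% under defaults, kept below 5%).

Gold labels come from an independent reference panel (25 simulated
raters, unit multiplier, own seed stream); each picture is labelled by
a random 8–25 of them, so gold means are finite-sample estimates — as
normative values are — and share a small common panel-bias offset.
Consequences worth knowing: the mean-shift test between crowd and gold
means sees that common offset as a genuine (random) shift, so
occasional small corrected p-values are expected behaviour, not bugs.

Parameter rationale. δ = 2 with σ_max = 0.6 and bias 0.25 puts
divisive subgroup modes ≈ 4 scale points (≈ 5 effective SDs) apart —
strongly bimodal, so a 40-rating pool detects them with high
probability, matching the regime in which reported unimodal fractions
(~75% with 25% divisive pictures) are reproducible. The price is that
unimodal per-picture rating SDs (~0.7) sit below those of typical
normative studies (~1.1–2); with realistic residual noise the same
subgroup separation would be largely invisible to the dip test at
these sample sizes. The generator models opinion structure first and
absolute noise magnitude second.

The generator does **not** model: per-dimension differences in mean
dispersion or noise (all dimensions are exchangeable by default, so it
will not by itself reproduce "valence reliable at 3 ratings, arousal
at 8, dominance poor" — those regimes are exercised through planted
variance pools instead), worker fatigue, response times, or picture
semantics (themes are opaque tags).

`gaussian_pool` provides the planted-variance testing pool: picture
means standardized to a sample variance of exactly σ_p² (so
closed-form comparisons are not blurred by the ~10% sampling noise of
a 200-picture variance draw), real-valued ratings, homoscedastic σ_w².

## Opinion transfer

Ratings are binarized about the neutral value 5; 5 itself is excluded
(reported in `n_excluded`, never silently dropped) because "below" and
"above" are the only defined sides. Transfer counts are computed over
workers who rated both pictures of a pair; pairs default to all
multimodal pairs within a dimension. With themed divisive pictures,
same-theme pairs show near-zero switch fractions (a worker's sign is
constant per theme; switches require noise crossing the neutral line)
while cross-theme pairs switch ≈ 50% of the time (independent signs).

## Agreement evaluation

Crowd labels are means over 30 simulated 8-rating runs (equivalently,
the grand mean of the sampled ratings). Quality is the
absolute-agreement ICC of the pictures × (crowd, gold) matrix,
alongside its consistency ICC: a constant crowd-gold offset keeps
consistency at exactly 1 while agreement drops strictly below 1.
Deviation flags list pictures with |crowd − gold| ≥ 1.5 scale points
(threshold explicit and configurable), largest first. The systematic
shift test is a paired two-sided t-test on per-picture means per
dimension (Wilcoxon signed-rank available; the choice is recorded in
the output), Bonferroni-corrected by the number of dimensions tested
— the family size is logged since conventions differ.

## Pipeline determinism

The CLI derives per-stage streams from the master seed through fixed
labelled offsets, writes no timestamps, and serializes JSON with
sorted keys, so `simulate` + `analyze` are byte-reproducible. Stage
errors in lenient mode are collected into the report's `errors` list
with partial results written; strict mode exits non-zero.

## Problem sizes

Defaults throughout are the reference campaign shape (60 pictures,
30–50 ratings per picture and population, k = 1…15 with 30 runs,
2000-replicate dip nulls). The statistical validation suite uses 500
random matrices for ICC oracle equivalence, 1000 samples for dip
oracle equivalence and for null calibration, 50 seeds per
minimum-ratings recovery scenario (200 pictures, pool 500), and 20
replicate campaigns for modality-fraction recovery.
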