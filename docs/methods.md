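# Methods

This note documents the models and procedures implemented in `driftdive`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Conventions

Depth is in metres, positive downward; within-dive time is seconds since
the dive start; absolute start timestamps are kept separately and daily
binning uses UTC calendar days.  Drift rate is Dr = −ΔD/ΔT over the drift
segment, so a sinking (negatively buoyant) seal has Dr < 0.  Dives are
pre-filtered to maximum depth ≥ 100 m (inclusive) — below which residual
lung air no longer biases buoyancy — and duration ≥ 300 s (inclusive);
the boundary conventions follow the filter definitions literally
("reaching 100 m" keeps an exact 100 m dive, "lower than 300 s" keeps an
exact 300 s dive).

## Broken-stick summarization and its reverse

`bsa_summarize` reproduces the on-board abstraction: the first selected
point is the dive's deepest sample (its residual is the discrepancy from
the start–end line); each subsequent point maximizes the absolute vertical
discrepancy between the profile and the piecewise-linear reconstruction
through the already-selected points.  Discrepancy is vertical (depth)
difference at sample times, not perpendicular distance, and reconstruction
interpolates in time.  Ties — including the all-zero discrepancies of an
exactly piecewise-linear profile — are broken by earliest time;
discrepancies below 10⁻⁹ m are treated as zeros so floating-point noise
cannot defeat the tie rule.  Profiles with fewer than four informative
interior samples are padded with earliest-time zero-residual points,
keeping the six-point schema fixed.

`recover_order` (RBSA) re-runs the same selection using only the six
transmitted points: the deepest transmitted point is placed first, then
each remaining point with the largest discrepancy from the reconstruction
through the placed points.  Because both directions share the discrepancy
definition and the earliest-time tie rule, the recovered order equals the
recorded forward order whenever each step's argmax over transmitted points
is unique (and in the zero-residual fill cases as well); the recovered
residuals then equal the forward residuals exactly.  The implementation
flags `ambiguous` when any step was decided by the tie rule.

A caution about a tempting "invariant": the maximum reconstruction
discrepancy is *not* guaranteed to be non-increasing as points are added.
Moving the reconstruction toward the worst sample can increase the
discrepancy of opposite-sign samples in the same span.  On dive-shaped
profiles the residual sequence is non-increasing for the large majority
of dives, and the six-point summary always improves on the start–end
baseline; the tests assert exactly that.

## Shape variables and grouping

All variables are unit-free proportions where possible so one threshold
serves short/long and shallow/deep dives alike: depth ratios d_i =
D_i/max-depth, time ratios t_i = T_i/E, duration proportions ps0..ps4
(descent, segments 1–3, final ascent; they sum to 1), segment rates
f, s, t (raw depth slope, positive = deepening), sratio (descent rate over
first post-descent segment rate), meand/sdd (mean and sample SD of the
d_i), least-squares line residuals r1..r4 through {(T_i, D_i)} (they sum
to zero), mrratio (smallest recovered residual over max depth),
mdepthbias (time at maximum depth minus E/2, in seconds), mdepthr (mean
inflection depth over max depth).  Two auxiliary criteria used by two
groups are defined here as: avratio = mean signed vertical rate after the
deepest inflection point divided by the mean before it; hp_i = d_i.  Both
are plain dataclass fields, so alternative definitions can be substituted
upstream of the rule engine.

Grouping admits eight of the 24 order labels as candidate drift-dive
groups (`2.1.3.4, 2.1.4.3, 2.4.1.3, 3.1.2.4, 3.1.4.2, 3.2.1.4, 3.4.1.2,
4.2.1.3`).  Within a group the drifting segment (1–3; descent and final
ascent are never drift segments) is assigned by an ordered rule table
shipped as YAML.  The engine — ordered predicates over named variables,
first hit wins, declared per-group fallback — is the tested artifact; the
default table is a best-effort transcription in which some cells of the
published rules render ambiguously, and those rows are marked
`reconstructed` in the file.  Notably, group `4.2.1.3` is assigned to
segments 2/3 by its mdepthbias branches: under that order the fourth
time-sorted point is the deepest, so segment 1 is the pre-drift descent
limb and cannot be the passive phase.  `mdepthbias = 0` exactly satisfies
only explicitly inclusive (`>= 0`) branches; elsewhere it falls to the
group's fallback.  Dr = 0 exactly belongs to neither sign subgroup and is
dropped (sign-specific thresholds cannot apply to it).

## Threshold criteria

Threshold rules are (group, sign, criterion, strict one-sided bound or
open interval, order index); rules matching a candidate are applied in
order and the first failure rejects, giving per-dive traces.  Because the
rules are conjunctive, ordering affects traces only, never the accepted
set.  The default ruleset ships only the rows whose attribution to
(group, sign) cells is determinate: d1 < 0.8 everywhere except group
3.2.1.4, where the bound applies to d2 (that group's drift segment is
always segment 2); d4 < 0.8 except group 4.2.1.3 (whose d4 ≡ 1 by
construction); mrratio < 0.3; t4 > 0.8 for negative candidates; ps1 > 0.4
for the negative `2.1.x` groups whose drift segment is segment 1.  Where a
published row lists several strictnesses across groups, the loosest value
is applied uniformly — a deliberately conservative transcription that
favours recall; users with verified tables should edit the YAML.

`tune_threshold` reproduces the accepting–rejecting procedure used to
derive such rules: scan every observed value of one criterion as a cutoff
in both directions, compute non-drift rejection and drift-dive loss, and
propose the cutoff maximizing rejection subject to a loss budget (default
≤ 10%), provided it reaches the target rejection (default 50%); the full
accept/reject curve is returned for plotting.  Interval rules are tuned as
two sequential one-sided rules.

## The trajectory filter

State-space model per seal, time in days:

    rho_k = (m0 + delta_k) / (v0 + V * delta_k)
    mu_k  = alpha * sign(rho_k - 1) * sqrt(|rho_k - 1|)
    delta_k = delta_{k-1} + eta_k,   eta_k ~ N(0, tau_delta * (t_k - t_{k-1}))
    z_k ~ Bernoulli(p)
    r_k | z_k ~ N(mu_k, tau_r_in) if z_k = 1 else N(mu_k, tau_r_out)

Water density is the constant 1 (relative units).  `tau_delta` is a
variance *rate*: increment variance grows linearly with the time gap, so
doubling all gaps while halving `tau_delta` leaves the path law unchanged.
`alpha` (m/s per √density-difference) is negative under positive-down
depths — a denser-than-water seal sinks.  The quadruple (m0, v0, V, alpha)
is not jointly identifiable from drift rates, so m0 = 1, V defaults to 1.1
(volume added per unit mass of accreted tissue, roughly the inverse
density of blubber) and is fixed, and v0 is calibrated from the median of
the first ten observations so that m0/v0 matches the seal's apparent
initial density; delta_k, alpha, both observation variances and p are
estimated.

Priors (all exposed in `BuoyancyModel`): log(−alpha) ~ N(log 1.5, 0.5²);
half-normal on the random-walk SD per √day (scale 0.2) and on the
in-trajectory observation SD (scale 0.1); the out-trajectory SD is the
in-trajectory SD plus a half-normal excess (scale 0.5), which enforces
tau_r_out > tau_r_in; p ~ Beta(9, 1) (after thresholding, most candidates
are genuine).  delta_1 ~ N(0, 1) weakly anchors the path start.

Inference marginalizes z_k analytically (two-component mixture
likelihood) and samples the rest by MCMC: vectorized odd–even single-site
Metropolis sweeps over the latent path plus a global shift move, and
per-coordinate adaptive random-walk Metropolis for the hyperparameters;
four chains run in lock-step as a batched array.  The path initializes at
the inverse-mapped rolling median of the observed rates — starting from a
flat path can trap the sampler in a mode where the in-component variance
inflates to cover the trajectory's slope.  P(z_k = 1) is the
Rao-Blackwellized average of the Bernoulli posterior over retained draws;
the reported mu_k is the posterior mean.  Convergence is gated on
split-R̂ < 1.05 of the identified functionals (mean buoyancy, p, both
observation variances); alpha and tau_delta are reported but not gated
because they are individually weakly identified whenever the trajectory
is nearly constant — a property of the model, not the sampler.
Non-converged fits are returned flagged with a warning, never silently.

Final drift dives are those with P(z_k = 1) strictly above 0.95; exactly
0.95 is rejected.  The accepted series carries the observed rates.

A calibration fact worth knowing: with ~10% contamination the posterior
soft-assigns tail inliers partially to the wide component, pulling p to
≈ 0.87 and the wide SD slightly below its generating value, which places
the P = 0.95 acceptance cut at ≈ 1.9 inlier standard deviations.  About
5–9% of *genuine* observations therefore fall below the cut even when the
model is exactly true — the filter is deliberately conservative, which is
also why retained dives keep their observed rather than smoothed rates.

## Synthetic trips

The generator emulates a tag's view of a foraging trip at 30-s sampling.
Defaults: 60 days × 50 dives/day; 6% drift dives; 5% drift mimics; 2.5%
shallow/short exploratory dives; the rest split between clean V-dives and
wiggly U-dives; daily buoyancy ramps from −0.3 m/s by +0.004 m/s per day
(custom schedules, including zero crossings, are supported).  Drift dives
descend at 1.5–2 m/s to 180–320 m and drift passively for 12–28 minutes
at the day's buoyancy plus per-dive jitter (SD 0.02 m/s) and 1 m depth
noise; active limbs carry mild rate changes (two features on the ascent of
sinking dives, on the descent of rising dives) because real swimming is
not metronomic — that contrast is what concentrates drift dives in the
eight candidate order groups, mirroring the field observation the grouping
stage relies on.  Phase boundaries are snapped to the sampling grid so the
knee samples exist exactly; real tags sample asynchronously, which would
add a small (< one sample interval) segment-endpoint bias.  Mimics share
the drift geometry but take their slope uniformly from ±0.6 m/s,
independent of the trajectory; they are the false positives the threshold
and trajectory stages must remove.  V-dives are exactly piecewise linear
(one depth extremum); their summaries trigger the zero-residual fill rule
and land outside the candidate groups, so they are rejected
deterministically at grouping.

What passing tests show: the pipeline's stages compose correctly, the
trajectory filter rejects off-trajectory rates, and daily series track a
known buoyancy signal.  What they do not show: performance on real
profiles with oceanographic noise, surface-detection error, asynchronous
sampling, or dive shapes outside the generator's repertoire; the default
threshold table's cell-level fidelity to the published criteria; or
absolute body-composition estimates (the model works in relative density
units by design).

## Problem sizes and numerical choices

End-to-end tests and the acceptance script use the 3000-dive default trip,
a 500-observation recovery study (4 chains, 2000 warmup + 2000 sampling
sweeps, thinned by 4) and a ~1100-dive summarize/recover round trip; each
runs in seconds to a few minutes on one CPU.  Tie tolerance in the
broken-stick algorithms is 10⁻⁹ m; duplicate candidate timestamps in the
trajectory filter are nudged by one second; degenerate geometry
(zero-duration segments) marks the variable set and the dive is rejected
with a trace rather than propagating NaNs.
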