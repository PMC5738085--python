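# Methods

This note documents the models, estimators and numerical conventions
implemented in `proximnet`, the parameters that matter, and what the
synthetic-study generator does and does not emulate.

## Study model and time grid

The package targets a small-cohort office study: participants carry a
smartphone app and a wearable badge, both performing Bluetooth discovery
scans, over several weeks of office hours (default Monday–Friday,
9 am–5 pm, four weeks). All analysis happens on a grid of half-open
5-minute bins covering office hours only; with the defaults that is
20 days × 96 bins = 1920 bins. Timestamps are stored UTC and converted
to the configured IANA timezone (default `Australia/Sydney`, the kind of
site the defaults describe) before office-hours masking, so logs from
any source can be pooled safely. The bin width must divide the office
day exactly; a 5-minute bin matches the app's scan schedule, making one
scheduled scan per device per bin.

## Activity reconstruction

Devices do not log when they are off; active periods are reconstructed
retrospectively from evidence of operation: a device's own scan events
(including scans that found nothing) and the instants it was detected by
others. Each evidence instant opens a window of width `activity_gap`
(default 15 min = three scheduled scan periods, tolerating two missed
scans) centred on the instant and clipped to its office day; a bin is
active iff it intersects the union of windows. The gap is a config
parameter rather than a constant because no single window rule is
canonical; 15 min is the default the rest of the documentation assumes.

Two consequences worth knowing. First, reconstruction is conservative
for sparse scanners: a device that scans once an hour is reconstructed
as active for at most ~25% of time even if its radio was on throughout,
because scan evidence is all the data model carries (there is no
telemetry side channel). Second, badges that scan every bin while worn
are reconstructed slightly *above* their wear fraction because each
evidence window covers three bins.

## Network estimation

Two weighting schemes produce symmetric, hollow, nonnegative matrices
over participants:

* **Scan-normalised strength** R_ij = (N_ij + N_ji)/(N_i + N_j), with
  R_ij = 0 when N_i + N_j = 0. Counts are accumulated at event level
  (scan occasions and detections), not bin level, because the definition
  is about scans. R_ij ∈ [0, 1] and is symmetric by construction.
* **Time fraction**: the share of analysed bins in which the dyad was
  detected by either device (proximity is undirected, so detections are
  OR-symmetrised per bin); 0 on an empty analysis mask.

Both accept a restriction of the analysis interval to the bins where
both of the dyad's devices were active, which separates missingness from
true absence of proximity. When every scan is a detection and both
devices scan once per bin, the two schemes coincide (a property the test
suite asserts on a constructed case).

The *sampling universe* for concordance — which dyad-bins enter the 2×2
table — is configurable: by default a dyad is "sampled" in a bin when at
least one of its devices emitted any scan event there (the most literal
reading of pooling over sampled time points), with `both_scanned` and
`all_bins` as alternatives. The published grand totals this package's
reference counts reproduce do not disambiguate the rule, which is why it
is exposed rather than fixed.

## Concordance statistics

From the pooled table (a, b, c, d): marginal odds are hits/misses per
modality expressed as a percentage (the only definition under which the
bundled reference counts give 2.92%/0.19% and 8.55%/1.28%); the odds
ratio is ad/bc; φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)) with the numerator
formed in exact integer arithmetic; χ² is the uncorrected Pearson
statistic, which satisfies χ² = Nφ² identically (asserted to 1e-9
relative in tests) — no continuity correction, because the reference
values are uncorrected. Sensitivity a/(a+c) and specificity d/(b+d)
treat the badge as the reference side, consistent with the badge being
the sparser, shorter-range observer. Undefined conditions (zero margins,
0/0 odds) raise a typed `UndefinedStatisticError` rather than returning
NaN, so pipelines fail loudly; a zero-denominator marginal odds returns
`inf` as an explicit infinite-odds signal.

## Network comparison

**Mantel test.** ρ is the Spearman correlation of the two upper-triangle
dyad vectors (ties mid-ranked). The permutation null applies a random
node relabeling to one matrix's rows and columns simultaneously — the
standard Mantel scheme — with a two-sided p-value and +1 correction,
p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(1 + n_perm), so p is never zero. The
95% CI is a percentile bootstrap over dyads resampled with replacement;
whether the original analyses bootstrapped dyads or nodes is not
knowable, so the choice is documented here as this package's convention.
Degenerate (zero-variance) bootstrap draws are skipped.

**Survey collapse.** Name-generator nominations (up to five alters per
ego) give a directed binary network; it is collapsed to undirected by
edge-wise OR.

**Disparity-filter backbone.** For a node of degree k ≥ 2 and strength
s, an edge of weight w has significance α = (1 − w/s)^(k−1), the closed
form of the defining integral 1 − (k−1)∫₀^p (1−x)^(k−2)dx at p = w/s
(matched to 1e-10 by numerical integration in tests). Degree-1 nodes get
α = 1 by convention, so isolated spokes are never automatically
significant. An edge's significance is the minimum over its two
endpoints (kept if significant from either side). The significance level
is swept over the sorted distinct edge alphas to the level whose
retained-edge density is closest to the target (the survey network's
density); ties keep fewer edges, and the achieved density is reported
since the exact target may be unattainable.

## Scan-rate bias resampling

For each required sample count m, participants whose app recorded at
least m scan occasions are retained; for each replicate a uniform random
subset of m occasions per participant (without replacement — a subset of
real scans) is drawn, the network is rebuilt, and Spearman ρ against the
badge and survey networks (restricted to retained nodes) is recorded.
The curve reports the median and a 99% percentile band (0.5–99.5) across
replicates. Rebuilding uses the scan-normalised weighting: it normalises
per occasion, which is exactly the confound fixed-m subsampling is
designed to remove. Because only the app is resampled, ρ(badge, survey)
at fixed m depends only on the retained node set — an invariance the
tests assert. The per-replicate rebuild uses a vectorised
occasion-sampling path proven equal to the event-level estimator by a
replay test.

## Synthetic-study generator

Ground truth is a per-dyad set of co-location *sessions*: counts drawn
from a Poisson process at `session_rate_per_hour` (default 0.2/h)
thinned by a per-dyad Gamma(0.6, mean 1) affinity, uniform starts over
office time, exponential durations (mean 20 min) clipped to the office
day, and a uniform representative distance in 0.5–12 m. Distance enters
only through range thresholds (app 10 m, badge 5 m), the minimal
structure the analysis distinguishes; sessions between the two ranges
are what makes the app's process denser than the badge's, alongside the
badge's much lower wear compliance. These defaults put the pooled
in-range fraction near 7% of dyad-bins and the app's pooled marginal
odds in the low percent range — the sparsity regime the estimators are
meant for.

Observation: each device gets an alternating on/off exponential renewal
process (mean cycle 4 h) matched to its modality's active fraction
(app 0.791 ± 0.222, badge 0.370 ± 0.184, truncated normals). Apps scan
on the 5-minute grid while on, with a per-slot probability calibrated so
the realized office-hour rate equals a per-device draw from the
OS-stratified truncated normal (Android 5.6 ± 3.8/h, iOS 1.1 ± 0.8/h,
floored at 0.1/h and capped at the scheduled 12/h); when a draw exceeds
what the drawn active fraction permits, the active fraction is raised to
match — fast scanners are necessarily highly active. Badges scan every
slot while worn. A scan detects a partner iff the dyad is in range for
the modality, the partner's device is on, and a Bernoulli (default 0.8
per modality) succeeds; scans that find nothing are emitted as empty
events, which matters for activity reconstruction and scan counting.
Everything is deterministic given `rng_seed`; app, badge and co-location
streams use independently derived child generators.

What the generator does *not* emulate: radio propagation and RSSI,
non-participant background devices, day-structure in wear compliance
(badges forgotten on whole days), correlated session behaviour (meetings
involving three or more people are independent dyad sessions here), and
survey subjectivity — synthetic surveys are the exact top-5 partners by
in-range time with lexicographic tie-breaks. Passing tests therefore
show that the estimators recover the structure of a process with the
configured sparsity, rates and missingness; they do not certify
behaviour under the social and radio complexities of real deployments.

## Problem sizes and numerical conventions

The default end-to-end configuration analyses the full 21-participant,
four-week grid (1920 bins, 210 dyads); the bundled demo pipeline runs it
with 1000 Mantel permutations, 500 bootstrap draws and 100 resampling
replicates in a few seconds, and the test suite scales replicate counts
(20 generator replicates for calibration and recovery, 200 Mantel
calibration runs, 200–500 resampling replicates) to keep the whole suite
around a minute. Networks are written to CSV at 17 significant digits
and parsed with the round-trip float parser, so write/read is lossless;
permutation counts use a tolerance of 1e-12 on |ρ| comparisons to make
tie handling deterministic across platforms; matrices are exactly
symmetrised (w ← (w + wᵀ)/2) after validation at 1e-12 tolerance.

## Known limitations

* The concordance sampling-universe rule is a modelling choice (see
  above); results at the margins depend on it.
* Activity reconstruction underestimates uptime for sparse scanners and
  slightly overestimates wear for dense scanners, as described.
* The disparity filter is computed per-edge in a Python loop — fine for
  hundreds of nodes, not tuned for large graphs.
* Bootstrap CIs over dyads ignore the dependence among dyads sharing a
  node; they are honest about Monte-Carlo error, not network dependence.
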