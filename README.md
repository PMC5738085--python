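# proximnet

Estimation and cross-validation of social networks of physical proximity
from Bluetooth discovery-scan logs.

## The problem

Passive sensing is an attractive alternative to self-report surveys for
mapping who spends time near whom: smartphones and wearable sociometric
badges can both log Bluetooth discovery scans, and a detection of one
participant's device by another's implies the pair was within radio range
(roughly 5–10 m). But each observer is imperfect in its own way — apps are
throttled by the operating system (Android scans far more often than iOS),
badges are only worn intermittently and appear to have a shorter detection
range — so the networks estimated from different modalities must be
cross-validated against each other and against name-generator surveys
before they can be trusted. `proximnet` implements that validation
pipeline for researchers working with timestamped scan logs from small
cohorts (tens of participants over weeks of office hours).

## What it computes

**Weighted networks.** For a dyad {i, j} over an analysis interval *T*,
the scan-normalised connection strength is

&nbsp;&nbsp;&nbsp;&nbsp;*R*<sub>ij</sub> = (*N*<sub>ij</sub> + *N*<sub>ji</sub>) / (*N*<sub>i</sub> + *N*<sub>j</sub>) ,

where *N*<sub>ij</sub> is the number of scans in which device *i* detected
device *j* and *N*<sub>i</sub> the number of scans *i* made during *T*;
*R*<sub>ij</sub> = 0 when neither device scanned. The alternative
`time_fraction` weight is the share of 5-minute office-hour bins in which
the dyad was detected at all. Either weighting can be restricted to the
bins where both devices of the dyad were active (activity is
reconstructed retrospectively from scan evidence).

**Pooled concordance.** Dyad-bin detections from two modalities are
cross-classified into one 2×2 table summarised by the phi coefficient
φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)), the odds ratio, marginal odds
(hits/misses per modality, as a percentage) and the uncorrected Pearson
χ² = *N*φ² with 1 df.

**Network comparison.** Mantel tests (Spearman ρ of the dyad weight
vectors, permutation p by simultaneous row/column relabeling, bootstrap
percentile CI over dyads), binary backbones via the disparity filter
(edge significance α = (1 − w/s)<sup>k−1</sup> from each endpoint, swept
to match the survey network's density), and edge-overlap counts.

**Scan-rate bias.** The app network is rebuilt from a fixed number *m* of
random scan occasions per participant and correlated against the badge
and survey networks as *m* grows — separating sampling effort from true
disagreement between modalities.

A synthetic-study generator (`proximnet.simulate`) produces ground-truth
co-location with app-like and badge-like observers at the study
conditions the package targets (21 participants, Android 5.6 vs iOS 1.1
scans/h, app ~79% vs badge ~37% active, badge range < app range), so the
whole pipeline is testable without access to raw participant data.

## Worked example

```sh
proximnet run -c src/proximnet/data/demo_config.yaml --out demo-out
```

simulates a four-week, 21-participant study and runs the full analysis.
The command prints the pooled office-hours concordance of the two
modalities, e.g. (seed 1):

```json
{
  "counts": {"a": 412, "b": 6821, "c": 382, "d": 204569},
  "n": 212184,
  "phi": 0.1637427282319807,
  "chi_square": 5689.009731669673,
  "odds_ratio": 32.34637564466373,
  "marginal_odds_pct_A": 3.529136232562905,
  "marginal_odds_pct_B": 0.3756090638156961,
  ...
}
```

Read: the app detected a dyad in about 3.5% of its sampled dyad-bins and
the badge in about 0.4% — physical proximity is sparse, and the badge
much sparser than the app — yet the two observers agree far beyond chance
(φ = 0.16, χ² = N·φ² ≈ 5.7×10³). `demo-out/report.json` additionally
contains the Mantel comparisons (here ρ(app, badge) = 0.66), backbone
densities, edge overlaps and the resampling curve, whose app–badge
correlation rises with the per-participant sample count (0.50 at m = 10
to 0.77 at m = 500 under this seed) as scan-rate noise averages out.

The printed-table entry point recomputes all concordance statistics from
the four cell counts of a pooled 2×2 table alone:

```sh
proximnet reproduce-tables          # bundled reference counts
proximnet reproduce-tables -c my_counts.csv
```

With the bundled reference counts this yields φ = 0.10, χ² = 2.5×10³ and
marginal odds 2.92% / 0.19% over all office hours, and φ = 0.17,
χ² = 8.7×10², odds 8.55% / 1.28%, odds ratio 11.22 when restricted to
both-devices-active intervals.

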