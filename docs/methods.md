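# Methods

## The prediction problem

Each reef site contributes one binary outcome per calendar year: did mass
bleaching occur? The predictor is accumulated heat stress derived from daily
SST, thresholded to give a yes/no forecast, so that every site-year falls into
one cell of a 2×2 contingency table — hits (H), false alarms (FA), misses (M),
correct negatives (CN). All skill metrics are exact functions of those four
integers; the package computes them from integer-cleared ratios (e.g.
`ETS = (H·n − (H+FA)(H+M)) / ((H+FA+M)·n − (H+FA)(H+M))`) so "denominator is
zero" is an exact integer test, and any metric whose denominator vanishes is a
typed undefined value (`None`), never a NaN that could poison a grid search.

## Heat-stress metrics

* **Climatology / MMM.** Monthly means are two-stage (days → month-of-year,
  month-years → climatological month), which is unbiased under missing days;
  the MMM is the maximum of the twelve monthly means. The baseline is a
  parameter (default 1982–2012). No operational recentering or sensor-bias
  adjustment is applied. A calendar month with zero baseline observations is a
  coverage error naming the month; there is no gap-filling.
* **DHW.** `DHW(t) = (1/7)·Σ a(d)·1[a(d) ≥ c]` over the trailing `7w` days.
  A day at or exactly on the cutoff contributes its **full** anomaly
  (operational convention), so the cutoff experiment is a pure change of `c`
  and saturates at exactly `a·w` for constant anomaly `a ≥ c`. Days before the
  series start contribute zero. Defaults: `w = 9`, `c = 0` (the best-verifying
  variant); the heritage configuration is `w = 12`, `c = 1`.
* **Annual maxima** are taken over the calendar year (the observation table is
  keyed by year). Southern-hemisphere summers straddle the year boundary; a
  February-peaking event is assigned to its calendar year. This is a stated
  convention, not a claim about how any particular database was built.
* **Neighborhood rule.** For gridded SST the site's annual value is the
  maximum over the nearest grid cell (great-circle distance to cell centers)
  and its 8-connected neighbors, ignoring missing (land) cells; an all-missing
  neighborhood is an error.
* **Marine heatwaves.** Standard definition: day-of-year 90th-percentile
  threshold pooled over an 11-day window across baseline years, threshold and
  mean climatology smoothed with a 31-day circular moving average, events are
  ≥5 consecutive days above threshold, gaps ≤2 days merged. Feb 29 shares
  Feb 28's climatology slot. Only the annual maximum intensity (SST minus the
  day-of-year mean) is exposed; categories/duration metrics are out of scope.

## Threshold optimization

All comparisons are inclusive (`≥`), and ETS ties break toward the smallest
threshold (more warnings), then the smallest second-axis value — deterministic
and sensitivity-favoring. Grids: θ ∈ 1–15 °C-weeks step 0.1 (the resolution at
which optima like 5.4 are quoted), El Niño threshold e ∈ −1.0–3.5 °C step
0.05, trend slope s ∈ −0.2–0.2 °C-weeks/yr step 0.005, anchored at 1999 (the
fitted threshold is the 1999 value; the effective threshold in year y is
θ + s·(y − 1999)).

The El Niño term combines with DHW by **conjunction** (predict bleaching only
if DHW ≥ θ *and* annual-max Niño3.4 ≥ e): a conjunctive rule is the only
combination that can lower the frequency Bias when the second predictor is
added, which is the observed direction, and it makes "adding e never raises
Bias at fixed θ" a provable invariant of the implementation. The annual El
Niño predictor is the maximum monthly index within the calendar year.

The top-2% mask of a bivariate ETS surface marks cells at or above the 98th
percentile of *defined* ETS cells. The trend-null diagnostic asks whether any
top-2% cell lies in the s = 0 column: if yes, a constant threshold is
statistically indistinguishable from the best trending one at this
granularity.

`severe_only` scope relabels moderate site-years as non-events rather than
dropping them, keeping n fixed across scopes. Regions with zero observed
events get an undefined regional threshold and are excluded from the pooled
report (predicted as non-events); optimization fails only if every region is
undefined. The annual-ETS trend is tested with an ordinary least-squares
two-sided slope test; an exactly constant annual series is reported as slope
0, p = 1.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a global bleaching-verification
study — 100 heterogeneous reef sites observed annually over 1982–2016
(n = 3,500) — not any real site's series.

* **SST**: seasonal sinusoid (365.25-day period, amplitude 1–3.5 °C, peak
  mid-August north / mid-February south), linear warming trend
  (0.05–0.35 °C/decade), ENSO coupling (−0.3–1.2 °C per °C of Niño3.4,
  monthly index linearly interpolated to days) and AR(1) daily noise
  (sd 0.25–0.5 °C, lag-1 0.75–0.92, initialized at stationarity). Sites are
  conditionally independent given the ENSO index; real spatial covariance,
  satellite gaps and retrieval error are deliberately absent.
* **ENSO index**: one Gaussian winter excursion per year (σ = 1 month,
  centered on December), amplitude 2.5 °C in event years and U(0, 1.2) °C
  otherwise, plus monthly noise (sd 0.1 °C). The continuous background
  amplitude spectrum is what makes a generative El Niño gate identifiable:
  neutral years approach the gate from below, pinning the optimal e.
* **Labels**: severity from the site-year maximum DHW (moderate at
  `theta_true = 5.4` °C-weeks, severe at 8.0, both computed with the same
  window/cutoff used downstream), optionally gated on annual-max Niño and/or
  drifting linearly in time. Label noise flips none↔moderate only — severe
  events are never fabricated — and is a free knob, not an estimate of real
  observation error.
* **Product ensemble**: six products sharing one latent global-anomaly series
  (0.015 °C/yr trend + AR(1) interannual variability, sd 0.08 °C) with small
  independent per-product noise (sd 0.005 °C) and one product receiving a
  −0.05 °C mid-record bias band. The noise is kept well below the injected
  bias so the non-outlier products cluster tightly, mirroring an ensemble in
  which one product's drift is the dominant disagreement.

Because labels are generated *from the same stress table* the optimizer later
sees, noise-free truth is exactly separable (ETS = 1 at the generative
parameters). Passing recovery tests therefore demonstrates correctness of the
optimization machinery, not real-world predictive skill; real data add label
error, predictor error, and scale mismatch that the generator only partially
emulates.

One emergent caveat worth knowing: with a warming trend in SST the true event
rate rises through the record, and uniform label noise then induces a genuine
upward drift in *annual* ETS (early low-base-rate years are dominated by
flipped labels). A significant ETS trend in such diagnostics does not by
itself imply a time-varying bleaching threshold.

## Scenario sizes and numerical choices

Chosen once as the package's study conditions:

* Threshold recovery: default fixture (100 sites × 1982–2016), noise-free and
  with 5% label noise over 20 relabeled replicates (the stress table is fixed;
  only labels are redrawn).
* El Niño gate recovery: 60 sites × 1952–2016 (the longer ENSO record
  populates the amplitude spectrum near the gate), gate 0.8 °C, e-grid step
  0.1 for the surface so the argmax localizes the gate to within one step for
  any seed.
* Trend null: default fixture; trended truth uses slope 0.15 °C-weeks/yr on
  the same stress table.
* Metric oracle: 1,000 uniform random contingency tables of n = 3,500
  (stars-and-bars sampling, exactly uniform over compositions), agreement
  tolerance 1e−12.

Floating-point policy: contingency counts are exact integers; metrics are
single divisions of exact integer products, so equal counts give bitwise-equal
scores and plateau ties are exact. Quantiles for the top-2% mask use numpy's
default linear interpolation. Noise-free template checks use 1e−9 °C
tolerances; the MHW square-pulse intensity check allows 0.1 °C for smoothing
distortion.

## Known limitations

* No confidence intervals on skill scores, and no probabilistic forecasts
  (ROC over continuous scores is outside the framework).
* Gridded I/O uses xarray with the scipy NetCDF3 engine; heavyweight formats
  are otherwise avoided in favor of CSV.
* The regional pooled-ETS ≥ global-ETS relation is a property of separable
  synthetic truth, not a theorem; with noisy labels, independently optimized
  regional thresholds can in principle pool worse than a single global one.
* Calendar-year event assignment penalizes predictors at Southern-hemisphere
  sites whose thermal summer straddles the year boundary when labels were
  assigned differently.
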