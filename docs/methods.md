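# Methods

## The soft-sensor problem

A buoy logs water temperature, electrical conductivity (EC), pH, system
battery voltage and chlorophyll-a (Chl-a) fluorescence every 15 minutes.
Chl-a is the expensive channel; the other four are cheap and robust. The
package treats Chl-a inference as supervised regression: learn
ŷ = f(temperature, EC, pH, battery) from a period where a fluorometer was
present, then run f where one is not (or as a backup when one fails). The
monitored quantity feeds a binary alarm: WHO alert level 1 corresponds to
Chl-a above 10 µg/L.

The physical rationale for each input: photosynthesis consumes dissolved
CO₂, so dense algal/cyanobacterial growth drives surface pH alkaline; many
bloom formers grow fastest in warm water, so temperature carries seasonal and
diel information; EC responds to rainfall dilution and drought concentration,
both tied to the mixing/stratification cycle that modulates blooms; and the
solar-charged battery's depth of discharge encodes day length and cloud
cover — a free seasonal clock.

## Cleaning

Each variable has configured physical limits [lo, hi]. With span s = hi − lo
and tolerance τ (default 0.05), a value in (hi, hi + τ·s] or [lo − τ·s, lo)
is snapped to the nearest boundary — small excursions are typical of
calibration drift and the sample is otherwise informative. A row holding a
value beyond the τ-band, or a missing value in any channel, is removed whole:
a sensor that far out of range taints the entire record. The rule is
idempotent and preserves the order and timestamps of kept rows.

The shipped limits (pH [0, 14]; temperature [−5, 50] °C; EC [0, 2000] µS/cm;
battery [0, 20] V; Chl-a [0, 500] µg/L) are plausible instrument envelopes,
not normative values; both the limits and τ are configuration. The band is
defined on the span rather than on each limit value because a fractional
band of a zero lower limit would be empty.

## Feature and target aggregation

Trailing windows are time-based intervals (t − W, t], not fixed row counts:
cleaning removes rows, so a row-count window would silently change duration
across gaps. Partial windows (series start, after a gap) use whatever ≥ 1
samples are present rather than being dropped; the window statistic of a
single sample is the sample itself with std 0. Windows never cross buoys.
Output aggregation is likewise trailing — a centered window would leak
future Chl-a into the target the soft-sensor is supposed to predict now.

Augmented columns are named `{Variable}_{window}_{stat}` (e.g. `pH_day_max`,
`Temperature_day_min`, `SystemBattery_day_min`), which is also the naming
used by the shipped 3-AGG/5-AGG importance subsets. The 4 input variants and
5 output variants combine into a 20-cell experiment grid.

## Normalization

Inputs are passed through a per-column Yeo-Johnson power transform followed
by standardization to zero mean, unit deviation. Yeo-Johnson is chosen over
Box-Cox because it is defined for non-positive values (sub-zero temperature,
anomalous battery readings); its identity point is λ = 1. The target is left
in µg/L so MAE keeps physical units and alarm thresholds stay interpretable.
The transform is fitted on each fold's training chunks only and applied
frozen to validation rows; a zero-variance column gets scale 1 with a
warning. Tree models do not need the transform, but applying it uniformly
keeps every family's training pipeline identical, and it does not harm them.

## Temporal validation

Random splits overstate performance on strongly autocorrelated series, so
the time-sorted (buoy-pooled, buoy-tagged) dataset is cut into K = 10
contiguous chunks whose sizes differ by at most one row; nothing is ever
shuffled. A hyperparameter configuration is evaluated as K models, each
trained on K − 1 chunks and validated on the held-out chunk; its score is
the mean of the K validation MAEs, and ties go to the simpler configuration
(fewer estimators, then smaller depth, then smaller L2, then sampling
order) for deterministic leaderboards. Random search draws 25 configurations
per family by default: the ridge L2 coefficient log-uniform on [10⁻⁴, 1]
(the range spans four decades), tree depth uniform on [1, 500], forest size
uniform on [2, 200]. A full grid run therefore schedules
20 variants × 25 configs × 3 families × 10 folds = 15,000 model fits.

Assembling each row's prediction from the fold that held it out yields a
full-coverage out-of-fold series; with a three-year record, grouping it by
calendar month pools three occurrences of every month, which is the point of
the design — single-final-year testing would see each month once. The
alternative reading, holding out one chunk as a final test set, is a
one-line variant of the same plan and is not the default.

Alarm truth labels use the same output variant as the regression target, so
each aggregation experiment is judged self-consistently; the alarm
comparison is strictly ">" by default with an inclusive "≥" switch.

## Models

Ridge regression, CART (unpruned, depth-capped, squared-error splits,
leaf-mean predictions, minimum leaf size 1) and a random forest (bootstrap
bags, per-split feature subsets of one third of the features — the
regression convention — prediction by averaging) are delegated to
scikit-learn; the baseline predicts the training-target mean. Every
stochastic fit takes an explicit seed derived from the run seed. Forest
importance is normalized mean impurity decrease, reported next to each
feature's Pearson correlation with the target so linear and nonlinear views
can be compared; correlated features share importance, so shares are read
comparatively, not causally.

## Synthetic reservoir generator

The generator emulates the statistical structure the pipeline exploits, per
buoy profile ("beach": shallow, noisier; "dam": deeper, larger diel Chl-a
swing via vertical migration of buoyant cyanobacteria):

- latent Chl-a = (winter baseline + seasonal Gaussian envelope peaking near
  day-of-year 248 × seeded log-normal bloom pulses, ~4 per summer, days-long
  — blooms are ephemeral and patchy) × a diel migration factor;
- pH = base + 0.55·log1p(latent Chl-a) + diel sinusoid + noise, clipped to
  [0, 14]; the saturating log-link keeps pH physical at bloom peaks;
- temperature = seasonal + diel sinusoids + AR(1) noise (5–29 °C);
- EC = baseline + drought-season drift − exponential rain-event drops
  (Poisson-seeded) + noise;
- battery = solar charge integrated over a seasonal daylight profile minus a
  constant drain, clipped to [12.6, 14.6] V — full by late morning, sawtooth
  overnight;
- measured Chl-a = latent + noise + rare positive log-normal fluorometer
  spikes (debris misdetections, rate 0.4%).

Defaults produce one year of 35,040 samples per buoy with summary statistics
in the range of a monitored eutrophic reservoir. Artifact injection plants,
on disjoint rows, values just inside the snap band, values beyond it, and
missing values; default rates (2% snap, 2% beyond, 3% missing) make cleaning
remove ≈5% of rows. What the generator does *not* model: hydrodynamics,
nutrient cycling, thermocline physics, sensor drift, or cross-variable noise
correlation. Passing tests therefore demonstrate that the pipeline recovers
*planted* structure under realistic noise — not field accuracy on any real
reservoir, whose dynamics are richer and whose couplings are weaker.

## Problem sizes and numerical choices

Property tests that train models use one synthetic year, one buoy, K = 5 and
at most three configurations per family — enough to separate the families
by an order of magnitude more than fold-to-fold scatter, as the package's
standard reduced-budget check; the full 15,000-fit schedule is verified
combinatorially. Chunk boundaries come from rounding a linear spacing, so
sizes differ by ≤ 1 row. Undefined metrics are reported as NaN (precision or
recall with empty denominator; MAE/STD of a constant group) with F1 defined
as 0 in those cases, keeping report tables machine-comparable. Degenerate
fits (single-row CART, constant columns) are handled, not errors.

## Known limitations

- Importance shares from impurity decrease are biased toward high-cardinality
  continuous features and split among correlated ones; permutation importance
  is not implemented.
- The generator's couplings are stronger and cleaner than field data; MAE/F1
  magnitudes on synthetic data say nothing quantitative about a real
  deployment.
- No gap imputation, sensor-drift correction, or level-2 (50 µg/L) alarm
  modelling; rare extreme values are exactly the regime where mean-based
  regressors underperform.
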