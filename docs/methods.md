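# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Set-point estimation (`vipertherm.tset`)

Each individual's gradient-trial readings are taken as draws from its
preferred-temperature distribution.  The estimator fits a Gaussian kernel
density with the Silverman-type rule-of-thumb bandwidth
0.9 · min(SD, IQR/1.34) · n^(−1/5) (the default of the common statistical
environments, chosen for reproducibility of the standard workflow),
rescales the curve so its maximum is 1, and evaluates it on a fixed grid
from 15 to 45 °C in 0.05 °C steps (601 points).  *T*<sub>p</sub> is the
grid temperature at the (first) maximum; the set-point bounds are the
smallest and largest grid temperatures at which the curve is ≥ 0.5.  Two
readings of the field literature coexist — a central-50% (interquartile)
range and the half-maximum crossing rule; the half-maximum rule is primary
here because it is what the grid read-out operationalizes, and the
interquartile variant is available via `method="iqr"`.

Numerical details: ties at the maximum break to the lowest temperature;
on a multimodal curve the bounds are the outermost crossings, so they
bracket all modes; readings outside the grid are clipped onto it with a
warning, and estimates whose half-maximum region touches a grid edge carry
a `clipped` flag; series with fewer than 5 readings or zero variance are
rejected.  Population-level estimates pool all readings of the population
into one series before estimation (the natural alternative — combining
individual bounds by min/max — is noted but not implemented).

Consequences measured by the test suite: the full width at half maximum of
a large-sample Gaussian (σ = 3) is recovered as ≈ 7.06 °C
(2·√(2 ln 2)·σ); a constant shift of all readings moves every output by
that constant up to the 0.05 °C grid; over 200 synthetic individuals with
2 °C within-individual noise the mean bias of *T*<sub>p</sub> is below
0.2 °C.

## Thermoregulation indices (`vipertherm.indices`)

The deviation of a temperature from the set-point range is 0 inside the
range, (t − upper) above and (lower − t) below — the standard Hertz
convention.  *d*<sub>b</sub> pools all spot records of a population
(per-individual averaging first is available behind a flag);
*d*<sub>e</sub> pools all operative series of the population restricted to
the diurnal window [06:00, 20:00), inclusive start, exclusive end.
Confidence intervals are percentile bootstrap over records (default 10,000
resamples, seeded) and are not clipped at zero, so a near-zero mean can
show a negative lower bound; with identical deviations the interval has
zero width.

*E* = 1 − *d*<sub>b</sub>/*d*<sub>e</sub> is undefined in a thermally
ideal habitat (*d*<sub>e</sub> = 0) and raises rather than returning a
sentinel.  For the exploitation index the "corresponding" operative
reading of a spot record is the nearest-in-time reading within ±2.5 min
(half the 5-min logger cadence) in each microhabitat series; the operative
environment overlaps the set-point range if at least one of the sun/shade
readings at that time lies inside it.  The ratio is not clamped: values
above 1 mean animals hold target temperatures more often than the
operative environment offers them, which is the expected signature of
active thermoregulation (basking) and is demonstrated by a hand-enumerated
fixture with *E*<sub>x</sub> = 3.  The population-level set-point range
enters all indices.  A population with operative series but no
body-temperature records reports *d*<sub>e</sub> only, with the other
indices flagged missing rather than zero.

## Annual restriction budget (`vipertherm.budget`)

The full coupled microclimate + ectotherm energy-balance machinery is
deliberately out of scope.  The hourly operative-temperature synthesizer
is a documented simplification that preserves the accounting and the
scenario logic: daily means are linearly interpolated between month
midpoints on a 365-day year (December wrapping to January, no leap day); a
sinusoidal diurnal cycle with configurable half-amplitude (default 8 °C)
peaks at 14:00; a radiative gain (default 6 °C) is added during daylight
(06:00–20:00), standing in for the solar load on an exposed animal model —
a 33.5 g, non-thermoregulating ("dead") cylinder.  The annual mean of the
series therefore equals the mean interpolated daily mean plus
gain × 14/24, which the tests verify by brute-force averaging.

*h*<sub>r</sub> counts hours strictly above the upper set-point bound
(ties are not restriction).  Warming offsets enter additively through the
monthly means, so *h*<sub>r</sub> is non-decreasing under any non-negative
offset and non-increasing in the threshold; restriction and
non-restriction hours always sum to 8760.  Per SSP scenario, the three
GCM series are averaged per cell with equal weights before differencing
against the current climate.  Which upper bound to use is genuinely open
(the synthetic grid has no population–cell mapping), so the cross-population
mean upper bound is applied to all cells; a per-population threshold can be
passed as a mapping.  Absolute *h*<sub>r</sub> magnitudes from this
synthesizer are not comparable to a full biophysical model — the package's
claims about *h*<sub>r</sub> are structural (ordering, trends, contrast
significance), not absolute.

## Phylogenetic signal (`vipertherm.phylosignal`)

Topology-only trees get Grafen branch lengths (node height = descendant
tips − 1, rescaled to unit root-to-tip depth), giving an ultrametric tree.
The Brownian covariance C has shared root-to-MRCA path lengths off the
diagonal and tip depths on it.  Blomberg's K uses the phylogenetic GLS
mean and the expected MSE ratio [tr(C) − n/(1ᵀC⁻¹1)]/(n − 1); on a star
tree K = 1 identically, and under Brownian simulation its mean is ≈ 1.
Its p-value permutes trait values across tips,
p = (1 + #{K≥K_obs})/(n_perm + 1).  Pagel's λ multiplies the off-diagonal
covariances; the profile log-likelihood (mean and rate analytically
maximized) is optimized over [0, λ_max] where λ_max = max tip depth /
deepest internal node height keeps C(λ) positive definite — deliberately
not capped at 1, since shallow internal nodes make λ > 1 admissible.  The
optimizer is a 51-point coarse grid plus bounded refinement, and matches a
0.001-step grid search within 0.01.  Significance is a likelihood-ratio
test of λ̂ against λ = 0 on χ²₁ (the alternative reference point λ = 1 is
noted but not used); λ̂ = 0 yields p = 1 by construction.  Because the
null λ = 0 sits on the boundary, the χ²₁ reference is conservative: the
measured type-I error at nominal 5% is ≈ 2–4%.

With only five populations both tests are nearly powerless; the
calibration checks therefore run on larger simulated trees (5–64 tips),
and the five-tip result should be read as descriptive.

## Population statistics (`vipertherm.popstats`)

OLS fits delegate to statsmodels; the Wilcoxon rank-sum delegates to
scipy's Mann–Whitney implementation with the count-of-wins statistic,
enumerated exactly for tie-free samples with m·n ≤ 400 and otherwise
normal-approximated with continuity and tie corrections (the two branches
agree within 0.01 on samples near the threshold).  Pairwise population
contrasts use pooled-variance t statistics from the one-factor linear
model with Holm adjustment by default — conservative and
dependency-free — with Bonferroni as the documented single-step stand-in.
Sex enters linear models coded 0 = male, 1 = female.

## Synthetic data (`vipertherm.synthgen`)

The generator encodes the study conditions: five populations on a
latitudinal gradient with 19/5/31/3/15 individuals, population-mean
preferred temperatures spanning ≈ 26.8–30.3 °C around a ≈ 28.8 °C grand
mean, a female-only size effect of 0.02 °C/mm on the latent preferred
temperature, hourly gradient readings 06:00–18:00 (13 per individual)
drawn truncated-normal (15–45 °C) around the latent value, paired sun/shade
operative series at 5-min cadence (sinusoid peaking at 14:00, sun amplitude
12 °C > shade 6 °C, AR(1) noise with coefficient 0.8), spot records during
06:00–20:00 held within ±1.5 °C of the latent preferred value except for a
5% early-morning "cold" fraction (animals at the start of morning basking),
a 102-cell climate grid with a July-peaking seasonal cycle and a negative
latitude trend, warming offsets near +1.8 °C (optimistic) and +4.5 °C
(pessimistic) with small between-GCM spread, and a five-tip tree with the
southern population sister to the northern clade.  The within/between
individual SDs (2.0/1.2 °C), operative-series parameters and climate
baseline are generator defaults chosen as field-realistic values and are
documented config, since individual-level distributions are not part of
the published record.

What it does not emulate: geography (latitude is a scalar, no rasters or
coordinates), capture probability, seasonal phenology, microhabitat choice
beyond the sun/shade pair, and any biophysical heat exchange.  Passing
tests therefore demonstrate that the estimators and accounting are correct
and that configured effects are recovered at realistic sample sizes — not
that the generator reproduces field data.

All randomness derives from a single root seed split into fixed per-stage
streams; reruns under one seed are byte-identical, which the test suite
checks on the full pipeline.  Timestamps are timezone-naive local clock
time; temperatures are °C floats throughout.

## Problem sizes

The shipped analysis and checks use the study-scale defaults: 73
individuals, 13 readings each, 3 logger days, 102 climate cells, 10,000
bootstrap resamples, 999 permutations; estimator-calibration simulations
use 200–1000 replicates and 5–64-tip trees.  The whole suite and the
acceptance script each run in well under a minute on a laptop-class CPU.
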