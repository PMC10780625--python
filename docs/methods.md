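# Methods

`dendrostand` implements the computational chain used in dendroecological
studies of multi-aged stands: spatial point-pattern statistics on a mapped
circular plot, tree-ring chronology construction with screening and
age correction, and bootstrap orthogonalized response functions of ring
growth on monthly climate.  This note documents the models, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Spatial statistics

**Estimator.** For a pattern of n stems in a circular window of area
A = πR², Ripley's K is the plain cumulative ordered-pair count

    K(d) = A · Σ_{i≠j} 1[dist(i,j) ≤ d] / n²,

evaluated on the closed grid {step, 2·step, …, d_max} (default 1 m steps to
d_max = R, half the plot diameter, the conventional cap limiting edge
effects).  Ties at exactly d count as within d.  No edge-correction weight
is applied by default: because the identical statistic is computed for the
observed pattern and for every Monte Carlo null realization, the
envelope test remains valid; the uncorrected K is simply biased low near
the boundary for both.  An isotropic correction for the circular window
(reciprocal of the fraction of each pair-circle inside the disc) is
available via `edge_correction="isotropic"` for users who want unbiased
K values; it is exact for a disc.  Besag's variance-stabilizing transform
L(d) = √(K(d)/π) − d is zero in expectation under complete spatial
randomness (CSR).

**Envelopes.** Significance is assessed pointwise against n_sims (default
99) simulations at level 0.95: for the univariate test, CSR patterns with
the same n and window; for the bivariate test, null realizations that
keep each group's internal structure and randomize only relative
placement.  A toroidal shift — the standard bivariate null on rectangular
windows — is undefined on a disc, so the null here is a random rigid
rotation of the second group about the plot centre, with a mirror
reflection in half of the simulations.  Rotations preserve each point's
distance to the centre and hence the window; they randomize relative
orientation but not relative radial position, which is the price of the
circular window (a pattern where both groups share a strong radial trend
would be treated as partially "structure" rather than "association").

Envelope bounds are the pointwise (1−level)/2 and 1−(1−level)/2 empirical
quantiles computed with Weibull plotting positions (`np.quantile(...,
method="weibull")`).  With 99 simulations this places the bounds between
the 2nd/3rd and 97th/98th order statistics, giving a fresh CSR draw a
~2.5% exceedance probability per side — i.e. an honest ~5% pointwise
two-sided test.  Min/max envelopes of 99 simulations would give a 2%
test, and the default linear interpolation ~7%; both were rejected on
this order-statistics argument.  The test is pointwise, not simultaneous:
scanning all 40 distances inflates the family-wise rate, exactly as in
the software this mirrors, so classifications should be read
distance-by-distance.

**Bivariate statistic.** Directed cross counts K̂12 (group-1 points to
group-2 neighbours, denominator n₁n₂) and K̂21 are combined as
K12 = (n₂K̂12 + n₁K̂21)/(n₁+n₂), which is exactly symmetric in the two
groups; L12 applies the same transform.  Above/below/inside the envelope
maps to attraction/repulsion/independence.

**Degenerate input.** Patterns with n ≤ 1 return K ≡ 0 with a
`degenerate` flag and a warning rather than raising, so batch runs over
sparse classes proceed; no classification is produced.

## Tree-ring chain

**Cross-dating screen.** Each core is reduced to high-frequency indices
by a cubic smoothing spline (cutoff wavelength min(32 yr, 67% of series
length)), then correlated with the leave-one-out mean of all other cores
over the common years.  Cores with r < 0.40 are discarded; cores with
fewer than 20 overlap years are flagged undatable.  This mirrors the
usual COFECHA-style statistical screen without its segment-wise
diagnostics.

**Pith offset.** When a core misses the pith, the missing radius is
estimated from the innermost ring arc by circle geometry: an arc of chord
L and sagitta h lies on a circle of radius r̂ = L²/(8h) + h/2; the number
of missing rings is r̂ divided by the mean width of the k (default 5)
innermost rings, rounded.

**Coring-height age correction.** The number of years a tree needed to
reach coring height is predicted from an OLS regression of the
ground-vs-DBH ring-count difference on age at DBH (fitted on trees with a
ground-level recount); predictions are rounded and clamped at zero.  When
no pairs are available the pipeline falls back to the line 16 − 0.1·age,
which spans the conventional 15-to-3-year range from young to old trees.
Age classes follow the age at coring height: young ≤ 40 yr, mature 41–80,
old > 80; plants below the adult DBH threshold count as established
regeneration only from age 3.

**Biometric screen.** Within 10-year age bins, a tree passes a parameter
(DBH, height, crown area) if its value exceeds the bin mean minus one
sample standard deviation; trees passing at least two of three and having
strictly more than 20 rings are retained for the climate analysis.  A
tree alone in its bin passes by default and is flagged.

**Detrending.** Indices are the ratio width / fitted growth curve:

* *spline* (old trees): cubic smoothing spline with a 50% frequency
  response at a cutoff wavelength of 67% of the series length by default.
  The penalty is λ = (wavelength/2π)⁴ in the
  `make_smoothing_spline` parameterization, from the smoothing-spline
  transfer function |H(f)| = 1/(1 + λ(2πf)⁴) evaluated at f = 1/wavelength.
* *negexp* (mature trees): a·e^(−bt) + k with a, b > 0, k ≥ 0 via bounded
  least squares; if the fit fails, degenerates (a ≈ 0) or is not strictly
  decreasing and positive, the curve falls back to the horizontal mean — the
  classic conservative fallback.
* *rcs* (young trees): one regional curve per cohort — mean width by
  cambial age with pith offsets applied, gaps interpolated, smoothed by a
  spline with a cutoff of 10% of the maximum cambial age (floor 5 yr) to
  avoid amplifying noise at low sample depth; ages beyond the curve's
  support reuse the last value.  RCS preserves low-frequency signal that
  per-series fits would remove, which matters for short young series.

**Chronology.** The master is the per-year arithmetic mean of the index
series (Tukey biweight, c = 9, optional).  Statistics: MSm, the Douglass
mean sensitivity 2|x_{t+1}−x_t|/(x_{t+1}+x_t) averaged over the master;
MSi, the mean of per-series sensitivities; CC, the mean pairwise
inter-series correlation over overlaps of ≥ 20 yr; CM, the mean
correlation of each series with the master; AC1, the lag-1 Pearson
autocorrelation of the raw and of the standardized master.  The exact
conventions behind CC/CM vary between dendro programs; the definitions
above are stated here precisely because no single canonical formula
exists.  Two cores of a tree are averaged into one tree-level series
before chronology building.

## Response functions

The design matrix holds 24 regressors over the biological year — October
of the year preceding growth through September of the growth year: 12
monthly precipitation totals plus 12 monthly maximum *or* minimum
temperatures (two separate designs, never a 36-column joint fit).

Each of n_boot (default 1000) replications draws calibration years with
replacement; the out-of-bag years are the verification set (replicates
with fewer than 3 out-of-bag years are redrawn).  Regressors and the
chronology are standardized on the calibration sample; principal
components of the calibration correlation matrix with eigenvalue above
the mean (Guttman rule; a fixed count is configurable) are retained; the
chronology is regressed on the retained components and the coefficients
are rotated back to the regressors.  Reported per regressor: the mean and
sd of the bootstrap coefficients and a significance flag |mean/sd| ≥ 1.96.
Globally: R_V, the mean Pearson correlation between predicted and
observed indices on the verification years, and r/s = R_V divided by the
across-replicate sd of the verification correlations, labelled p < 0.05
at |r/s| ≥ 1.96, p < 0.1 at ≥ 1.645, else ns.

Two behaviours of this classical machinery are worth knowing:

* **Coefficient attenuation.** Back-rotated coefficients are shrunk when
  the signal loads on discarded components; recovery tests should check
  flags and signs, not magnitudes.
* **Conservative r/s.** The across-replicate sd of verification
  correlations overestimates the sampling sd of their mean (replicates
  share the one observed dataset), so under a white-noise chronology the
  null distribution of r/s is roughly N(0, 0.6) rather than N(0, 1) and
  |r/s| ≥ 1.96 fires in well under 5% of experiments (≈0.5% in a
  400-experiment measurement at n = 40 years).  The threshold is kept at
  the conventional 1.96; users should read r/s as a conservative
  significance screen, not a calibrated z-statistic.

## Synthetic data

The generators provide the statistical structure the pipeline assumes,
with exact per-class counts (rejection sampling) and full determinism
under a seed.

* **Stem maps.** Uniform (binomial) points in the disc; Thomas cluster
  processes (parents in a 3σ-enlarged window to avoid edge intensity
  bias, Gaussian offspring redrawn until inside); sequential-inhibition
  hardcore patterns with bounded retries and an explicit infeasibility
  error.  Cross-class rules: independence, repulsion (minimum cross-class
  distance) or attraction (shared Thomas parents).
* **Climate.** Independent monthly Gaussians around a Mediterranean
  profile — 644.6 mm mean annual precipitation with the maximum in
  November and minimum in July, ~14.5 °C mean annual temperature —
  truncated at zero for precipitation, with Tmin capped below Tmax.
  Monthly sds default to 45% of the monthly mean (precipitation) and
  1.5 °C (temperatures).
* **Ring widths.** width(t) = agecurve(cambial age) ·
  exp(β·z(t) + ε_tree(t) + ε_core(t)) with a per-class negative
  exponential age curve, z the standardized monthly regressors, ε_tree an
  AR(1) (default φ = 0.6, innovation sd 0.138) shared by a tree's cores
  and ε_core white (sd 0.141).  The multiplicative log-normal form
  guarantees positive widths.  The default β places most weight on
  previous-October/November precipitation with smaller December, March
  and January-temperature terms — the signal shape expected for a
  Mediterranean pine on sandy soil.  The implied core-versus-master
  correlation is ≈0.85–0.90, deliberately at the high end of real stands
  so the 0.40 cross-dating threshold separates planted defects from good
  cores with a > 4σ margin at any seed.
* **The default study** (`generate_study`): 111 adults (56 young Thomas-
  clustered, 31 mature hardcore-inhibited and ≥ 6 m from the old trees,
  24 old random) plus 50 established-regeneration plantlets, two cores
  per adult (222), 25 cores reaching the pith.  26 cores on old trees are
  made undatable by shuffling their widths across years (8 trees lose
  both cores, leaving 103 trees), and 33 trees are planted as stunted:
  trees already failing the 2-of-3 screen by natural spread are adopted
  into the set, the rest are chosen subject to a 40% per-age-bin cap (a
  mean−sd threshold cannot remove half a bin), and their DBH/H/CW are
  lowered below the realized per-bin thresholds by a deterministic
  fixed-point loop, verified in-generator.  Six young "anchor" trees are
  pinned at age 40 with pith reached so the young chronology spans the
  full 1958–1997 analysis period.  The stunted structure is planted
  against the *estimated* corrected ages (ring count plus fitted
  correction), i.e. against exactly what the screening stage later
  observes.

**What the generator does not emulate:** spatially explicit dispersal or
birth–death dynamics, climate autocorrelation between months, drought
indices, size–growth feedbacks, measurement error beyond the 0.01 mm
quantization, or missing/locally absent rings.  Passing tests therefore
demonstrate that the estimators and screens recover structure of the kind
assumed, not that real stands satisfy those assumptions.

## Problem sizes and numerical choices in the validation suite

The test suite and `scripts/acceptance.py` use: 100 random patterns
(n ≤ 50) for exact oracle equivalence of the pair counts; 200 trials of
n = 100 CSR patterns for envelope calibration at a fixed 10 m distance;
a 50-tree RCS cohort (ages 90–110, log-scale noise sd ≈ 0.04) sized so
that the sd of a depth-10 mean index (≈0.015) sits well inside the ±0.05
acceptance band and the check measures smoothing bias rather than
sampling noise; 1000 bootstrap replications for planted-signal recovery
and 300 for each of the 200 white-noise calibration experiments (r/s is a
mean-to-sd ratio and stabilizes quickly in the replicate count); and 100
twelve-tree cohorts for the persistence-removal check.  The perfect-fit
limit of the response function is exercised on an 80-year span with full
component retention: with 40 years, a bootstrap calibration sample
contains fewer than 24 distinct rows about 20% of the time, and the
minimum-norm solution then differs from the true coefficients even
without noise.

## Known limitations

* The uncorrected K is biased low near the window boundary; only
  envelope-based inference, not raw K values, should be interpreted
  unless the isotropic correction is enabled.
* The rotation null randomizes orientation, not radial placement.
* r/s is conservative (above); borderline climate signals will be missed
  more often than a nominal 5% test would suggest.
* RCS assumes one common growth law per cohort; applying it across
  cohorts with different site histories confounds the regional curve.
* The RWL writer emits the classic Tucson dialect only (0.01 mm units,
  999 stop marker); 0.001 mm files are read only via the −9999 marker.
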