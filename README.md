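# dendrostand

Dendroecology of multi-aged forest stands: spatial point-pattern
statistics, tree-ring chronologies and tree-ring/climate response
functions in one tested Python package.

Studies of uneven-aged stands — for example multi-layered Mediterranean
umbrella-pine (*Pinus pinea*) forests — ask how management history shaped
the spatial arrangement of tree cohorts and whether trees of different
ages respond differently to climate. Answering both questions takes a
chain of classical methods that usually lives in three separate legacy
programs: point-pattern analysis of the stem map, chronology building
from increment cores, and bootstrap response functions against monthly
climate. `dendrostand` implements that chain as a library for ecologists
and dendrochronologists, together with synthetic-data generators that
reproduce the statistical structure those methods assume, so every stage
is testable without field data.

## Methods at a glance

* **Spatial**: univariate Ripley's K, K(d) = A·Σ_{i≠j} 1[d_ij ≤ d]/n²,
  and the bivariate K12(d) = (n₂K̂12 + n₁K̂21)/(n₁+n₂) between age
  classes, both through Besag's L(d) = √(K(d)/π) − d; pointwise 95%
  Monte Carlo envelopes from 99 simulations (CSR null for one class, a
  rigid-rotation null preserving within-class structure for two classes);
  per-distance classification into clustered/random/regular and
  attraction/independence/repulsion.
* **Tree rings**: cross-dating screen against a leave-one-out master
  (discard r < 0.40), pith-offset estimation from arc geometry
  (r̂ = L²/8h + h/2), coring-height age correction by regression,
  age classes Y ≤ 40 < M ≤ 80 < O, a 2-of-3 biometric screen per 10-year
  age bin, detrending by cubic smoothing spline, modified negative
  exponential or Regional Curve Standardization, and chronology
  statistics (mean sensitivity, inter-series correlations, AC1).
* **Climate response**: bootstrap orthogonalized regression of a
  chronology on 24 monthly regressors over the biological year
  (October t−1 … September t; precipitation with either Tmax or Tmin),
  1000 replications, out-of-bag verification; per-regressor significance
  |mean/sd| ≥ 1.96 and the global statistic r/s = R̄_V/sd(R_V).

`docs/methods.md` documents every model, default and numerical choice.

## Worked example

`examples/` holds one short script per capability. Classifying planted
spatial structure (`examples/point_patterns.py`):

```
Thomas cluster pattern (expect 'clustered' at a few metres):
  1m:clustered, 2m:clustered, 3m:clustered, 4m:clustered, 5m:clustered, ...
Hardcore pattern, min distance 6 m (expect 'regular' below 6 m):
  1m:random, 2m:regular, 3m:regular, 4m:regular, 5m:regular, 6m:regular, ...
Two groups kept >= 8 m apart (expect 'repulsion' below 8 m):
  1m:independent, 2m:independent, 3m:repulsion, 4m:repulsion, 5m:repulsion, ...
```

Each line is the per-distance envelope verdict: the clustered pattern
sits above the CSR envelope, the inhibited one below it at short range,
and the segregated pair falls below the rotation-null envelope out to the
planted 8 m separation.

Running the full chain on the default synthetic stand
(`examples/full_pipeline.py`):

```
cores discarded by cross-dating: 26 of 222
trees retained after biometric screen: 70 of 103

age_class  n_trees  mrw_mm   msm    cc    cm  ac1_raw  ac1_std  rv_tmax  r_over_s_tmax p_tmax
        Y       30   1.349 0.456 0.744 0.875    0.312   -0.208    0.592          3.454  <0.05
        M       25   2.601 0.476 0.793 0.895    0.186   -0.202    0.607          3.743  <0.05
        O       15   1.627 0.444 0.791 0.896    0.595   -0.140    0.625          3.828  <0.05
```

The screen discards exactly the 26 planted undatable cores and the 33
planted stunted trees; `ac1_std` far below `ac1_raw` shows detrending
removed the age-trend persistence, and `r_over_s ≥ 1.96` marks a
significant climate/growth relationship in every class (the generator
plants a strong autumn-precipitation signal).

A thin CLI wraps the same pipeline for shell use:

```sh
dendrostand simulate --seed 0 --out data/      # stem map, RWL cores, climate CSV
dendrostand all --seed 0 --out results/        # the full pipeline
dendrostand spatial --stem-map data/stem_map.csv --out results/
```

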