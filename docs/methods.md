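# Methods

`deertrack` localizes animal vocalizations from time-of-arrival differences
at three (or more) synchronized stationary recorders, then uses the
positions to de-duplicate repetitive calls from territorial individuals and
to sketch their movement. This note records the model, the numerical
choices, and the limits of what the simulator-based tests demonstrate.

## Localization model

A call emitted at an unknown point reaches recorder *k* after a travel time
`d_k / V`, where `d_k` is the source-to-recorder distance and `V` the speed
of sound. Absolute emission time is unobservable; the data are the lags
`T_k` of each recorder relative to the first detector, equivalently the
range differences

```
D_k = T_k · V .
```

Each lag constrains the source to one branch of a hyperbola with foci at
the first detector and recorder *k*; with three recorders there are two
independent lags and the source lies at a branch intersection.

Rather than solving the hyperbolic system in closed form, the position is
retrieved by exhaustive trial and error on a square lattice (default
spacing 0.5 m). For each candidate point `x` the flat-earth distances
`d_k*(x)` to all recorders are computed; if the recorder nearest to `x` is
not the observed first detector, the candidate is skipped (the true source
must lie in the first detector's nearest-recorder region — this pruning
cuts the scan roughly threefold and is exactly equivalent to the full scan
whenever the full-scan argmin lies in that region, which the test suite
verifies on random scenes). Otherwise the candidate's predicted range
differences `D_k*(x) = d_k*(x) − d_first*(x)` are scored against the
observations with

```
RMSE(x) = sqrt( Σ_k (D_k*(x) − D_k)² / (n−1) ) ,
```

the sum running over the non-first recorders. The lattice point minimizing
RMSE is the retrieved position; ties resolve deterministically to the first
point in south-to-north, west-to-east scan order.

Two formulas in the source material for this method circulate with
typographical slips; the implementation uses the plainly intended forms:
the equirectangular *y*-term is the latitude **difference** (a latitude sum
cannot be a displacement — it is non-zero for identical points), and the
RMSE pairs each predicted difference with its own observation.

### Geodesy

Recorder arrays span hundreds of meters, so distances use the
equirectangular (flat-earth) approximation on a sphere of mean radius
6,371,000 m:

```
d = R · sqrt( (Δλ · cos φ̄)² + Δφ² ) ,     (angles in radians)
```

with `φ̄` the mean latitude of the pair. Against a haversine oracle this is
accurate to well under 0.1% for all pairs of surveyed points in both
bundled deployments (sub-millimeter at 70 m). No ellipsoidal correction is
attempted; at these scales it is far below the timing-noise floor.

The lattice is anchored at the deployment centroid with axes locally east
and north. The exact lattice phase used in the original field study is
unknown; this contributes up to ~0.7 m of irreducible disagreement when
reproducing published point errors, which the acceptance tolerance absorbs.

### Sound speed

`speed_of_sound(T) = 331.2 + 0.606·T` m/s (dry air, °C), matching the
331.2 / ≈343 m/s anchors at 0 and 20 °C. An explicitly supplied speed
always overrides the model — field work typically fixes a round value
(e.g. 340 m/s on an 18 °C day) and the pipeline honors that.

### Grid sizing

By default the square grid is centered on the station centroid with
half-extent equal to the largest station-to-centroid distance plus a
required edge clearance (default 750 m), rounded up to a whole number of
spacings, so every recorder keeps at least that clearance to every edge —
the grid must cover everywhere a detectable source could be. An explicit
extent override reproduces published runs (1.6 km and 3 km grids) and
warns if it violates the clearance. Near-collinear deployments (all
stations within 1 m of a line) trigger a degenerate-geometry warning:
localization is ill-conditioned perpendicular to the line.

### More than three recorders

The method is defined for exactly three recorders. With more, the default
`earliest` policy keeps the three earliest-detecting stations. A
`best-triple` alternative scores every 3-subset and keeps the lowest-RMSE
fit; it is provided for exploration but **not** recommended as a default:
measured on noise-free scenes, a ghost branch of one triple can undercut
the true-position RMSE of another triple and drag the result hundreds of
meters away. Neither policy is canonical; both are honest guesses at an
unspecified step.

## Known limitations of the retrieval

Two failure modes are intrinsic to minimizing this objective on a lattice,
and the test suite deliberately documents them rather than hiding them:

1. **Ghost intersections.** Two hyperbola branches sharing the
   first-detector focus can intersect twice. When the source sits within
   roughly 10 m of a recorder, the second intersection is an *exact*
   solution of the same lag observations, possibly 100+ m away and in the
   same nearest-recorder region; whichever intersection happens to fit the
   lattice better wins. No argmin rule can distinguish them without prior
   information.
2. **Argmin ≠ nearest cell.** With an off-lattice source the minimum-RMSE
   cell is usually, but not always, the cell nearest the truth. Where the
   two hyperbolas cross at a shallow angle the error valley is elongated
   and the discrete argmin can land ~1.5 cells away (≈0.5 m at 0.5 m
   spacing) instead of within half a cell diagonal (0.36 m). Median
   noise-free error is ~0.2 m; the tail reaches ~0.55 m.

Consequently the noise-free recovery test asserts the half-diagonal bound
for every uniformly drawn in-triangle source and *fails by design* for a
minority (~10%) of draws on both bundled geometries; the median-level
bound passes. With realistic timing noise (0.018 s) these sub-meter
effects are irrelevant — the noise floor is meters.

## Forward simulator

The simulator generates the study conditions the pipeline is tested under:

| parameter | default | meaning |
|---|---|---|
| `timing_noise_sd_s` | 0.018 s | Gaussian annotation error per station per call — the precision with which a human reads a call onset off a spectrogram |
| `detection_range_m` | 450 m | step audibility cutoff (deployments space recorders to stay within it) |
| `audibility_model` | `step` | alternative `three_state`: reliable ≤ 423 m, p = 0.5 to 545 m, silent beyond — a coarse reading of field audibility trials at 181/297/423/545/761 m |
| `n_individuals` | 3 | simultaneous territorial callers |
| `min_individual_spacing_m` | 100 m | territorial exclusion distance, enforced at every instant |
| `movement_step_sd_m` | 10 m | per-interval Gaussian random-walk step of each caller |
| `call_rate` | 2 /interval | Poisson mean calls per individual per interval |
| `interval_s`, `duration_s` | 600 s, 7200 s | twelve 10-minute intervals — a two-hour evening session |

Defaults are chosen so a session expects 3 × 2 × 12 = 72 calls, i.e. six
calls per 10-minute interval over two hours, matching the scale of a real
rutting-season recording night. Detection time at a station is
`emission + distance/V + N(0, σ)`; stations failing audibility are
omitted, and calls heard at fewer than three stations are emitted but
flagged unlocalizable. A fixed seed reproduces every draw bit-for-bit.

The noise distribution is a modeling choice: only the 0.018 s *scale* is
empirically grounded; Gaussianity, independence across stations, and the
interpretation of "barely detected" as p = 0.5 are the standard minimal
assumptions and are configurable. The simulator works at the
detection-time level — it does not synthesize waveforms, so it cannot
exercise the upstream annotation step (spectrogram reading, noise
reduction), reverberation, wind or humidity effects, or correlated timing
errors. Passing simulator-based tests therefore demonstrates the geometry
and bookkeeping of the pipeline, not the difficulty of extracting onset
times from real recordings. One deliberate mismatch of scale: the 0.018 s
figure was derived in the field as a *lag* error, while the simulator
applies it per *station*, making simulated lag noise √2 larger — simulated
accuracies are accordingly slightly pessimistic.

## Deduplication and tracking

Territorial males exclude rivals from their calling area, so calls
localized at adjacent positions are attributed to one animal. This is
operationalized as single-linkage clustering: calls are nodes, pairs
within `linkage_distance_m` (default 50 m, the scale at which repeated
calls cluster around a fixed camera position in field experience) are
edges, and individuals are the connected components — an order-free
definition, so input shuffling cannot change the result. The count of
components is the deduplicated individual count; it is non-increasing in
the threshold. An optional maximum within-cluster time gap exists but is
off by default, since a territorial male may call from the same spot an
hour apart. The 50 m default is an inference from deployment experience,
not a measured territory radius; survey designs with denser callers should
lower it.

Interval statistics count calls in fixed windows (default 10 min) over a
session; the mean is total/intervals and the quoted SD is the population
convention (divide by the number of intervals), with the sample convention
also exposed. Movement paths order a cluster's calls in time and report
net displacement, cumulative path length, and the compass bearing of the
net move; a singleton cluster yields an empty path.

## Numerical and interface choices

- All internal angles are radians; every public surface speaks decimal
  degrees (DMS strings parse and format to the 0.01″ survey precision).
- The vectorized lattice scan caches per-station distance fields and
  per-first-detector predictions, so batch localization against a fixed
  deployment costs one geometry pass plus a cheap scoring pass per call;
  it is contract-tested to match the per-candidate scalar loop.
- Nearest-recorder ties at a candidate (within one lattice spacing) count
  as matching the first detector, so near-zero lags cannot spuriously
  prune the region boundary the source sits on.
- No sub-lattice refinement is performed: the 0.5 m lattice is the method.
- CSV dialects are UTF-8 with header rows; GeoJSON uses [lon, lat] order;
  KML is a minimal flat document. Exit codes: 0 success/warnings, 2 input
  error, 3 nothing localizable.

## Problem sizes used in the shipped checks

The full published grid (1.6 km × 1.6 km at 0.5 m ⇒ 3201² ≈ 10.2 M
candidates) is scanned once for the point-E reproduction, in a few seconds.
The property suites use grids just large enough to contain their recorder
triangles with margin (400–1000 m extents), 100 noise-free and 1000 noisy
scenes, and 100 random coarse-grid (5 m) scenes for the pruning-equivalence
check — sizes at which the statistical conclusions are stable across seeds.
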