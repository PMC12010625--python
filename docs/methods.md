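# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. It is the package's
own account; every number quoted here is computed by the tests or by
`scripts/acceptance.py`.

## Movement model

State per axis is (position, velocity); velocity is Ornstein–Uhlenbeck
with autocorrelation β (h⁻¹) and noise scale σ (m·h⁻³ᐟ²), position the
integral of velocity. For a step of Δ hours with e = exp(−βΔ) the exact
discretization is

    x' = x + v(1−e)/β + ξ,   v' = e·v + η,

with Var(η) = σ²(1−e²)/(2β), Var(ξ) = σ²/β²·(Δ − 2(1−e)/β + (1−e²)/(2β)),
Cov(ξ,η) = σ²(1−e)²/(2β²). The two axes are independent in the process but
coupled through rotated measurement ellipses, so the filter runs jointly
on the 4-state vector. The filter grid is the union of observation times
and the 5-min lattice anchored at the first fix; the likelihood is
invariant to the extra latent times.

* Initialization: position prior at the first fix with a diffuse variance
  of 1e10 m² per axis; velocity prior stationary, N(0, σ²/(2β)). The
  diffuse term contributes an additive constant to the log-likelihood
  that does not affect estimation; the test-suite oracle (a brute-force
  joint-Gaussian density at small n) reproduces the filter likelihood to
  1e-6 under the same prior.
* Optimization: L-BFGS-B on (log β, log σ), three starts (β₀ ∈ {0.3, 3,
  30} h⁻¹; σ₀ from the RMS displacement rate of the data), ftol 1e-8.
  Bounds log β ∈ [log 1e-3, log 1e3] guard the β → 0 ridge that a
  noise-free straight-line track induces.
* β is measured per hour, so the Brownian variant fixes β = 3 h⁻¹. The
  unit is a package convention (the alternative readings of "three" —
  per minute or per day — produce movement either indistinguishable from
  white noise or from a smooth spline at these sampling rates);
  it is configurable through `track.BM_FIXED_BETA_PER_H`.
* Standard errors come from a finite-difference Hessian in log-parameter
  space with the delta method; AIC = 2k − 2 logL with k = 2 (CTCRW) or
  k = 1 (BM). Ties in AIC go to the CTCRW.
* Imputation is trajectory simulation (forward-filter backward-sampling
  from the joint smoothing distribution), not pointwise draws; the
  pointwise mean over many imputations converges to the predicted track
  (tested at 2000 draws).
* When ellipse fields are missing, per-class isotropic fallback SDs are
  substituted (`track.CLASS_FALLBACK_SD_M`), a convention for older tags.
* The location prefilter replaces the external Douglas/Movebank filter
  with a documented equivalent contract: strict GPS thresholds
  (residual < 35, time error < 10 s), best-quality deduplication at equal
  timestamps, then iterative removal of the fix requiring the largest
  implied speed (ties broken by summed adjacent speeds) until all
  consecutive speeds are ≤ 3 m/s. The speed threshold is a configuration
  default, not an inferred value.
* Rerouting densifies the barrier boundary (default every 500 m), builds
  a visibility graph (an edge is admitted when the segment misses the
  barrier eroded by 1 m, which keeps boundary-hugging edges), and takes
  the shortest path between the entry and exit fixes; displaced points
  are spaced evenly along the detour. A track entirely inside the barrier
  is an error.

Geodesy uses a local azimuthal-equidistant projection on a spherical
Earth centered at the track centroid (fitting) or the synthetic range
(simulation); forward/inverse round trips are exact to numerical
precision and tested below 0.5 m.

## Dive reconstruction

Transmitted bins are symmetric around truth in the generator, so the bin
mean is an unbiased apex/duration estimate and the round-trip test can
demand recovery within the bin half-width. Bottom-time fractions by shape
(V 0–0.20, U 0.20–0.50, square 0.50–0.85, midpoints used) and the
vertical-rate bounds (descent 0.2–1.7 m/s, ascent 0.1–1.5 m/s) are
calibration constants, configurable per call — they reproduce the
min/max-then-mean logic of tag-vendor dive shapes without vendor
documentation. When a rate clamps, the freed time returns to the bottom
phase so descent + bottom + ascent always equals the logged duration;
when even the extreme rates cannot fit the depth into the duration the
profile is flagged rather than rejected. Dive start/end are triggered at
3 m depth; the profile therefore starts and ends at 3 m and no correction
is applied for the 2–4 s truncation this implies. Surface-period depth is
nominal 0 m standing for "somewhere in 0–50 m"; no analysis treats it as
exact. Gap timestamps within 1 min of a fix or shore-receiver uplink are
assumed shallow (top 50 m); all other gap samples are unknown and
propagate as missing depth into the RL stage.

## GVP matching

The 95% confidence ellipse scales the per-axis SEs by √(χ²₂,₀.₉₅) ≈
2.4477, the same convention used everywhere in the package. "Within
10 min" is measured from the track sample time to the nearest point of
the GVP interval; distance to the ellipse is max(0, center distance −
ellipse support along that direction). Containment (dive start ≤ click
start and click end ≤ dive end) is strict with a configurable clock
tolerance defaulting to 0 s. Only the explicit containment rule is
implemented; no qualitative goodness-of-match judgment is applied, so the
accepted set on real data would be a superset screened by an analyst.

## Received levels

The propagation interface is a pure function TL(range, depth, config) so
a full parabolic-equation model can be plugged in. The bundled default is
geometric spreading with absorption and an optional depth hook,
k·log₁₀(range) + α·range/1000 + duct(depth), k = 20 and α = 0 by default;
with duct ≡ 0 the two depth regimes produce equal medians, which the
tests document as the stand-in's limit. Ranges below the 1-m source
reference are capped. Ellipse sampling is systematic in azimuth (36
radials; boundary + midpoint per radial + center = 73 positions), and RL
percentiles are computed over that full sample set (recorded in output
metadata). Stoplight activity categories default to tertiles of the
nonzero per-bin transmission counts; the thresholds are declaredly
arbitrary and configurable.

## Response statistics

Percentiles use linear interpolation between order statistics (type 7);
the IQR band test is inclusive at its bounds. Anomalously deep
intermediate dives (> 300 m) can be masked from IDDI percentile analyses
via a labeled filter. Step metrics pool the 30 imputations into a single
test per metric (matching the presentation of one χ²/p per whale ×
metric); pooling inflates effective n, which is documented as a caveat,
and per-imputation testing can be built from the same step table. Bearing
is analyzed as a linear variable in [0, 360) to mirror the rank-test
usage despite its circularity. The gap filter removes a step only when
the enclosing observed-fix gap at both of its endpoints exceeds 1 h, so
boundary steps adjoining a fix survive. Tukey–Kramer on mean ranks refers
|R̄ᵢ−R̄ⱼ|/√((N(N+1)/12)(1/nᵢ+1/nⱼ)) times √2 to the studentized-range
distribution with k groups and infinite df; its null familywise error is
measured at ≈ 0.05 and it is never smaller than the unadjusted two-group
normal reference on the same statistic (tested).

## Synthetic data: what it emulates, and what it does not

The generator is the generative twin of the analysis: CTCRW truth track
at 1-min resolution (defaults β = 3 h⁻¹ and σ derived to give a 130-m
mean 5-min step); a deep-dive/IDDI cycle whose split-uniform draws match
the published min/median/max envelopes (deep 304/1200/1424 m,
13.8/50.7/71.0 min; intermediate 50/105/256 m, 0.8/10.7/26.7 min); a
shifted-geometric intermediate count per IDDI (p = 0.26, clipped to
0–12) putting the deep-dive share of dives near the observed 26%;
error-ellipse-tagged fixes only during surface states with log-uniform
5-min–6-h gaps; behavior logs with symmetric ±2.5% bins and a
configurable gap fraction; GVPs with truncated-normal onset delay
(median 5.8 min) and cessation lead (median 12.7 min) on every hydrophone
within a hard 6-km radius; and MFAS schedules in which hull pings ride on
10-s ship fixes so the 1-s/400-m join always succeeds.

Not emulated: acoustic waveforms or real propagation (so RL magnitudes
are plausible, not site-accurate); detection-probability falloff with
range (a hard radius stands in for a detection function, chosen to equal
the matching rule's 6-km constant); behavior-switching movement;
tag-failure modes beyond uniform log gaps; and clock drift. Passing
round-trip tests therefore demonstrates the pipeline's internal
consistency and the correctness of its rules, not field performance on
real tags.

## Problem sizes

The test suite and acceptance script use 100 replicate fits of 300-fix
tracks for parameter recovery, 96-h simulations for round-trip and GVP
checks, 10 000 null replicates for Kruskal–Wallis calibration and 2 000
for the familywise-error measurement — sizes at which the Monte-Carlo
error of each reported rate is well below the acceptance margins.

## Known limitations

* The CTCRW β is weakly identified on very sparse, very noisy tracks;
  the optimizer can run to its β bound, which mimics uncorrelated
  movement and is handled by the BM comparison rather than suppressed.
* IDDIs bounded by a behavior-log gap or the record edge are flagged
  truncated and excluded from exact-recovery checks.
* The 2022 exercise-schedule rows in the source tables are mutually
  inconsistent (overlapping phases, durations that contradict their own
  timestamps) and are not shipped; only the validated 2014 and 2021
  schedules are included.
* The printed 2014 After-phase duration (6.0 h) differs from its own
  timestamps (5.0 h); the package reports computed durations and does not
  assert that row.
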