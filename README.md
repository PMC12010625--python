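# sonarwake

Movement, dive, and sonar exposure-response analysis for satellite-tagged
beaked whales.

Blainville's beaked whales (*Mesoplodon densirostris*) living near naval
training ranges are exposed to mid-frequency active sonar (MFAS) from
hull-mounted ships (nominal source level 235 dB re 1 µPa at 1 m),
helicopter-dipping units (217 dB) and active sonobuoys (201 dB). Long-lived
satellite tags record sparse, error-prone surfacing positions and
transmitted dive summaries; bottom-mounted range hydrophones detect group
vocal periods (GVPs) of echolocation clicks from foraging groups. This
package implements, end to end, the analysis chain that turns those raw
streams into an exposure-response assessment, and ships a ground-truthed
synthetic-data generator so every stage can be validated against known
truth.

## The model and method

**Movement.** Surfacing fixes are filtered (GPS residual < 35 and time
error < 10 s; iterative speed filter) and fitted to a continuous-time
correlated random walk (CTCRW): per axis the velocity ν(t) is an
Ornstein–Uhlenbeck process, dν = −β ν dt + σ dW, and position integrates
the velocity. Each fix enters a Kalman filter on the exact discretization
of this state space with per-fix measurement covariance built from its
Argos error ellipse (semi-major a, semi-minor b as 1-σ axis SDs,
orientation θ from north). A Brownian-movement variant (BM) freezes
β = 3 h⁻¹; AIC = 2k − 2·logL chooses per tag. The smoother yields a
5-minute predicted track with per-axis SEs; forward-filter
backward-sampling draws 30 track imputations from the joint smoothing
distribution. Points falling inside a barrier polygon (the 300-m isobath)
are rerouted along the shortest barrier-avoiding path on a visibility
graph.

**Dives.** Behavior logs report binned min/max depth and duration plus a
shape code for every dive ≥ 50 m lasting > 30 s. Reconstruction takes bin
means, assigns a bottom-time fraction by shape (V 0–0.20, U 0.20–0.50,
square 0.50–0.85; midpoint used), splits the remaining time equally into
descent and ascent, clamps vertical rates to published bounds, and
interpolates 60 points per dive. Dives are classed intermediate
(50–300 m) or deep (> 300 m); spans between consecutive deep dives become
inter-deep-dive intervals (IDDIs).

**GVP matching.** A hydrophone is a candidate when it lies within 6 km of
the whale's 95% confidence error ellipse for a track position within
±10 min of the GVP; a GVP is accepted when its click interval is strictly
contained in a deep dive, and click start/end depths are read off the
reconstructed profile.

**Received levels.** MFAS transmissions chain into bouts (breaks
< 30 min), hull pings join ship fixes within 1 s and 400 m, and one
transmission per source unit per 5-min bin (±2.5 min) is selected. RL =
SL − TL is evaluated over a systematic radial sampling of the 95% error
ellipse, at the modeled animal depth or — when depth is unknown — for two
depth regimes (0–54 m and 54–1125 m). The bundled transmission-loss
function is a geometric-spreading stand-in, TL = k·log₁₀r + α·r + duct(z),
behind a pluggable interface.

**Response statistics.** Baseline (pre-MFAS) dive-cycle metrics give
per-whale empirical percentiles (2.5/25/50/75/97.5); exposure metrics are
banded against them, with values outside the central 95% flagged atypical.
Per-step bearing, step length, speed and turning angle on the 30 imputed
tracks are compared across exercise phases with Kruskal–Wallis tests and
Tukey–Kramer multiple comparisons on mean ranks, on full tracks and on
tracks restricted to ≤ 1 h between observed fixes.

## Worked example

```python
from sonarwake import pipeline, synthetic, reference_data

sim = synthetic.SimConfig(seed=42, duration_h=96.0,
                          mfas_schedule=synthetic.default_mfas_schedule(48.0))
cfg = pipeline.RunConfig(seed=42, outdir="out", sim=sim, n_imputations=30,
                         schedule=reference_data.scc_phase_schedule(2021))
report = pipeline.run_pipeline(cfg)
```

On this seed the run simulates a 96-h deployment, keeps 54 of 68 raw fixes
after filtering, and prints (in `out/run_report.json`):

```
"selected_model": {"kind": "CTCRW", "aic_ctcrw": 1956.99, "aic_bm": 1957.35,
                   "beta": 0.82, "sigma": 951.98}
"gvp_summary":    {"n_gvps": 129, "n_matches": 31, ...}
"rl_summary":     {"n_bouts": 3, "n_bins": 38, "rl_median_max_db": 166.5}
```

meaning: AIC (barely) favors the free-β CTCRW over the β = 3 BM variant;
all 129 simulated GVP detections resolve to 31 matched deep dives
(several dives are heard on multiple hydrophones); and the three simulated
sonar bouts expose the whale in 38 five-minute bins with a peak median RL
of 166.5 dB re 1 µPa over the positional ellipse. The movement tests on
the gap-filtered tracks flag bearing, step length and speed as differing
across phases (Kruskal–Wallis p < 10⁻²⁴) while turning angle does not
(p = 0.84) — the pattern expected here, since the simulated whale's
movement process does not change across phases but its heading
distribution drifts over a finite track.

The same stages are exposed as a thin CLI:

```sh
sonarwake simulate --seed 1 --out data/
sonarwake run --seed 1 --out out/
```

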