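# Methods

This note records the models implemented in `coastnoise`, the conventions
and defaults they use, and what the synthetic scenarios do and do not
establish about performance on real field data.

## Calibration and band levels

Audio is single-channel PCM WAV. Calibration maps digital full scale to
the recorder's *clipping level* interpreted as a **peak** pressure level:
a full-scale sample equals `10^(clip_db/20)` µPa. This matches the
convention of autonomous recorders that advertise a clipping level (e.g.
172 dB re 1 µPa at the study-type deployment); an RMS-full-scale recorder
is handled by passing `clip_db − 20·log10(√2)`. Recorder clock drift is
corrected with a two-point linear map from device time to reference time —
the minimal strictly monotone model when only start/end synchronisations
are available.

Third-octave bands are base-10 decidecades: exact centres `10^(n/10)` Hz,
edges `centre·10^(±1/20)`, nominal centres from the preferred-number
series (63, 80, 100, 125 … Hz). The 63 Hz–125 kHz analysis range holds 34
bands. Levels are computed per non-overlapping 1-s window by FFT
band-energy summation (bins assigned by `f_low ≤ f < f_high`), which by
Parseval ties each band level exactly to the windowed mean-square
pressure; tones away from band edges are recovered to ±0.1 dB and flat
noise to PSD + 10·log10(bandwidth) ± 0.5 dB. Digital silence yields a
−inf "below floor" flag rather than an error, and levels are never
clipped to the recorder self-noise floor (66/60/66 dB re 1 µPa at
0.125/2/16 kHz, retained as a QC constant only).

Ambient noise per band is the 5th percentile (95% exceedance level) of
the 1-s levels over the whole series, linearly interpolated between order
statistics. Elevation over ambient is max level minus that percentile,
and is invariant to adding a constant to the series.

M-weighting uses the high-frequency-cetacean curve (two-pole high-pass at
200 Hz, two-pole low-pass at 180 kHz, normalised to a 0-dB plateau), the
functional hearing group containing the harbour porpoise. The weighted
broadband level applies the curve as a spectral gain inside a hard
25 Hz–80 kHz passband and averages power over a 30-s sliding window with
a 1-s hop (the hop is a package choice; only the window length is fixed
by the threshold definition). The weighting family is configurable since
the original study did not name its curve.

## Waveguide cutoff

An ideal shallow-water waveguide passes no modal propagation below
`f0 = c_w / (4h·√(1 − (c_w/c_b)²))`; the rigid-seabed limit is
`c_w/(4h)` (18.75 Hz at h = 20 m, c_w = 1500 m/s) and softer seabeds
raise f0 (≈135 Hz at c_b ≈ 1504 m/s). When `c_b ≤ c_w` there is no total
internal reflection and the function signals "no modal cutoff" (NaN with
a warning).

## Tracks

Positions live in a local tangent plane centred on the recorder
(equirectangular; < 1 m error at the 2-km working range, negligible
against the ~200-m theodolite error bound). Theodolite ranges come from
the dip angle as `r = h/tan θ`, with an optional earth-curvature +
standard-refraction correction (fixed-point solve; ~mrad-scale at 2 km,
off by default).

Interpolation to the 1-s grid uses a constant-velocity Kalman filter with
RTS smoothing. Measurement noise defaults: σ = 5 m for AIS fixes,
`max(5, 50·(r/1 km)²)` m for theodolite fixes; process noise is white
acceleration with σ_a = 0.2 m/s². These are package defaults exposed in
the API, not values taken from any field calibration; the Monte-Carlo
test requires only that the smoother not lose to raw linear interpolation
under noise. The grid covers [first fix, last fix] exactly; there is no
extrapolation. Speeds are AIS speed-over-ground where transmitted,
otherwise the smoothed state-velocity magnitude, in knots throughout
(range in metres, log10-transformed, in the regression — matching how
dB-per-knot and dB-per-decade coefficients are conventionally reported).

A theodolite track duplicating an AIS vessel is identified by the median
concurrent separation falling within 200 m (the estimated maximum
theodolite error); the AIS record wins because its positions are
authoritative.

Spatial acceptance marks seconds outside the compass sector (default
31–263°, inclusive both ends, wrapping allowed; `None` disables it) or
beyond 2 km as absent.

## Presence categories and the 200-m rule

Each second is category 1 (AIS only), 2 (AIS + any non-AIS), 3 (≥ 1
motorised non-AIS, no AIS), 4 (only sail-rigged non-AIS) or 5 (nothing).
Sailboats with sails rigged *may* be motoring, but are conservatively
treated as non-motorised for the category split and for the 200-m rule;
sailboats under bare poles are motorised non-AIS. This is a documented,
configurable choice. The closest *motorised* vessel supplies the range
and speed covariates (ties break to the lexicographically smaller id),
and a second motorised vessel within 200 m of it flags the second for
exclusion from single-source statistics. The exclusion is idempotent.

## Mixed model

`TOL_band ~ 1 + log10(range) + vessel_type + speed + (1 | day)`, normal
response, fitted by maximum likelihood (for cross-software likelihood
comparability), Wald p-values, no interactions in the default model.
Only category-1/2/3 seconds passing the 200-m exclusion enter. A
singular or non-converging random-effect fit degrades to a flagged
fixed-effects-only result rather than raising. Parameter recovery is
verified on data simulated from the model itself (slope −15 dB/decade
recovered to ±1, speed coefficient 0.55 dB/knot to ±0.1, n = 2000 over 5
days), including the OLS limit at zero day variance and ~5% type-I error
for a permuted vessel-type factor (500 simulations at n = 200 per
dataset, a size chosen to keep the suite fast; the property is
size-free).

## Thresholds, events, attribution

The three built-in thresholds are evaluated on per-second level series:
the 16-kHz band level directly; sensation level as the max over bands of
(TOL − audiogram threshold), audiogram interpolated in log-frequency; and
the M-weighted broadband level either from raw audio or approximated from
TOLs (M-gain applied at band centres — adequate because the curve varies
slowly across one decidecade). The bundled audiogram
(`data/porpoise_audiogram_synthetic.yaml`) is a *synthetic*,
representative U-shaped table — best sensitivity near 100 kHz — not a
digitisation of a specific published audiogram; replace it with measured
data for real analyses.

Events are maximal runs strictly above the threshold; runs separated by
≤ 10 s are merged and merged runs shorter than 1 s dropped. Both values
are sensitivity parameters, not published constants. Each event is
attributed from the union of presence categories over its span:
`only_AIS`, `only_nonAIS_motor`, `both_present` (category 2 or a mix of
1 and 3), `sail_only`, `no_vessels`. The summary reports each vessel
type's exclusive fraction as a lower bound and exclusive + ambiguous as
an upper bound.

Two monotone invariants of event detection are proven in the tests: the
total above-threshold time never grows with the threshold, and every
higher-threshold event nests inside a lower-threshold event. The raw
event *count* is **not** monotone in the threshold — raising it can split
one long event into several separated by more than the merge gap — and
simulated scenarios exhibit that non-monotonicity routinely; a test
asserting count monotonicity is retained and expected to fail, as a
record of the behaviour.

## Synthetic scenarios

The generator emulates the study conditions: an offshore lane of AIS
vessels (default 1.5/h, 10–15 kn, CPA 1.2–2 km, source spectrum
160 dB re 1 µPa @ 1 m at 1 kHz falling 8 dB/decade), nearshore motorised
recreational vessels (3/h, 5–25 kn, CPA 50–800 m, 152 dB @ 1 kHz,
−3 dB/decade — flatter, cavitation-like), sail-rigged sailboats (4/h,
quiet) and motoring sailboats (1/h). Arrivals are Poisson; passes are
straight lines at constant speed through a uniformly drawn CPA. Source
levels grow by 0.55 dB/knot about a 10-kn reference — inside the
0.5–0.6 dB/knot band that speed-dependence studies report — so that
end-to-end regression recovery is a meaningful check. Propagation is
15·log10(r) spreading (between cylindrical and spherical, a standard
shallow-water compromise), Thorp absorption, and a 12 dB/octave penalty
below the waveguide cutoff (f0 ≈ 89 Hz for the default 9-m site).
Ambient is a wind-noise PSD of 44 dB re 1 µPa²/Hz at 1 kHz falling
14 dB/decade (giving band levels near 71/66/63 dB at 0.125/2/16 kHz),
with 2-dB lognormal per-second fluctuation on totals. Note the 5th
percentile of a fluctuating ambient-only series sits ~1.645σ below the
configured ambient; the tests assert exactly that, and the median equals
the configured value.

Each vessel's contribution is truncated beyond a 2-km audibility range
(configurable). This leans on the same argument that motivates the 2-km
acceptance criterion — rapid shallow-water transmission loss — and keeps
the generator's ground-truth event causes consistent with the presence
window the classifier can see. AIS fixes are emitted every 10 s
(noise-free, with SOG); theodolite fixes every 20 s with 10-m position
noise.

Waveform synthesis renders each second as random-phase noise whose
spectral magnitudes are flat within each band and scaled so the band
mean-square matches the target exactly; re-analysis recovers the levels
to well within 1 dB. Block boundaries are phase-discontinuous, which is
irrelevant at the 1-s analysis resolution but makes the audio unsuitable
for waveform-level listening studies.

What passing these tests shows: the pipeline's logic, calibration
arithmetic and statistics are correct against independent oracles and
ground truth. What it does not show: performance under real propagation
(multipath, sound-speed structure), vessel directivity and aspect
changes, manoeuvring tracks, theodolite operator error structure, or
rain/wave ambient dynamics — none of which the generator attempts.

## Problem sizes

Default validation sizes, chosen to make sampling error small relative to
the tolerances being asserted: 100 random series for the event-detection
oracle; 200 seeded 20-minute scenarios for attribution-bound coverage
(coverage required ≥ 95% of runs with events); n = 2000 over 5 days for
mixed-model recovery; 500 permutation datasets of n = 200 for type-I
control; 100 Monte-Carlo tracks for the smoother-vs-interpolation
comparison.

## Known limitations

- The Kalman defaults are not calibrated against any supplementary field
  parameterisation; treat interpolated speeds at track edges with care.
- Sensation level uses a max-over-bands rule; a single-band rule is
  available but the choice matters when spectra are steep.
- The earth-curvature correction assumes a standard refraction
  coefficient (0.13) appropriate for temperate marine horizons.
- `vessel_census` and event-rate rounding use round-half-up, matching how
  percentages are conventionally reported, not banker's rounding.
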