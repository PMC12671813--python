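# Methods

This note documents the models behind `physiotag`, the defaults and why they
were chosen, what the synthetic data generator does and does not emulate, and
the numerical choices that affect results.

## Solar geometry

Declination and the equation of time use the Spencer truncated-Fourier
series (the NOAA solar-calculator approximation): declination accurate to
about 0.2°, equation of time to about a minute — both far below archival-tag
light-sensor noise. Local apparent solar time is UTC + longitude/15 h + EoT;
civil time zones are never used. "The equinox" in tests means the instant the
declination series crosses zero (found by root-finding), not a calendar date.

## Synthetic tag data

The generator produces the study conditions the analysis assumes; it is
first-class, tested code, not a fixture dump.

**SST field.** `sst(t, φ, λ) = base − g·(φ − φ₀) + A·cos(2π(doy − doy_peak)/365)`
plus spatially/temporally smoothed Gaussian noise. Defaults: base 26.2 °C at
φ₀ = 20°N, meridional gradient g = 0.35 °C/deg (colder northward), seasonal
amplitude A = 4.5 °C peaking at day 235 (early September — the northwestern
Pacific SST maximum lags the solstice), noise sd 0.15 °C. With these
defaults the field at ~36°N drops below the 18 °C lethal limit in
January–March and exceeds the 24 °C spawning threshold in July, matching the
seasonal envelope of the study region. An optional saturation `max_c`
(applied after noise) caps the linear gradient at a tropical maximum; the
residence/migrant scenarios use 29.5 °C, because the linear mid-latitude
gradient would otherwise overshoot observed equatorial SST and push
event-free body temperature across the 31 °C event threshold. The
geolocation benchmark scenario deliberately leaves the cap off and uses a
0.5 °C/deg gradient so the SST observation carries latitude information
everywhere along a 250-day track.

**Movement.** Daily steps on a sphere (R = 6371 km). Step lengths are
truncated normal on [0, 300] km with the *realized* mean calibrated to the
target (34.6 ± 27.6 km/day residents, 77 ± 61 km/day migrants) — naive
truncation at zero would inflate the mean by ~5 km/day. Bearings are von
Mises: uniform (κ = 0) for residents; for migrants κ = 0.5 around due south,
chosen so the ratio of net displacement to daily distance travelled (~0.24)
matches the observed southward deployments, whose tracks are fast but
tortuous. The residence *scenario* adds a drifting home centre
(36.7°N → 31°N through November–January, then holding) with an
Ornstein–Uhlenbeck-style attraction (10 %/day): a pure unbiased random walk
diffuses without bound (±4° over 200 days), whereas real residents stay in a
slowly southward-shifting home range ahead of seasonal cooling, reaching
28–31°N in winter. The plain `simulate_track(behavior="resident")` default
remains the unbiased walk. Latitudes are clipped to [−30°, 55°], the
modelled domain.

**Sensors.** External temperature = field SST at the (daily-interpolated)
position − 0.02 °C/m × depth + N(0, 0.1 °C) sensor noise; the noise sd is an
implementer choice (the tags' spec is unpublished) exposed in the generator.
Internal temperature = clean external + thermal excess. The excess is
scenario-dependent: 3 °C for residents in cool water, 1 °C for migrants in
warm water, reflecting the observed collapse of the body–ambient difference
in the tropics. Depth follows a smooth diel cycle — ~3 m at night and around
twilight, deepest (~11 m) near local noon — so dawn and dusk light crossings
see symmetric attenuation. Light is logistic in solar elevation (inflection
−6°, half-width 3°), attenuated as exp(−0.03·depth), with a dark-count floor
and 5 % multiplicative noise.

**Thermal events.** From a scheduled onset: linear ramp (35 min) from the
current baseline to a 32 °C peak, 15-min plateau, exponential decay back to
baseline (τ = 15 min, the shape being otherwise unspecified). Events recur
at 1–3-day integer intervals; onset hours are normal (mean 16:00 local
solar, sd 1.5 h) clipped to the 05:00–20:00 window in which such events are
observed. The implanted onsets are returned as ground truth. Onset-to-onset
intervals therefore live in [1 − 15/24, 3 + 15/24] days; the generator
contract test uses exactly that envelope.

**Dart-tag cohorts.** Releases uniform in 35–41°N; each recapture is south
of 25°N with the configured probability, otherwise between 25°N and 0.1°
south of release, so simulated cohorts pass the southward filter by
construction.

What the generator does **not** emulate: mesoscale oceanography, prey
fields, behavioural thermoregulation dives after events (off by default),
tag failure/attrition, or fishery-driven recapture bias. Passing tests on
synthetic data therefore demonstrates that the estimators recover what the
generating model encodes — not that real tags are free of unmodelled errors.

## Geolocation

**Twilights.** Centred rolling *median* (10 min) of log light, threshold at
0.3 of the sensor range. A maximal above-threshold run counts as a day only
if it lasts 4–20 h and is bracketed by ≥ 60 min of darkness on both sides;
this rejects fragments created by deep dives or by the record ends. The
median makes crossings exactly robust to dives shorter than half the window.

**Template fit.** Longitude from local noon (dawn/dusk midpoint); latitude
solves the sunrise equation at the *calibrated* sun altitude — the elevation
at which the logistic light model crosses the detection threshold,
including attenuation at a nominal 3 m twilight depth (≈ −8.1°). Latitude is
flagged invalid within |δ| < 3° of the equinoxes (template-fit latitude
variance diverges as δ → 0; window width configurable) and its observation
sd inflated from 1.0° to 20°. Default observation sds (lon 0.5°, lat 1.0°,
SST 0.3 °C) are typical archival-tag magnitudes, all in `GeoConfig`.

**Smoother.** State (φ, λ); identity transition with isotropic process noise
σ km/√day converted to degrees at the current latitude; observations fused
per day by an unscented transform (Julier symmetric sigma points, κ = 1 —
the only nonlinearity is the bilinear SST lookup, so sigma-point tuning is
uncritical). Innovations in longitude are wrapped to (−180°, 180°]. The
forward pass accumulates the likelihood; σ is fitted by golden-section
search on [10, 300] km/√day (a one-parameter search is more robust than EM
here), and the reported likelihood history is the best-so-far sequence,
hence non-decreasing. Backward smoothing is Rauch–Tung–Striebel, exact for
the identity transition. Divergence (any innovation beyond 6 sd for more
than 3 consecutive days) re-initialises the state at the day's raw estimate
and is logged. Initialisation uses the release position when known, else
the first valid raw estimate, with a 2° prior sd.

On the 250-day synthetic benchmark the smoothed track's median great-circle
error is ~45 km, and removing the SST stream roughly triples the
equinox-window latitude error — both recomputed by `scripts/acceptance.py`.

**Grid oracle.** The same observation likelihoods on a 0.5° grid with a
Gaussian random-walk kernel applied as a separable blur, forward–backward.
It exists to validate the UKF (they agree to within two grid cells on > 90 %
of days in tests), and to show expected no-information behaviour (posterior
spread grows monotonically from release).

## Thermal physiology

Daily bins are UTC midnight, not local: positions (hence local time) are
estimates, and UTC binning is reproducible. Local solar time is used only
for event onset hours.

The event threshold is derived, never tuned: 35 °C red-muscle limit minus a
4 °C muscle-to-peritoneum gradient = 31 °C. Runs of body temperature ≥ 31 °C
are merged across dips shorter than 10 min and discarded below 1 min
(noise guards; the physiological criterion is the threshold itself). Onset
tracing walks backward from the threshold crossing along a 5-min centred
moving average while the backward difference stays positive, bounded at
120 min; half a smoothing window is added back to the stopping time (the
centred average advances the apparent foot of a ramp by w/2), so an
instantaneous step yields onset = crossing and a clean ramp its true foot.

Monthly means are flagged spawning-suitable when mean ≥ 24 °C. The lethal
flag marks months *in contact with* the 18 °C limit — mean minus one daily
sd ≤ 18 °C — rather than mean ≤ 18 °C, because winter monthly means in this
system sit marginally above the limit (minimum monthly mean ≈ 18.2 °C) while
individual days dip below it; a strict mean threshold would miss exactly the
months the limit is constraining.

UPGMA clustering is implemented in-repo (naive O(n³), full distance matrix,
size-weighted average-linkage update) because its tie rule must be
deterministic for oracle comparison: ties merge the lexicographically
smallest index pair. Features are (daily max body, daily mean water) in °C
with no standardisation — plain Euclidean distance on those axes. scipy's
average linkage serves as the independent oracle in tests, never as the
implementation.

## Reproduction

GI = G_w/FL³ × 10⁴ and GSI = G_w/B_w × 10². Staging applies, in order:
POF present or MAGO ∈ {GVM, Hyd} → spawning-capable (recent or imminent
spawning overrides the oocyte stage, and germinal-vesicle-migration/hydrated
oocytes mark imminent spawning under standard reproductive-phase criteria
even though the summary criteria table has no such row); MAGO ∈ {Pn, Ca} →
immature; yolked with IA ≥ 50 % → regression; otherwise developmental, with
absent IA treated as < 50 %. The "below minimum mature GI" column is a
report flag (mirroring the empirical observation that fish below the
smallest mature GI are uniformly immature), not a staging rule.

## Cohort summaries

Southward filter: release ≥ 35°N and release − recapture latitude ≥ 0.1°;
decades are assigned from the release date (the only date guaranteed for
every record). The 25°N comparison is strict (< 25.0): a fish exactly on the
boundary has not migrated *into* the southern area. Days at liberty are the
exclusive date difference (recapture − release); the historical tables mix
conventions for pre-2021 releases, and the exclusive form is the one that
reproduces every 2021 deployment. The weighted sd of yearly proportions uses
the population form (Σw(p−m)²/Σw); with recapture counts as weights the
weighted mean is algebraically the pooled proportion, which tests verify to
1e−12.

## Problem sizes and determinism

Default analyses run at the tags' native 30-s sampling. The package's own
benchmarks use a 250-day migrant track for geolocation, 20 implanted events
for detection scoring, 50 × 200-point sets for the clustering oracle and
1000 random partitions for the weighted-proportion identity; unit tests
reuse session-scoped scenario fixtures at coarser (1–2 min) sampling. All
randomness flows through `numpy.random.default_rng` seeds; identical
configurations produce byte-identical pipeline artifacts.

## Known limitations

- Template-fit latitudes inherit any miscalibration between the light
  model's threshold elevation and the real sensor response; the SST match
  compensates only where the field has a usable meridional gradient (not in
  saturated tropical water).
- The smoother's process noise is a single isotropic σ; strongly anisotropic
  movement (fast directed transits) is absorbed rather than modelled.
- Event detection keys on a fixed 31 °C threshold; fish whose baseline
  excess differs from the assumed gradient would need the threshold
  revisited.
- The residence scenario's home-range drift is a parsimonious stand-in for
  temperature-following behaviour, not a behavioural model.
- Monthly flags summarise experienced temperature only; they do not model
  fishery effort, sex, or size structure.
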