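# Methods

This note records the models implemented in `whaletrack`, their assumptions,
the numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate.

## Detection

The B call of the northeast Pacific blue whale is a long tonal call whose
first harmonic sweeps down nearly linearly from ~15.7 Hz to ~14.4 Hz over
~10 s.  Spectrograms use a 2-s Hann window with 80% overlap (0.4-s frames,
0.5-Hz bins), median-subtracted per frequency to suppress stationary noise.
The detection kernel places, at each of 26 lags spanning 10 s, a
second-derivative-of-Gaussian profile across frequency centred on the
instantaneous call frequency with a 0.5-Hz bandwidth; this yields negative
side bands and an (analytically) zero-sum kernel.  On the discrete frequency
grid the residual column means — of order 10⁻⁸ of the peak weight, since the
profile is Gaussian-smooth and integer-sampled in bandwidth units — are
subtracted so the zero-sum property holds to machine precision.

The recognition score is log₁₀ of the kernel–spectrogram inner product,
floored at 10⁻⁶ to avoid −∞.  The absolute score scale is arbitrary; we fix
it by rescaling the normalized spectrogram so its 90th percentile equals
one.  The default threshold (2.2) and the 10-s minimum peak separation are
configuration values; when the score scale is recalibrated for a new
dataset the threshold should be recalibrated with it, using the precision
module.  Equal peaks within the exclusion window keep the earlier peak, so
output is deterministic.  Whether the reference detector normalized its
cross-correlation per frame is not documented; the raw inner-product form is
used here.

## Precision calibration

B-call occupancy is strongly seasonal.  Under two assumptions — the
false-detection rate is constant through the year, and whales do not call
outside the calling season — the excess of the calling-season detection rate
over the non-calling rate estimates the true-positive rate, so per
recognition-score bin

    precision = (r_c − r_nc) / r_c .

The calling season is inferred per station from 5-day bins: bins are sorted
by their count of strong (score ≥ 6) detections, descending with ties to the
earlier bin, and the smallest prefix holding 98% of strong detections is
labelled calling.  Rates divide counts by days of data coverage per season,
not calendar span, so record gaps do not bias them.  Negative raw precision
(possible when the noise climate varies) is clipped to zero with a warning;
bins with no calling-season detections are flagged undefined rather than
zero.  Score bins are half-open `[lo, hi)` with default edges
2.2, 2.5, 3, 3.5, 4, 4.5, 5, 6, ∞.

## Travel times and geodesy

All localization uses a single cubic travel-time-versus-range curve, valid
to 300 km.  The default is an isospeed curve `t = d / 1.48 km s⁻¹`; a
site-specific curve (e.g. fitted to ray-trace samples through a measured
sound-speed profile) can be supplied as coefficients or as (range, time)
samples, to which a least-squares cubic is fit and validated for
monotonicity.  Model uncertainty defaults to a linear ramp from 1.25 s at
75 km to 2.5 s at 150 km, constant outside.  Ranges are great-circle
distances on a 6371-km sphere — whale depth (tens of metres) is negligible
against ranges of tens of kilometres, and the geodesic convention of the
reference dataset is not documented, so the spherical form is assumed.
Local Cartesian work (covariances, smoothing, relocation) uses an
equirectangular tangent frame centred on the object of interest.

## Localization

Each detection with true-positive probability ≥ 0.9 is tried as a master
detection, interpreted as the earliest arrival of its call.  Candidates are
detections with p ≥ 0.2 arriving within (0, 100 s] after the master on
stations within 150 km of the master's station; later detections on the
master's own station are excluded since the master is by construction the
earliest arrival in the solution.  Detection-time uncertainty is a step
function of probability: 2.0 s (p ≥ 0.9), 2.5 s (≥ 0.8), 3.0 s (≥ 0.5),
3.5 s below.

Method 1 evaluates, at every grid node, the product over candidate stations
of the best-matching candidate's Gaussian misfit term, floored at
`q_small = e^{−4.5} ≈ 0.011` so stations whose detections cannot fit do not
dominate, marginalized by trapezoid over the master origin-time misfit t′ in
±3σ₁₁ at 0.25-s steps.  Stations with no candidates at all are excluded from
the product entirely — a global per-station floor would make the surface
depend on network size.  Method 2 instead counts stations whose best
candidate fits within m′ = 3 standard deviations (the normalized-residual
form; the printed σ² normalization is dimensionally inconsistent with the
likelihood and is not used), each weighted by the candidate's probability
over the station distance floored at R = 50 km, gated at ≥ 4 fitting
stations; the same t′ grid is searched jointly.

Both methods yield a fitting subset — per station, the candidate with the
smallest normalized residual, kept if ≤ 3σ.  A spatial posterior is built
from just these detections on a fine local grid (0.005° lat × 0.01° lon)
around the search argmax, normalized with latitude-dependent node areas.
The fitting subset is then re-selected at the refined most probable point
and the posterior recomputed until the subset is stable; selecting it once
at a coarse search node would shift residuals by up to ~1σ and spuriously
drop detections near the 3σ boundary.  The posterior window (default ±25 km)
expands, up to a cap, whenever the 95% region reaches its edge, so a
boundary rejection reflects a genuinely unbounded solution rather than an
undersized evaluation window.

The most probable point is refined by bicubic spline interpolation of the
5×5-node neighbourhood of the argmax on a 100-m lattice; the mean and 2×2
covariance come from quadrature in the local km frame.  A solution is
discarded when the 95% highest-density region (8-connected) has more than
one component or touches the grid boundary, or when the covariance's largest
1-σ axis exceeds 20 km.

The search surface is restricted to nodes within 150 km of the master's
station — the same feasibility radius applied to candidate stations.  Grid
spacings are configuration: the tests and synthetic experiments run the
search at 0.03° × 0.045° (≈ 3.3 km) with the posterior at the fine default,
which keeps a full localization near 0.2 s without changing any statistical
conclusion (a finer search grid was verified not to change the track-level
results).

### Calibration

On 500 synthetic calls with per-bin Gaussian timing noise and no false
positives (8×8 network at the 35-km slope spacing), the squared Mahalanobis
distance of the truth from the posterior mean has mean 2.0 — the exact
expectation for a calibrated 2-D posterior.  The fraction inside the 95%
confidence ellipse is ~0.94 rather than 0.95 because the travel-time model
is weakly nonlinear, so the posterior has slightly non-Gaussian tails; the
corresponding test asserts the one-sided binomial bound appropriate to a
finite coverage sample.  Pooled normalized residuals of fitted detections
have standard deviation ≈ 0.91, consistent with three fitted parameters per
call absorbing part of the noise.

## Tracks

Localizations are deduplicated (a solution whose fitted set is a subset of
an earlier-kept master's is a repeat), grouped by a space–time filter (a
location within 10 km and 15 min of ≥ 4 others seeds a group, expanded
iteratively), and groups ≤ 1 h apart are merged when ≥ 4 locations of one
lie within 20 km of 4 of the other, iterated to a fixed point.  Grouping
distances use the most probable points; input ordering is fixed (origin
time, then master id) so the result is deterministic.

Because the ~50-s ABB call spacing is comparable to the inter-station travel
time at 70-km spacing, spurious localizations that mix successive calls are
common.  They are dissolved iteratively: detections appearing in tracks of
at least 25 (then 15) locations are assigned to the specific location —
i.e. master — they belong to (ties: biggest track, then earliest), and the
localization pass is repeated with assigned detections excluded from every
other master; a master itself assigned elsewhere is not retried.  Locking to
the location rather than merely to the track is what prevents detections of
call *n* from re-entering solutions for call *n+1* of the same whale.
Assignment uses method 2 and the final pass method 1 by default; both are
selectable.  After the final grouping each detection is kept in at most one
track (largest first).

Track reliability diagnostics per the reference practice: per call, stations
ranked by range are labelled included (in the fitted set) or
missing-with-activity (≥ 1 detection between 60 s before and 120 s after the
first fitted arrival); a reliable track keeps the cumulative included/missing
ratio above one out to ~75 km and has ≥ 20 locations, and its
inter-call-interval histogram peaks at a song cadence (~50 s ABB, ~120 s AB).

## Smooth paths

For calls i−1, i, i+1 with origin times O, the smoothing constraint
`(1−w)x_{i−1} − x_i + w x_{i+1} = 0`, `w = (O_i−O_{i−1})/(O_{i+1}−O_{i−1})`,
is weighted by `1/(O_{i+1}−O_{i−1})` (uniform penalty on acceleration) and
`1/min(w, 1−w)` (geometry sensitivity of the central call).  The constraints,
scaled by a smoothing weight α, are stacked against covariance-whitened
location misfits and solved by iterated least squares (convergence when the
largest coordinate update is < 10 m).  α descends a log-spaced schedule
(10⁸ → 10³, 4 steps per decade) until the mean squared normalized spatial
misfit reaches its two-degree-of-freedom expectation of ~2; at each α, calls
whose misfit exceeds the χ²(2) 99% quantile (9.21) are removed — cumulatively
— and the fit repeated.  As α → ∞ the path tends to uniform-velocity
interpolation; as α → 0 it returns the raw locations.

The pooled misfit statistic for tracked calls uses squared residuals,
`s² = ΣΣ (T−T^pred)²/σ² / ΣM_j` (the printed reference form omits the square
but is described as a variance), with expectation `Σ(M_j − 3)/ΣM_j`
counting the three parameters fitted per call — the per-call form reproduces
the reference's worked expectation (≈ 0.74 for M ≈ 6.5), which a single
global parameter count would not.

## Double-difference relocation

For nearby calls j, l sharing station i, the double difference
`d = (T_ij − T^pred_ij) − (T_il − T^pred_il)` cancels travel-time model
error common to the two paths.  Each call links to up to 8 later calls
within an hour having ≥ 4 common stations.  The linearized system in
position and origin-time shifts, with partial derivatives from the curve
slope along the station-to-call unit vector, is weighted by 1/σ_d with
σ_d² the sum of the two detection-time variances, stacked with the β-scaled
smoothing constraints, and solved iteratively (5 iterations per β, each β
restarted from the raw locations); after 3 iterations, differences with
|misfit| > 3σ_d are dropped — which is also how spurious detection times
reveal themselves.

Difference times constrain only relative geometry: uniform translations (and
a uniform origin-time shift) are near-null modes of the stacked system, two
to three orders of magnitude below the leading singular values.  Singular
values below 5% of the largest are truncated, pinning the absolute position
to the starting locations; without this, least squares amplifies noise along
the translation modes into multi-kilometre drifts.  Origin-time shifts are
otherwise neither bounded nor damped.

## Synthetic data

The generator reproduces the study conditions: quasi-regular lon/lat
networks at 70 km (deep water) or 35 km (slope) spacing; constant-velocity
whales at 2–4 km/hr; ABB songs with successive B calls ~50 s apart (an A
call interleaved before each pair without pausing the B cadence) or AB songs
at ~120 s, with 2-s timing jitter; arrival times equal to origin plus the
travel-time curve plus Gaussian noise at the σ(p) of the assigned score bin;
a recognition-score proxy `10 − 3.3 log₁₀(r) + N(0, 0.6)` mapping received
level into the calibration bins; logistic detection probability in range
(midpoint 100 km, width 15 km); and station-wise Poisson false positives per
score bin at the reference non-calling daily rates (~1036/station-day
total).  Waveform synthesis provides B-call chirps and pulsed near-constant
A-call confusers for the detector round trip.  All randomness flows through
one integer-seeded generator; a fixed seed reproduces a scene exactly.

What the generator does **not** emulate: propagation loss and multipath,
depth effects, clustered or wandering song cadences, nonstationary noise,
earthquake and fin-whale interference, or spatially correlated false
positives.  Passing tests therefore demonstrate the pipeline's statistical
behaviour under its own model assumptions, not field performance.

## Problem sizes in the test suite

The test experiments use: 500 isolated calls on an 8×8/35-km network for
posterior calibration; three 2-h single-whale ABB scenes on 4×4/70-km
networks with full false-positive rates for end-to-end track recovery
(pooled, since a single ~140-call scene estimates a 90% recovery rate with
±3% binomial error); 150-call tracks for smooth-fit calibration; and
36-call tracks with a 1.44 vs 1.48 km/s speed mismatch for the
double-difference comparison.

## Known limitations

- Method 1 rewards fitting more detections (each station above the floor
  multiplies the likelihood by ~1/q_small ≈ 90), so with several false
  positives in the window a wrong node fitting more stations can outscore
  the true location; the track iteration recovers most but not all such
  calls (~90% of localizable calls end in the reliable track under the
  synthetic conditions above).
- The master-detection scheme conditions candidate inclusion on arriving
  after the master, slightly truncating near-tie stations' noise; the effect
  on calibration is within the binomial resolution of the tests.
- Season inference requires strong detections; a station with none cannot be
  calibrated (an explicit error, not a silent default).
- The CLI covers the simulate → track path for single-channel CSV waveforms
  and detection logs; waveform container formats (miniSEED/SAC) are out of
  scope — records are plain sampled arrays with a stated rate.
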