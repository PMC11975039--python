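# Methods

`vimreach` implements a peri-reach analysis chain for single-unit
recordings from cerebellar-receiving motor thalamus (VIM) during a 3D
center-out-and-back reaching task, together with a synthetic-session
generator that provides ground truth for every stage. This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic tests do and do not establish about real data.

## The task and the synthetic session generator

The task presents a central target and 8 outer targets evenly spaced on a
circle of radius 178 mm (target diameter 30 mm) in the display plane. Each
trial shows the center for 3 s, overlays a 0.7 s directional cue, then
shows the outer target for 3 s; the center re-display is the go cue for
the return reach. Outer targets cycle in a load-balanced pseudorandom
order (a fresh permutation of the visible set per cycle) until at least 24
out-and-back sequences — 48 reaches — are scheduled.

The generator (`vimreach.synthetic`) builds three layers:

1. **Movement.** Holds at target positions joined by point-to-point
   minimum-jerk segments. Minimum jerk is chosen because its speed profile
   is smooth, unimodal and analytically known (peak speed
   `1.875·distance/duration`), which makes the reach detector's crossing
   and 5%-of-peak rules exactly testable. Reach durations are lognormal
   (median 0.8 s, log-sd 0.15, matching the ~800 ± 250 ms durations typical
   of this task); reaction times are uniform on 150–400 ms, placeholders
   exposed in `MotorParams` since subjects' true reaction-time statistics
   are not constrained by the task description.
2. **Tremor.** Essential-tremor patients tremble in the 4–12 Hz band.
   The default model is stochastic narrowband tremor — Gaussian noise
   band-passed to 4–12 Hz, independent components on the three axes, total
   RMS matched to a 2 mm sinusoid — because patient tremor wanders in
   amplitude, phase and direction; a pure single-axis sinusoid
   (`tremor_model="sinusoid"`) is retained for controlled detector tests.
   A pure tone also creates a periodic ambiguity in lag estimation
   (correlations repeat every tremor period) that real tremor does not
   have. Tremor is applied during holds by default;
   `tremor_during_movement=True` models action tremor, the defining
   phenotype of the patient population. Tremor belongs to the *movement*
   (clean) trajectory: the neurons see it. White positional noise
   (0.3 mm sd) and dropped frames (p = 0.01) form the measurement layer on
   top.
3. **Spiking.** Each unit is an inhomogeneous Poisson process sampled by
   thinning. Its intensity is
   `drift(t) · max(0, baseline + Σ_f w_f·z_f(t − lag) + direction term)`,
   where `z_f` are session-z-scored kinematic/error features of the clean
   trajectory, `lag` follows the analysis convention (positive = neural
   activity follows kinematics), the direction term is
   `gain · (reach direction · preferred direction)` during reaches, and
   drift is a one-cycle-per-session multiplicative gain emulating slow
   electrode drift. Baseline 20 spikes/s is representative of VIM units
   (~20 ± 15 spikes/s).

All randomness derives from a single master seed through fixed stream
keys (task, trajectory, per-unit, per-test), so a session is a pure
function of (config, params, seed) and adding a unit perturbs nothing
else.

What the generator does **not** emulate: video/markerless-tracking error
structure (correlated, occlusion-driven dropouts rather than Bernoulli),
submovements and corrective jerks, non-Poisson spiking (refractoriness,
bursting), tremor-locked spiking, and behavioral lapses. Passing tests
therefore establish correctness of the *pipeline* under a clean generative
model, not performance claims about intraoperative recordings.

## Kinematics

Dropped frames are linearly interpolated between the nearest valid
neighbours; leading/trailing invalid runs are never extrapolated — they
stay masked, as does anything within one kernel half-width of them. Each
coordinate is convolved with a unit-sum Gaussian kernel truncated at
±4 sd (50 ms sd for peri-reach rate analyses, 15 ms for regressions),
with edge-value extension so constants are preserved to the array ends.
Velocity is computed by central differences on the native 120 frames/s
grid, acceleration by applying the same operator to velocity. Signed
acceleration is `‖a‖·sign(v·a)` — positive while the hand speeds up along
its path, negative while braking; this scalar equals `sign(d‖v‖/dt)·‖a‖`
wherever v ≠ 0, which is the property that separates acceleration from
deceleration phases.

## Reach detection and curation

Fingertip speed is zero-phase low-pass filtered (4th-order Butterworth,
3 Hz cutoff, forward–backward) to suppress 4–12 Hz tremor before peak
picking; the same filter is applied to the 3D velocity used downstream.
Per trial: the speed peak is found in −0.5…+2.5 s around target display;
the dominant reach direction is the mean velocity in a 0.5 s window
around the peak; velocity from ±2 s around the peak is projected onto
that direction. Reach Start is the last time before the peak at which the
projected velocity becomes positive (the first positive sample of a
crossing) or shows a local minimum below 5% of its peak value; Reach End
mirrors this after the peak. Trials with no qualifying start or end are
invalid (`undetectable`).

Detection runs on the **15 ms-smoothed** features. The 50 ms kernel,
appropriate for rate visualization, smears movement onsets roughly five
samples early; with light smoothing plus the 3 Hz filter the detector
recovers noiseless minimum-jerk onsets/offsets within one sample
(8.33 ms) and stays within two samples under 2 mm, 5 Hz hold tremor.

Curation removes duration outliers above Q3 + 1.5·IQR (quantiles by
linear interpolation between order statistics — the convention matters
and is fixed here) and flags sessions with fewer than 25 valid reaches.

## Firing rates

Rates are estimated by the fractional-interval method on a 1 ms grid: the
rate within an inter-spike interval of length L is 1/L, so every interval
integrates to exactly one spike. Implementation integrates the
piecewise-linear cumulative spike-count function, which yields the
duration-weighted mixture in bins straddling a spike automatically and
preserves `∫rate dt = count − 1` over the spike span exactly; bins beyond
the first/last spike extend the adjacent interval's rate. Gaussian
smoothing (50/15 ms) follows on the same grid; evaluation at arbitrary
times is linear interpolation between bin centers. For regressions, a
sliding 45 s centered z-score (partial windows at the edges, sd floor
10⁻⁶ spikes/s, zero-variance windows set to 0 and flagged) removes slow
drift. Z-scoring is applied after smoothing; the order is exposed in the
API since either reading is defensible.

## Peri-reach grid, modulation and tuning

Each reach contributes 380 grid samples: 150 pre samples at 10 ms steps
over [−1.5 s, start), 80 evenly spaced in-reach samples inclusive of both
endpoints (spacing duration/79; a `midpoint` convention is available),
and 150 post samples over (end, +1.5 s]. Alternative alignments
(`realtime`, `cue_aligned`, `go_aligned`, `peak_aligned`) sample at fixed
10 ms steps around their anchor. The analysis window covers −400 ms to
+400 ms (160 samples).

The modulation test compares the across-reach mean rate at each grid
sample with a shuffle baseline: 10,000 means of `n_reaches` rate values at
uniformly random times over the entire recording (reach epochs included,
deliberately). Empirical p-values use add-one smoothing ((r+1)/(n+1));
two-sided α = 0.01 is the union of the two 0.005 tails. Same-sign
significant runs shorter than 5 samples (50 ms) are rejected, and a unit
is modulated only if a surviving run intersects the analysis window.

**Calibration caveat.** Per-sample calibration of this test is correct
(~1% of samples significant for stationary units), but the *unit-level*
false-positive rate is substantially above 1%: the 50 ms kernel gives the
mean-rate curve an autocorrelation time τ ≈ 71 ms, so by the Rice
upcrossing formula a stationary unit produces ≈ 0.6 chance |z| > 2.58
excursions across the 3.8 s grid with mean duration ≈ 61 ms — longer than
the 50 ms contiguity requirement. Simulation (500 stationary Poisson
units) puts the unit-level false-positive fraction at 11–14%, essentially
independent of baseline rate. The contiguity rule would control the
unit-level rate only if adjacent samples were independent, which the
smoothing kernel precludes. The same applies a fortiori to the tuning
test at α = 0.05 (~45% null tuned fraction). Fractions of "modulated" or
"tuned" units produced by these criteria should therefore be read as
liberal screening calls, not family-wise-controlled counts.

Directional tuning uses a tie-corrected Kruskal–Wallis test across
reach-direction groups at every grid sample (vectorized over samples;
verified against `scipy.stats.kruskal`), with outward reaches to a target
pooled with inward reaches from the diametrically opposite target (same
movement direction), groups under 3 reaches dropped, and the same
contiguity/window rule (α = 0.05; a p < 0.01 severity grade is retained
per sample). Spatial heatmaps average the rate in 15 mm cells of the
top-two-PC plane of 3D fingertip position.

## Encoding models

Regressors are 15 ms-smoothed features at native kinematic times within
250 ms before each valid Reach Start to 250 ms after its Reach End:
3D position, 3D velocity, speed, 3D acceleration, acceleration magnitude,
signed acceleration (12 columns, 6 groups), optionally plus 3D error and
error magnitude (16 columns, 8 groups). The error vector is instantaneous
position minus the mean position 0–1 s after that reach's end — the early
hold over the cued target, a proxy for the goal; reaches whose hold window
leaves the recording are dropped from error-set samples. Columns and
response are centered and scaled to unit sd over the concatenated sample;
zero-variance columns are dropped first; rank-deficient designs drop the
dependent columns with a warning.

OLS is fit at 241 lags (±1 s in steps of one kinematic sample, 1/120 s ≈
8.33 ms), response = rate evaluated at `t + lag` (positive lag: neural
activity follows kinematics). R² is computed from the design's cached
orthonormal (QR) basis; adjusted R² uses the Ezekiel correction
`1 − (1−R²)(n−1)/(n−p−1)`; the optimal lag is the R² argmax.

**Significance** uses a circular-shift null: the 1 ms rate register is
rotated by a random integer offset spanning the entire recording
(wrap-around) and the regression is refit. Because a rotation is a fixed
interpolation stencil applied at shifted positions, the sufficient
statistics (Qᵀy, Σy, Σy²) for *every* possible rotation are circular
cross-correlations of the rate (and its square and lag-one product) with
scattered stencil weights, computed exactly by FFT; nulls are then free
lookups. A slower `continuous` variant (real-valued offsets, clamped
interpolation at the wrap seam) exists as a cross-check; the two differ
only at seam samples.

By default each null draw mimics the full analysis — rotate, sweep the
same lag grid, take the maximum R² — so the observed best-lag R² and the
null draws are exchangeable under the null and the resulting p-values are
uniform for response-independent units (verified by KS test at 200 units).
The cheaper single-lag-at-optimum null
(`account_for_lag_selection=False`) ignores the selection of the best lag
over ~241 correlated lags and inflates the unit-level false-positive rate
several-fold; it is kept because it is the more literal reading of the
procedure. Windowed regressions (500 ms windows centered on Reach Starts
or Reach Ends, zero lag, α = 0.05) have no lag selection and use the
single-lag null.

**Shapley attribution.** The full-model R² is decomposed exactly over
regressors: the value of column i is the average over all orderings of
its marginal R² gain, `Σ_S |S|!(p−|S|−1)!/p!·(R²(S∪{i}) − R²(S))`. Subset
R² values come from the correlation matrix of the normalized design
(solve per subset, batched by subset size; least-squares fallback keeps
R² well-defined for collinear columns), not from refits on raw samples —
verified equivalent to brute-force refitting to 10⁻⁸. Enumeration is
exact and refuses p > 20. Values sum to the full R² (efficiency), equal
squared simple correlations for orthogonal designs, and 3D groups sum
their component columns.

## Lag identifiability

A finding from the synthetic studies worth stating explicitly: the
precision of the optimal-lag estimate is governed by the bandwidth of the
kinematics, not only by R². Minimum-jerk reaches alone (~1 Hz content)
identify lag only to roughly ±50 ms regardless of firing rate, because
the R²(lag) curve is nearly flat near its peak. Movement-band tremor
content (4–12 Hz) sharpens the curve; with action tremor present and the
response in the moderate-fit regime (R² ≈ 0.1), lag recovery reaches the
one-sample level for rate-trace responses. Poisson spiking at
physiological rates (~20 spikes/s) additionally low-passes the tremor
band (inter-spike intervals ≈ 50 ms), which degrades lag recovery to
~2–4 samples; interpreting single-unit optimal lags at one-sample
resolution therefore presupposes substantial movement-band drive.

## Summary statistics

Phase-bias comparisons are chi-square goodness-of-fit tests of
significant-sample counts against expectations proportional to the
number of tested samples per phase (the construction consistent with a
near-equal two-phase split being only marginally significant). The
two-proportion comparison is the pooled two-sided z-test
(statsmodels). Rank-sum comparisons use the exact Mann–Whitney
distribution for small tie-free samples and the tie-corrected normal
approximation (no continuity correction) otherwise. Onset/end-time
densities are Gaussian KDEs with Silverman bandwidth by default.

## Pipeline and reproducibility

`run_pipeline` executes features → reaches → rates → peri-reach tests →
encoding → report on a plain-text session bundle (CSV/YAML/JSON; times in
seconds, positions in mm, x rightward, y upward in the display plane, z
toward the subject). Every Monte-Carlo stage draws from a stream derived
from the master seed and the unit index, so outputs are byte-identical
across reruns. A manifest records the package version, seed and a config
hash. Sessions failing curation are reported and skipped, not raised.

Default problem sizes used by the test-suite simulations: one
24-sequence session (48 reaches, ~168 s), 10,000 shuffles/shifts for
single-unit analyses, 500 null units for modulation calibration, 200 for
encoding-null calibration (1,000 shifts each), and 20 units for the lag-
and error-recovery studies; these sizes give Monte-Carlo error comfortably
below the tolerances being checked.

## Known limitations

- Unit-level modulation/tuning calls are anti-conservative by
  construction (see the calibration caveat above).
- The Kruskal–Wallis χ² approximation is used at all group sizes (groups
  with < 3 reaches are dropped, but small-group p-values remain
  approximate).
- The generator's error signal is defined relative to the true goal
  position; real estimates of goal position from post-hoc hold means are
  only approximate when subjects point inaccurately.
- Exact Shapley enumeration is O(2^p); p > 20 is refused rather than
  approximated by sampling.
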