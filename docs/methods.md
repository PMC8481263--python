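# Methods

## The measurement being modelled

A single-spot proton beam is delivered to a prostate phantom holding an
endorectal balloon (ERB).  For beams energetic enough to pass the
prostate and rectal wall, the Bragg peak lands inside the balloon; if
the balloon is filled with a silicon-dioxide/water mixture, inelastic
reactions on ²⁸Si emit a prompt gamma line at 1.78 MeV.  A CeBr₃
spectrometer (3.49% FWHM energy resolution at the 661.7 keV Cs-137
reference) records the prompt-gamma energy spectrum; a scintillating
beam trigger provides time of flight, and a segmented BGO annulus
provides anticoincidence Compton suppression.  The analysis decides,
per measurement, whether the 1.78 MeV line is present, and calibrates
its area against the Bragg-peak-to-phantom-end distance `d_end`.

## Detection model

Within E ∈ [1.58, 1.84) MeV (inclusive-left on bin centres; 65 bins on
the default 4 keV axis) the spectrum is modelled as a constant plus
Cauchy-Lorentz lines,

    f(E) = c + Σⱼ Aⱼ γⱼ² / ((E − mⱼ)² + γⱼ²),

with amplitude Aⱼ the peak height and γⱼ the half width at half
maximum.  The restricted model carries the oxygen line only (4
parameters), the unrestricted model adds the silicon line (7
parameters).  Both are fitted by unweighted least squares; the F
statistic ((SSR_r − SSR_ur)/q)/(SSR_ur/df_ur) with q = 3 is compared to
the (1 − α) quantile of F(3, df_ur) at α = 10⁻⁴.

Degrees of freedom.  With 65 observations and 7 estimated parameters
the residual degrees of freedom are df_ur = 58, and that is the
default.  The originally reported bookkeeping gives df_ur = 65 − 6 = 49, which cannot
be reconciled with its own parameter counts (a 4-parameter restricted
and 7-parameter unrestricted model differ by q = 3, not 15);
`DetectionConfig(df_convention="printed")` reproduces the printed
bookkeeping for comparison.  At these sample sizes the critical values
differ by ~3% (8.40 vs 8.69) and no campaign decision changes.

Fit protocol.  Centroids are box-constrained within ±0.05 MeV of the
known de-excitation energies (1.635, 1.78 MeV) — a calibration-level
tolerance — and widths within γ ∈ [0.009, 0.05] MeV, a factor-two band
around the expected detector width (~0.018 MeV at these energies).
Amplitudes are unconstrained in sign, so the null hypothesis is not on
a boundary.  The unrestricted fit starts from the restricted solution
with zero silicon amplitude; the fitter only ever accepts
SSR-decreasing steps, so the nesting SSR_ur ≤ SSR_r is guaranteed
numerically, and a negative F numerator can only arise from user-mixed
inputs (it is clamped to zero with a warning).

Which vector is fitted.  The fit runs on the raw counts histogram by
default, not the Savitzky-Golay-smoothed vector stored alongside it.
The unweighted-SSR F statistic presumes independent errors; smoothing
correlates neighbouring bins over the filter length and inflates the
null F several-fold (measured up to F ≈ 40 on oxygen-only windows),
which would produce spurious detections.  `data_vector="smoothed"` and
`"subtracted"` (smoothed minus SNIP baseline) remain available.

Null distribution.  Under the oxygen-only null the silicon amplitude
is exactly zero and the second component's centroid and width are
unidentified, so the classical F(3, 58) reference distribution is an
approximation, not an identity.  With the bounded local fit protocol
above, 2×10⁵-replicate Monte Carlo gives a rejection rate at the
0.01% level consistent in magnitude with nominal and a distribution
whose upper quantiles sit ~2-3% low in F (Kolmogorov-Smirnov distance
~0.015 against F(3, 58)).  Wider bounds instead let the extra
component scan the window and inflate the tail.  The
`null_f_values` routine regenerates this calibration; the residual
approximation error is irreducible for any local-fit protocol and is
irrelevant at the F ≫ F_crit separations the campaign produces.

## Dead time, traces, event selection

Traces are modelled as at most three exponentially modified Gaussian
(EMG) pulses — a Gaussian of width σ convolved with a one-sided
exponential of decay τ (fixed shape ratio τ/σ = 3 in the generator) —
plus white noise, each summarised by (area, mode, height) with a joint
adjusted R².  Event filtering accepts fits with adjusted R² at or above
mean − 7.5 sd, pooled per run (a distribution is only meaningful across
events; the pooling choice is a documented assumption).  The
non-paralyzable dead-time correction is applied as live-time scaling
observed/(1 − DT); a rate-form m = n/(1 − nτ) is provided when a rate
and per-event dead time are known instead.  Corrections above the 15%
operating regime warn.  Histogramming uses half-open [low, high) bins
with the last bin closed.

## Spectral processing

Energy calibration is a polynomial through (bin, energy) anchors —
degree 1 with two anchors, degree 2 from three (a mild nonlinearity
correction; higher degrees are rejected to avoid oscillation) — that
must be strictly increasing over the axis and reproduce each anchor to
20 keV.  Savitzky-Golay smoothing defaults to window 9, order 3, which
preserves the ~10-bin-wide peaks at 4 keV binning.  The SNIP baseline
uses the log-log-sqrt transform with a clipping window decreasing from
24 bins to 1; it never exceeds the spectrum and reproduces a flat
continuum to better than 1%.

## Suppression layers

The prompt time-of-flight window (10 ns, inclusive at both ends) and
the BGO anticoincidence veto (companion deposit strictly above 225 keV
arriving after the primary) define four event populations Raw / TOF /
BGO / All with exact set inclusion.  The deposited retention figures
(TOF keeps 13%, BGO 32%, both 6%) are mutually inconsistent under cut
independence (13% × 32% ≈ 4.2%), so the event generator exposes a
`joint_retention` knob that correlates the cuts to match all three
figures at once; the default is independent cuts.

## The synthetic campaign

The generator reproduces the study conditions rather than the physics:

- Campaign table: the 24 tabulated energies (43 measurements; 23 main,
  10 reference + 10 validation) with their `d_end` and target regions.
- Totals: expected raw counts interpolate linearly from 1.39×10⁶ at
  86.72 MeV to 2.13×10⁶ at 128.11 MeV, for the nominal 4.69×10⁹
  protons per run.
- Spectrum: a decaying-exponential continuum (decay constant 3.0 MeV)
  plus Lorentzian lines — 0.511, 1.635 (O), 2.223, 4.44, 5.24 (O),
  6.13 (O) MeV at fixed area fractions — with widths following the
  3.49% fractional FWHM at 661.7 keV scaled as 1/√E.  Per layer, the
  configured retention (Raw 1, TOF 0.13, BGO 0.32, All 0.06) sets the
  total counts and a continuum-rejection factor (1 / 0.60 / 0.45 /
  0.12) reshapes background against peaks, so the suppressed layers
  gain peak prominence (strongest in All) and detection power while
  losing statistics.  Bins are independent Poisson draws; a config
  switch renders Gaussian peaks instead to probe shape misspecification.
- Silicon signal: zero for prostate/rectal-wall hits and in the
  silicon-free handle (d_end 2.4-2.9 cm); for balloon hits it ramps
  linearly from zero at the balloon entry (d_end = 4.6 cm) to its
  maximum at 3.4 cm and saturates beyond.  The default line area at
  full strength is 1% of total counts — phenomenological, calibrated
  only so the campaign-wide detection pattern is reproducible, not
  quantitative.
- The continuum decay and layer rejection factors were likewise fixed
  so the generated spectra share the measured data's two qualitative
  features the analysis relies on: a locally flat background under the
  detection window, and better detection in the suppressed layers.

What the generator does not emulate: nuclear cross sections and
absolute yields, detector nonlinearity (the synthetic calibration is
exact), pile-up at spectrum level, beam-energy spread, or any
correlation between bins.  Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under its own
assumptions, not the physical accuracy of a real campaign.

## Range model

The silicon line area (A·γ·π analytically; a windowed arctan form for
cross-checks) is normalised per delivered proton for cross-campaign
comparisons, regressed on `d_end` by ordinary least squares over the
3.4-4.6 cm band (balloon surface to handle; handle points excluded),
and inverted as d = (area − intercept)/slope.  Agreement is reported
as RMSE in mm; between-campaign reproducibility as the mean relative
error of matched per-proton areas with a symmetric denominator
(|a − b| / ((a+b)/2); a campaign-referenced convention is available).

## Numerical engine

All peak fits share one batched, box-constrained Levenberg-Marquardt
implementation (`_lorentz.py`) with analytic Jacobians and a
per-parameter relative damping ridge.  Batching is what makes the
2×10⁵-window null calibration run in minutes on one core; single
spectra are the batch-of-one case, so there is exactly one code path.
The engine is cross-checked in the test suite against
`scipy.optimize.least_squares` on random windows (restricted SSRs agree
to 10⁻⁷ relative; unrestricted SSRs are never worse).  Monte Carlo
problem sizes in the test suite (e.g. 400 replicates per amplitude in
the power-monotonicity check, 2×10⁵ null windows) were chosen to give
stable statistics at desk scale.

## Known limitations

- The F-test's null reference is asymptotic and approximate (see
  above); at α = 10⁻⁴ the empirical size can sit a factor ~2 below
  nominal under the default protocol.  Decisions are insensitive to
  this because real detections separate from the null by orders of
  magnitude in F.
- Whether the deposited archives' `counts` are dead-time corrected is
  not documented; the reader treats them as-is.
- Which oxygen lines anchored the original fine-tuning calibration is
  unknown; the default anchor set is an assumption.
- No multiple-testing correction is applied across the 43
  measurements, matching the original analysis.
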