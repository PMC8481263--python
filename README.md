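# pgsrange

Prompt-gamma spectroscopy (PGS) analysis for in vivo proton range
verification in prostate treatments, using a silicon-loaded endorectal
balloon (ERB) as a range probe.

## The problem

Anterior proton beams for prostate cancer stop just short of the rectal
wall, and millimetre-level range errors decide whether they overshoot.
When the beam reaches an ERB filled with a silicon-dioxide/water
mixture, proton-induced nuclear reactions on silicon emit a prompt
gamma line at 1.78 MeV next to the ubiquitous 1.635 MeV oxygen
de-excitation line.  Detecting that line in the measured energy
spectrum tells you the beam entered the balloon; quantifying its area
tells you how far.

This package implements the full analysis chain for such measurements
and a synthetic-data generator that emulates the 43-run phantom
campaign the method was characterised on (23 main-campaign energies of
86.72-134.06 MeV plus 10 paired reference/validation energies):

- `dataset_io` — read/write/validate the nested campaign archives
  (energy -> proton count + four suppression layers x five 2048-bin
  arrays), with a portable CSV/YAML export.
- `synthetic_data` — campaign tables, four-layer Poisson spectra with
  a silicon line that ramps with beam penetration, EMG pulse traces,
  and labelled event streams.
- `trace_processing` — EMG pulse fitting (area, mode, height), the
  pooled adjusted-R² outlier cut (mean − 7.5 sd), in-spill selection,
  non-paralyzable dead-time correction, histogramming.
- `spectral_processing` — polynomial energy calibration (Cs-137 anchor
  + oxygen lines, quadratic nonlinearity correction), Savitzky-Golay
  smoothing, SNIP baseline, energy thresholds, photopeak resolution
  fits.
- `suppression` — the 10 ns prompt time-of-flight gate and the 225 keV
  BGO anticoincidence veto, building the Raw/TOF/BGO/All layers.
- `silicon_detection` — the statistical core (below).
- `range_prediction` — Lorentzian peak areas, the linear
  area-vs-distance model, inverse prediction, RMSE in mm, and
  between-campaign reproducibility.

## The statistic

In the window E ∈ [1.58, 1.84) MeV (n = 65 bins at 4 keV) two nested
models are fitted by unweighted least squares:

- restricted: `c + A₁·γ₁²/((E−m₁)² + γ₁²)` — oxygen line only
  (4 parameters),
- unrestricted: the same plus a second Cauchy-Lorentz term at the
  1.78 MeV silicon line (7 parameters),

and compared with

    F = ((SSR_r − SSR_ur)/q) / (SSR_ur/df_ur),   q = 3,  df_ur = n − 7,

rejecting the oxygen-only hypothesis when F exceeds the (1 − α)
quantile of F(q, df_ur) at α = 10⁻⁴ (the 0.01% level).  The
unrestricted fit is warm-started from the restricted solution with zero
silicon amplitude, so SSR_ur ≤ SSR_r holds by construction.  The
silicon line area A₂·γ₂·π, normalised per delivered proton, is then
regressed linearly on the Bragg-peak-to-phantom-end distance over the
sensitive 3.4-4.6 cm band and inverted to predict distances.

## Worked example

```python
from pgsrange import detect_campaign, simulate_campaign

dataset = simulate_campaign("main", seed=0)       # 23 records, ~1.5e6 counts each
report = detect_campaign(dataset, layer="BGO")    # F-test per measurement
print(report[["beam_energy", "f_value", "f_critical", "reject"]].head(3))
```

prints

```
   beam_energy   f_value  f_critical  reject
0        86.72  0.553340    8.403396   False
1        90.70  1.409770    8.403396   False
2        94.54  0.260391    8.403396   False
```

— beams stopping in the prostate leave F far below the critical value,
while for the deepest silicon run of the same campaign
(`report.iloc[16]`, 115.55 MeV) F is 1000.5.  The companion CLI runs
the same chain from a shell:

```sh
pgsrange simulate --campaign main --seed 0 --out main.pkl
pgsrange detect main.pkl --campaign main --layer BGO --report detect.csv
pgsrange rangefit detect.csv --out model.yaml
pgsrange predict --model model.yaml --area 1.2e-8
```

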