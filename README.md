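# gammakit

Spectral analysis and phenomenological simulation of cholinergically induced
gamma oscillations in hippocampal slice local field potentials (LFPs).

Bath application of acetylcholine plus an esterase inhibitor induces
persistent gamma-band (~30–90 Hz) oscillations in the CA3 region of
hippocampal slices; their power, frequency and sharpness are widely used as
network-level biomarkers for the pharmacology of psychiatric drugs. This
package is for electrophysiologists and methods developers who need that
analysis chain as tested, scriptable code — and a synthetic-data generator
realistic enough to validate every stage of it without recorded data.

## What it computes

From each recording, power spectra are estimated every 2 min over a 120-s
window (Welch: 4-s Hann segments, 50% overlap, 0.25-Hz resolution) and
reduced to the gamma-peak metrics

- peak power (µV², tone-calibrated spectrum scaling),
- peak frequency *f₀* (Hz, parabolic interpolation),
- half bandwidth *B* (Hz) — the full width at 50% of maximum peak power,
- quality factor *Q* = *f₀*/*B* — a frequency-drift-insensitive periodicity
  index used when oscillations desynchronize.

Metrics are normalized per slice to a 10-min baseline, aggregated over
cohorts as mean ± SEM (absolute powers: geometric mean with a
back-transformed t confidence interval, since they are log-normal across
slices), and compared between groups with Student's unpaired t test
(normalized metrics) or the Mann–Whitney U test (absolute powers), with
D'Agostino–Pearson K² for normality checks.

The generator produces single slices or whole cohorts: a two-pole resonator
(peak parameterized directly by *f₀* and *B*) on a 1/f background, with
first-order induction, agonist wash-out/re-wash-in, and drug wash-in
kinetics; named condition presets (`naive-saturated`, `naive-nonsaturated`,
`mk801`, …) and drug presets (`pramipexole-30`, `cariprazine-mk801`, …) are
calibrated against published cohort endpoints, including the
MK-801-pretreatment phenotype whose gamma power never plateaus. See
`docs/methods.md` for the model and every calibration constant.

## Worked example

Simulate one slice under the standard drug protocol (induction at 0 min,
pramipexole 30 µM at 100 min) and measure the effect 60 min after drug
onset:

```python
from gammakit import (load_presets, drug_protocol, generate_slice_recording,
                      compute_timecourse, normalize_to_baseline, evaluate_endpoint)

presets = load_presets()
params = presets["conditions"]["naive-saturated"].location_params()
protocol = drug_protocol("pramipexole-30", drug_on_min=100.0, duration_min=160.0)
rec = generate_slice_recording(protocol, params, presets["drugs"], seed=42)

tc = compute_timecourse(rec)                     # one PeakMetrics per 2-min window
ntc = normalize_to_baseline(tc, (90.0, 100.0))   # % of the pre-drug baseline
endpoint = evaluate_endpoint(ntc, at=160.0)      # 60 min after drug onset

baseline = tc.peak_power[(tc.window_start_min >= 90) & (tc.window_start_min < 100)]
print(f"baseline peak power : {baseline.mean():8.1f} uV^2")
for name, value in endpoint.items():
    print(f"{name:>15s} : {value:6.1f} % of baseline")
```

Output:

```
baseline peak power :    467.4 uV^2
     peak_power :   39.9 % of baseline
 peak_frequency :  102.4 % of baseline
 half_bandwidth :  202.0 % of baseline
       q_factor :   49.4 % of baseline
```

The slice developed gamma oscillations with a plateau peak power of
~467 µV²; the D₃-receptor agonist suppressed peak power to ~40% of baseline
and roughly doubled the half bandwidth (halving oscillation periodicity, Q),
while the peak frequency stayed put — the programmed preset encodes exactly
this pharmacological fingerprint.

A command-line interface wraps the same machinery:

```bash
gammakit simulate --protocol protocol.yaml --cohort cohort.yaml --seed 7 --out sim/
gammakit analyze sim/*.dat --out features.csv
gammakit run --config experiment.yaml        # simulate + analyze + compare
gammakit reproduce-paper --seed 7 --out report.csv
```

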