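# Methods

`gammakit` couples a phenomenological generator of cholinergically induced
hippocampal gamma-band local field potentials (LFPs) with the classical
windowed-spectrum analysis used for slice pharmacology, so the whole analysis
chain — spectral feature extraction, baseline normalization, cohort
aggregation, group statistics — can be exercised and validated end to end on
synthetic cohorts whose presets are calibrated to published endpoint values.

## Spectral analysis

Power spectra are computed every 2 min over a 120-s window for the whole
recording. Inside each window the estimator is an averaged modified
periodogram (Welch): 4-s Hann-tapered segments with 50% overlap, giving
0.25-Hz resolution and 59 averages per window. Scaling is tone-exact
("spectrum" scaling): a sinusoid of amplitude *a* µV reads *a*²/2 µV² at its
bin. Broadband power is recovered through the estimator's equivalent noise
bandwidth (ENBW = 1.5 bins = 0.375 Hz for this taper), exposed as
`SpectrumEstimate.total_power()`.

Each window's spectrum is reduced to the gamma-peak metrics:

* **peak power** — the raw spectrum value at the in-band maximum (µV²);
* **peak frequency** *f₀* — the maximum's location, refined by 3-point
  parabolic interpolation on log power (ties break toward the lower
  frequency);
* **half bandwidth** *B* — the full width of the peak at 50% of its maximum
  (FWHM), found by walking outward from the peak to the first crossings of
  half maximum, each crossing located by linear interpolation between bins.
  If a crossing is not reached before the band edge, the edge is used and the
  value is flagged `clipped`;
* **quality factor** *Q* = *f₀*/*B*, a dimensionless periodicity index that is
  insensitive to drifts of the peak frequency itself — used in wash-out
  experiments where the peak both collapses and moves.

The search band defaults to 20–90 Hz: gamma is conventionally 30–90 Hz, and
the 20-Hz lower edge admits ~33-Hz peaks (typical of the MK-801 model) with
margin. "Half bandwidth" is everywhere interpreted as the FWHM; both the
bandwidth column and the *Q* denominator use the same operator.

### Peak-search smoothing (a deliberate estimator choice)

With 59 averages each bin carries ~13–16% standard error. Two small-sample
artifacts follow if the peak is taken naively: the maximum over many noisy
bins overestimates the true peak by ~12–25% (selection bias), and the raw
first-crossing rule then places the 50% crossings too early, shrinking the
measured FWHM by ~15–40% depending on peak width. The pipeline therefore
*locates* the peak and walks the 50% crossings on a 7-bin (1.75-Hz)
edge-aware moving average of the spectrum, while *reporting* the raw spectrum
value at the located bin, which keeps the tone calibration exact. Measured
FWHM then tracks programmed FWHM to within 0–3% across 5–24-Hz widths. The
kernel adds <2% width to a 5.6-Hz peak (boxcar variance 1.75²/12 Hz²).
`find_gamma_peak`/`half_bandwidth` default to no smoothing when called
directly; the pipeline config (`SpectralConfig.smooth_bins = 7`) switches it
on.

A window is flagged **invalid** (metrics = NaN, excluded from baselines and
group means) unless the located maximum (i) is not at a band edge, (ii)
exceeds twice the median in-band power (prominence floor), and (iii) falls
off below 70% of the peak on *both* sides inside the band — a monotone 1/f
background slope never satisfies (iii), so desynchronized windows degrade
gracefully instead of returning background argmaxes.

## Synthetic LFP generator

The generator is phenomenological by design: no conductance-based network
model, no receptor kinetics. It reproduces the *statistical* structure that
the analysis assumes.

**Oscillation.** White noise driven through a two-pole (AR-2) resonator
yields an approximately Lorentzian spectral peak naturally parameterized by
(*f₀*, *B*). The pole radius is `r = exp(-π B / fs)`; the pole angle is
corrected by `cos θ = cos ω₀ · 2r/(1+r²)` so the *response maximum* (not the
pole angle) lands exactly on *f₀*. The analytic FWHM of the calibrated filter
is within 0.4% of the request at gamma frequencies. Synthesis proceeds in 2-s
blocks with piecewise-constant coefficients and filter-state carry-over; all
modulation time constants are ≥ 9 min, so the block discretization is far
below the kinetics' time scale.

**Power calibration.** A slice's `plateau_power` is defined on the *measured*
scale: the driving-noise gain of each block is set so that the analytic
spectrum peak (density × ENBW of the default analysis configuration) equals
the programmed envelope. This decouples spectral shape from power — drug
effects on bandwidth do not silently change peak power — and makes generator
presets directly comparable to published µV² peak powers.

**Background.** 1/f^α noise (spectral shaping of white noise, flattened below
1 Hz), α = 1 and 8 µV RMS by default; present throughout, so windows without
induced oscillation exercise the invalid-window path.

**Kinetics.** All first-order (exponential relaxation toward a target), per
quantity:

| process | target | τ (default) | rationale |
|---|---|---|---|
| induction rise | plateau | 25 min | >97% of plateau at 90 min ("plateau after ~90 min") |
| agonist wash-out | residual_fraction (5%) × plateau | 9.4 min (naïve), 11.2 (MK-801) | calibrated so power reads 6.6% / 8.5% of baseline 40 min after wash-out |
| wash-out peak drift | ×1.162 (naïve) / ×1.09 (MK-801) frequency; ×4.33 / ×3.22 FWHM | shares wash-out τ | so frequency reads ~116% and Q ~27% (naïve), Q ~34.5% (MK-801) at +40 min |
| re-wash-in rise | plateau | 25 min (reuses induction τ) | reproduces ~69%/66% power recovery at +30 min |
| frequency recovery | ×1 | 37.7 min (naïve); effectively none (MK-801) | ~107.5% at +30 min (naïve); "further increased" ~109% (MK-801) |
| FWHM recovery | ×1 | 19.6 min (naïve), 23.8 (MK-801) | Q recovery ~61.5% / ~66.5% at +30 min |
| drug wash-in | preset factors | 15 min | steady state well within a 60-min application |

**Drug presets** are multiplicative steady-state factors on
power/FWHM/frequency with the above wash-in kinetics; two extra fields cover
the MK-801 phenomenology: `growth_factor` scales the runaway growth rate
(0 = arrest) and `fwhm_recovery_scale` scales the FWHM resynchronization τ
(0.41 for cariprazine, calibrated so the normalized Q factor reaches ~98% 30
min after re-wash-in instead of ~66%).

**Runaway growth (MK-801 pretreatment).** Post-plateau power multiplies by
`exp(growth_rate·t)` from 90 min, `growth_rate = 0.0111 /min`, calibrated in
closed form so the cohort-mean normalized power reads ~208% at 160 min
against the 90–100-min baseline (window centers at 95 and 159 min give
`exp(64·g)·drift = 2.08`). Growth accumulates only during the first
continuous induction epoch: whether it resumes after re-wash-in is not
constrained by any published endpoint, and the wash-out/re-wash-in power
recoveries are matched without resumption. Between 90 and 160 min the growth
law is exponential by construction; only the 160-min endpoint is calibrated.

**Slice-to-slice variability.** Plateau power is log-normal with the
published geometry (naïve saturated: ln-location ln 463.6, ln-scale 1.9226,
reproducing the 95% CI [183.5, 1171] at n = 19; non-saturated: ln 43.7,
scale 1.699). Peak frequency jitters normally with SD = printed SEM × √n
(3.9 Hz for the 39.1 ± 0.9 Hz cohort). FWHM jitter is kept at a small CV
(SD 1.5 Hz, truncated at 1.5 Hz): the printed FWHM SEMs would imply a slice
SD larger than the mean, which is incompatible with a Gaussian jitter model
and irrelevant here because within-slice normalization cancels baseline FWHM
spread. Per-slice drug-effect factors carry log-normal jitter (σ = 0.15
power, 0.08 FWHM, 0.02 frequency). The MK-801 absolute plateau power has no
published value ("significantly higher", shown only as a bar on a log axis);
the preset uses a geometric mean of 1400 µV² (~3× naïve), which no endpoint
depends on.

**Determinism.** Every cohort derives all randomness (parameter draws,
effect jitter, drive noise, background) from one seed through a spawned
`SeedSequence` tree; identical configs reproduce byte-identical cohorts.

## Cohort pipeline

Metrics are normalized within-slice to the mean over a 10-min baseline —
the 10 min immediately preceding drug application or agonist wash-out
(90–100 min in the standard protocols), or the matching clock time in
control arms — using valid windows only, and expressed in percent. Endpoints
default to the single 2-min window ending at the stated time (e.g. "at 160
min" = the window starting at 158 min). Group trajectories are reported as
mean ± SEM per timepoint with per-timepoint n (invalid windows are excluded,
never imputed; SEM is 0 by convention at n = 1). Absolute peak powers are
summarized as geometric mean with a back-transformed t interval on the log
values.

## Statistics

Normalized metrics: Student's unpaired two-sample t test (pooled variance —
the equal-variance form, not Welch). Absolute powers: Mann–Whitney U
(U = min(U₁, U₂); exact enumeration for pooled n ≤ 12 without ties,
tie-corrected normal approximation otherwise, mid-rank ties). Normality:
D'Agostino–Pearson K² (requires n ≥ 8). All tests two-sided at α = .05; no
multiple-testing correction (none is used in this literature for these
designs). The implementations wrap `scipy.stats`; the test suite validates
them against exact enumeration, closed-form hand calculations, and
Monte-Carlo type-I calibration (rejection rate within [0.03, 0.07] at
nominal .05, 2000 replicates per test).

## Reproduction harness and problem sizes

`gammakit.targets` re-simulates each published endpoint at the published
group size (n = 6–34 slices, 100–170-min protocols) and compares the cohort
mean with the published mean ± SEM; `scripts/acceptance.py` writes the
values as JSON. Synthesis runs at 1 kHz by default — the gamma band
(< 90 Hz) is unaffected relative to a 5-kHz acquisition rate and synthesis
costs 5× less; `fs=5000` restores the acquisition rate. A full 10-target
reproduction (112 slices, ~16,000 simulated minutes) takes a few minutes on
one CPU. Unit tests use time-compressed protocols (shorter inductions,
smaller τ) for everything except the reproduction targets themselves.

## What the synthetic data does and does not show

The generator reproduces: narrow-band gamma on a 1/f background, induction
and wash-out kinetics, log-normal cohort power spread, multiplicative drug
effects with wash-in, the non-plateauing MK-801 power phenotype, and
desynchronization/resynchronization trajectories. It does **not** contain:
spike-field structure, cross-frequency coupling, non-stationary frequency
jitter within windows, state switching, electrode drift or line noise, nor
any receptor-level dose–response behaviour (condition presets are fixed
factors, not dose curves). Passing closed-loop tests therefore demonstrates
that the *analysis pipeline* measures what it claims on signals with the
assumed structure — not that the biological claims of any particular study
are correct, nor that the pipeline is robust to artifacts the generator
does not model.

## Degenerate inputs and numerical choices

Zero-length protocols and non-increasing event timelines are rejected; drug
application before induction is allowed (pre-application paradigms).
Recordings shorter than one analysis window, empty search bands, and
non-positive peak powers raise errors. Equal spectral maxima resolve to the
lower frequency (deterministic). `q_factor` is the exact ratio f₀/B and
propagates invalidity for B ≤ 0. Background subtraction before the 50%
search is not performed (and not offered): published workflows of this kind
do not describe one.
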