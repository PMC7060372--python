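# Calibration preset table for the synthetic LFP generator.
#
# [conditions.*] describe slice populations: resonator location/scale
# parameters (peak frequency and half bandwidth in Hz, Gaussian across
# slices), log-normal plateau peak power (natural-log location/scale, µV²),
# induction / wash-out / resynchronization kinetics (time constants in min)
# and the runaway-growth phenotype of MK-801-pretreated tissue.
#
# [drugs.*] describe bath-applied compounds as multiplicative steady-state
# effects on peak power / half bandwidth / peak frequency, reached with
# first-order wash-in kinetics; growth_factor scales the runaway growth rate
# (0 = full arrest) and fwhm_recovery_scale scales the bandwidth
# resynchronization time constant (<1 = faster recovery of periodicity).
#
# Endpoint calibration arithmetic is documented in docs/methods.md.

[conditions.naive-saturated]
center_frequency_hz = 39.1
center_frequency_sd_hz = 3.9
fwhm_hz = 5.6
fwhm_sd_hz = 1.5
fwhm_min_hz = 1.5
log_plateau_power_mean = 6.1391   # ln(463.6 µV²)
log_plateau_power_sd = 1.9226
induction_tau_min = 25.0
growth_rate_per_min = 0.0
growth_rate_cv = 0.0
growth_onset_min = 90.0
residual_fraction = 0.05
washout_tau_min = 9.4
washout_freq_factor = 1.162
washout_fwhm_factor = 4.33
freq_recovery_tau_min = 37.7
fwhm_recovery_tau_min = 19.6
background_exponent = 1.0
background_rms_uv = 8.0

[conditions.naive-nonsaturated]
center_frequency_hz = 45.9
center_frequency_sd_hz = 4.8
fwhm_hz = 5.9
fwhm_sd_hz = 1.5
fwhm_min_hz = 1.5
log_plateau_power_mean = 3.7774   # ln(43.7 µV²)
log_plateau_power_sd = 1.6988
induction_tau_min = 25.0
growth_rate_per_min = 0.0
growth_rate_cv = 0.0
growth_onset_min = 90.0
residual_fraction = 0.05
washout_tau_min = 9.4
washout_freq_factor = 1.162
washout_fwhm_factor = 4.33
freq_recovery_tau_min = 37.7
fwhm_recovery_tau_min = 19.6
background_exponent = 1.0
background_rms_uv = 8.0

[conditions.mk801]
center_frequency_hz = 35.1
center_frequency_sd_hz = 6.4
fwhm_hz = 5.19
fwhm_sd_hz = 1.5
fwhm_min_hz = 1.5
log_plateau_power_mean = 7.2442   # ln(1400 µV²); no printed value, ~3x naive
log_plateau_power_sd = 1.6
induction_tau_min = 25.0
growth_rate_per_min = 0.011122
growth_rate_cv = 0.10
growth_onset_min = 90.0
residual_fraction = 0.05
washout_tau_min = 11.2
washout_freq_factor = 1.09
washout_fwhm_factor = 3.219
freq_recovery_tau_min = 1.0e6     # frequency does not drift back after re-wash-in
fwhm_recovery_tau_min = 23.8
background_exponent = 1.0
background_rms_uv = 8.0

[conditions.saline-control]
center_frequency_hz = 33.3
center_frequency_sd_hz = 4.0
fwhm_hz = 3.55
fwhm_sd_hz = 1.0
fwhm_min_hz = 1.2
log_plateau_power_mean = 6.1391
log_plateau_power_sd = 1.9226
induction_tau_min = 25.0
growth_rate_per_min = 0.0
growth_rate_cv = 0.0
growth_onset_min = 90.0
residual_fraction = 0.05
washout_tau_min = 9.4
washout_freq_factor = 1.162
washout_fwhm_factor = 4.33
freq_recovery_tau_min = 37.7
fwhm_recovery_tau_min = 19.6
background_exponent = 1.0
background_rms_uv = 8.0

[drugs.pramipexole-30]
power_factor = 0.381
fwhm_factor = 1.981
frequency_factor = 1.0
washin_tau_min = 15.0

[drugs.pramipexole-10]
# mild, non-significant suppression
power_factor = 0.85
fwhm_factor = 1.10
frequency_factor = 1.0
washin_tau_min = 15.0

[drugs.sb-277011]
power_factor = 1.0
fwhm_factor = 1.0
frequency_factor = 1.0
washin_tau_min = 15.0

[drugs.cariprazine-naive]
# no effect on saturated oscillations in naive tissue
power_factor = 1.0
fwhm_factor = 1.0
frequency_factor = 1.0
washin_tau_min = 15.0

[drugs.cariprazine-nonsaturated]
power_factor = 1.0
fwhm_factor = 0.907
frequency_factor = 1.0
washin_tau_min = 15.0

[drugs.cariprazine-mk801]
power_factor = 1.0
fwhm_factor = 1.0
frequency_factor = 1.0
washin_tau_min = 15.0
growth_factor = 0.0          # arrests the runaway power growth
fwhm_recovery_scale = 0.41   # accelerates Q-factor resynchronization

[drugs."pramipexole-10+cariprazine"]
# qualitative: potentiated suppression (no printed magnitudes)
power_factor = 0.55
fwhm_factor = 1.30
frequency_factor = 1.0
washin_tau_min = 15.0

[drugs."pramipexole-30+cariprazine"]
# qualitative: attenuated suppression (no printed magnitudes)
power_factor = 0.65
fwhm_factor = 1.50
frequency_factor = 1.0
washin_tau_min = 15.0
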