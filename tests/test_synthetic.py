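"""Generator tests: resonator calibration, background, slices, cohorts."""

import numpy as np
import pytest
from scipy.signal import lfilter, welch

from gammakit.spectral import compute_timecourse
from gammakit.stats import dagostino_pearson_k2
from gammakit.synthetic import (
    CohortConfig,
    ProtocolTimeline,
    ResonatorParams,
    calibrate_resonator,
    draw_slice_params,
    drug_protocol,
    generate_background,
    generate_slice_recording,
    induction_protocol,
    iter_cohort,
    resonator_stationary_std,
    sample_cohort,
)

FS = 1000.0


# --------------------------------------------------------- calibrate_resonator


def test_rejects_aliasing_and_non_resonant_requests():
    with pytest.raises(ValueError):
        calibrate_resonator(600.0, 5.0, FS)  # f0 >= fs/2
    with pytest.raises(ValueError):
        calibrate_resonator(40.0, 45.0, FS)  # fwhm >= f0


def test_undamped_limit_pole_magnitude_approaches_one():
    _, a = calibrate_resonator(40.0, 0.01, FS)
    assert np.sqrt(a[2]) > 0.9999


def test_wider_bandwidth_gives_smaller_pole_magnitude():
    _, a5 = calibrate_resonator(40.0, 5.0, FS)
    _, a10 = calibrate_resonator(40.0, 10.0, FS)
    assert np.sqrt(a10[2]) < np.sqrt(a5[2])


def _oracle_peak_and_fwhm(x, fs, nperseg=8192, smooth=5):
    """Independent oracle: dense Welch density (lightly averaged over adjacent
    bins to tame single-bin noise) + interpolated half crossings."""
    f, pxx = welch(x, fs=fs, nperseg=nperseg)
    if smooth > 1:
        k = np.ones(smooth)
        pxx = np.convolve(pxx, k, "same") / np.convolve(np.ones_like(pxx), k, "same")
    i = int(np.argmax(pxx))
    half = pxx[i] / 2.0
    j = i
    while pxx[j] >= half:
        j -= 1
    fl = np.interp(half, [pxx[j], pxx[j + 1]], [f[j], f[j + 1]])
    j = i
    while pxx[j] >= half:
        j += 1
    fr = np.interp(half, [pxx[j], pxx[j - 1]], [f[j], f[j - 1]])
    return f[i], fr - fl


def test_realized_fwhm_within_15_percent():
    b, a = calibrate_resonator(40.0, 5.0, FS)
    x = lfilter(b, a, np.random.default_rng(0).standard_normal(2_000_000))
    peak_f, fwhm = _oracle_peak_and_fwhm(x, FS)
    assert fwhm == pytest.approx(5.0, rel=0.15)
    assert peak_f == pytest.approx(40.0, abs=2 * FS / 8192)


def test_stationary_std_closed_form_matches_realization():
    b, a = calibrate_resonator(40.0, 5.0, FS)
    x = lfilter(b, a, np.random.default_rng(1).standard_normal(500_000))
    assert x.std() == pytest.approx(resonator_stationary_std(a), rel=0.05)


def test_resonator_params_invariants():
    with pytest.raises(ValueError):
        ResonatorParams(center_frequency=40.0, target_fwhm=50.0)
    with pytest.raises(ValueError):
        ResonatorParams(center_frequency=-1.0, target_fwhm=5.0)


# ----------------------------------------------------------- generate_background


def test_zero_amplitude_background_is_silent():
    x = generate_background(1.0, FS, alpha=1.0, amplitude=0.0, seed=0)
    assert x.shape == (60_000,)
    assert np.all(x == 0)


def test_background_is_seed_deterministic():
    x1 = generate_background(1.0, FS, 1.0, 8.0, seed=42)
    x2 = generate_background(1.0, FS, 1.0, 8.0, seed=42)
    assert np.array_equal(x1, x2)


def test_background_loglog_slope_near_minus_alpha():
    x = generate_background(10.0, FS, alpha=1.0, amplitude=8.0, seed=7)
    f, pxx = welch(x, fs=FS, nperseg=2**15)
    sel = (f >= 1.0) & (f <= 100.0)
    slope = np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)[0]
    assert -1.3 < slope < -0.7


def test_background_rejects_bad_inputs():
    with pytest.raises(ValueError):
        generate_background(-1.0, FS, 1.0, 8.0, 0)
    with pytest.raises(ValueError):
        generate_background(1.0, FS, 3.0, 8.0, 0)


# ------------------------------------------------------ generate_slice_recording


def test_background_only_protocol_has_no_valid_peaks(presets):
    protocol = ProtocolTimeline((), total_duration_min=20.0)
    params = presets["conditions"]["naive-saturated"].location_params()
    rec = generate_slice_recording(protocol, params, {}, fs=FS, seed=0)
    tc = compute_timecourse(rec)
    assert (~tc.valid).mean() >= 0.9


def test_unknown_drug_preset_rejected(presets):
    params = presets["conditions"]["naive-saturated"].location_params()
    protocol = drug_protocol("no-such-drug", 5.0, 10.0)
    with pytest.raises(KeyError):
        generate_slice_recording(protocol, params, {}, fs=FS, seed=0)


def test_sampling_rate_floor_enforced(presets):
    params = presets["conditions"]["naive-saturated"].location_params()
    with pytest.raises(ValueError):
        generate_slice_recording(induction_protocol(10.0), params, {}, fs=100.0, seed=0)


def test_slice_recording_seed_deterministic(presets):
    params = presets["conditions"]["naive-saturated"].location_params()
    prot = induction_protocol(5.0)
    r1 = generate_slice_recording(prot, params, {}, fs=FS, seed=9)
    r2 = generate_slice_recording(prot, params, {}, fs=FS, seed=9)
    assert np.array_equal(r1.samples, r2.samples)


def test_envelope_rises_monotonically_to_plateau(presets):
    """Without drugs or runaway growth the windowed oscillation power is
    non-decreasing (within estimator noise) up to the plateau."""
    params = presets["conditions"]["naive-saturated"].location_params()
    rec = generate_slice_recording(induction_protocol(90.0), params, {}, fs=FS, seed=2)
    tc = compute_timecourse(rec)
    p = tc.peak_power[tc.valid]
    smoothed = np.convolve(p, np.ones(3) / 3, mode="valid")
    assert np.all(np.diff(smoothed) > -0.12 * smoothed[:-1])
    thirds = np.array_split(p, 3)
    assert thirds[0].mean() < thirds[1].mean() < thirds[2].mean()


def test_plateau_recovery_of_programmed_parameters(presets):
    """Closed loop at plateau on 20-replicate medians: programmed frequency
    recovered within one grid bin, FWHM within 15%, peak power within 20%."""
    from dataclasses import replace

    cond = presets["conditions"]["naive-saturated"]
    params = replace(
        cond.location_params(),
        induction_tau=0.1,  # reach plateau immediately for a stationary check
    )
    freqs, bws, pows = [], [], []
    for rep in range(20):
        rec = generate_slice_recording(
            induction_protocol(6.0), params, {}, fs=FS, seed=100 + rep
        )
        tc = compute_timecourse(rec)
        assert tc.valid.all()
        freqs.append(np.median(tc.peak_frequency))
        bws.append(np.median(tc.half_bandwidth))
        pows.append(np.median(tc.peak_power))
    assert np.median(freqs) == pytest.approx(cond.center_frequency_hz, abs=0.25)
    assert np.median(bws) == pytest.approx(cond.fwhm_hz, rel=0.15)
    assert np.median(pows) == pytest.approx(np.exp(cond.log_plateau_power_mean), rel=0.20)


def test_mk801_growth_exceeds_baseline(presets):
    """Runaway growth: with growth_rate > 0 the normalized power at the end of
    a (time-compressed) recording exceeds its pre-growth baseline."""
    from dataclasses import replace

    from gammakit.cohort import evaluate_endpoint, normalize_to_baseline

    cond = presets["conditions"]["mk801"]
    params = replace(
        cond.location_params(),
        induction_tau=1.0,
        growth_onset=10.0,
        growth_rate=0.05,
    )
    above = 0
    for rep in range(10):
        rec = generate_slice_recording(
            induction_protocol(30.0), params, {}, fs=FS, seed=300 + rep
        )
        ntc = normalize_to_baseline(compute_timecourse(rec), (10.0, 14.0))
        if evaluate_endpoint(ntc, 30.0)["peak_power"] > 100.0:
            above += 1
    assert above >= 9  # probability >= 0.95 over seeds ~ allow one failure in 10


# ---------------------------------------------------------------- sample_cohort


def _tiny_cohort_cfg(n=2, seed=77):
    return CohortConfig(
        n_slices=n,
        condition="naive-saturated",
        seed=seed,
        scale_overrides={
            "center_frequency_sd_hz": 0.0,
            "fwhm_sd_hz": 0.0,
            "log_plateau_power_sd": 0.0,
        },
        effect_jitter={},
    )


def test_cohort_is_seed_deterministic(presets):
    prot = induction_protocol(4.0)
    c1 = sample_cohort(_tiny_cohort_cfg(), prot, presets, fs=FS)
    c2 = sample_cohort(_tiny_cohort_cfg(), prot, presets, fs=FS)
    assert len(c1) == len(c2) == 2
    for a, b in zip(c1, c2):
        assert np.array_equal(a.samples, b.samples)


def test_single_slice_zero_scales_matches_location_parameters(presets):
    """With all scales zero, the cohort draw reduces to the location params
    and the derived per-slice seed stream."""
    prot = induction_protocol(4.0)
    (rec,) = sample_cohort(_tiny_cohort_cfg(n=1, seed=5), prot, presets, fs=FS)
    child = np.random.SeedSequence(5).spawn(1)[0]
    _, signal_ss = child.spawn(2)
    params = presets["conditions"]["naive-saturated"].location_params()
    ref = generate_slice_recording(
        prot,
        params,
        presets["drugs"],
        fs=FS,
        seed=np.random.default_rng(signal_ss),
    )
    assert np.array_equal(rec.samples, ref.samples)


def test_cohort_rejects_bad_size():
    with pytest.raises(ValueError):
        CohortConfig(n_slices=0, condition="naive-saturated", seed=1)


def test_unknown_condition_rejected(presets):
    cfg = CohortConfig(n_slices=1, condition="no-such-condition", seed=1)
    with pytest.raises(KeyError):
        next(iter_cohort(cfg, induction_protocol(4.0), presets, fs=FS))


def test_plateau_powers_are_lognormal(presets):
    """Log plateau powers of a 50-slice draw pass the normality test in at
    least 18 of 20 seeded replicates (parameter-level Monte Carlo)."""
    cond = presets["conditions"]["naive-saturated"]
    passes = 0
    for rep in range(20):
        rng = np.random.default_rng(rep)
        logs = [
            np.log(draw_slice_params(cond, rng).plateau_power) for _ in range(50)
        ]
        if dagostino_pearson_k2(logs).p_value > 0.05:
            passes += 1
    assert passes >= 18


def test_protocol_timeline_invariants():
    with pytest.raises(ValueError):
        ProtocolTimeline(((0.0, "induction_on", ""),), total_duration_min=0.0)
    with pytest.raises(ValueError):
        ProtocolTimeline(
            ((10.0, "induction_on", ""), (10.0, "drug_on", "x")), 60.0
        )
    with pytest.raises(ValueError):
        ProtocolTimeline(((70.0, "induction_on", ""),), 60.0)
    with pytest.raises(ValueError):
        ProtocolTimeline(((0.0, "not-a-kind", ""),), 60.0)
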