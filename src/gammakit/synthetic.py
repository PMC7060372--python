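"""Phenomenological generator of hippocampal gamma-band LFP recordings.

The generator emulates the statistical and temporal structure of
cholinergically induced gamma oscillations in hippocampal slices, so that the
whole analysis pipeline can be exercised end to end without recorded data:

* the oscillation itself is white noise driven through a two-pole (AR-2)
  resonator, which yields an approximately Lorentzian spectral peak naturally
  parameterized by peak frequency f0 and half bandwidth B (FWHM);
* a 1/f^alpha broadband background is added throughout;
* the oscillation envelope follows the pharmacological protocol: first-order
  saturating rise after induction (plateau after ~90 min), first-order decay
  toward a small residual after agonist wash-out (desynchronization, with the
  peak drifting up in frequency and broadening), partial resynchronization
  after re-wash-in, multiplicative drug effects with first-order wash-in
  kinetics, and — for slices from MK-801-pretreated animals — runaway
  post-plateau power growth;
* slice-to-slice variability: log-normal plateau peak power, Gaussian jitter
  of peak frequency and bandwidth, log-normal jitter of drug-effect factors.

Power is calibrated in *measured* units: a slice's ``plateau_power`` is the
expected gamma peak power (µV²) that the default spectral configuration
(:data:`gammakit.spectral.DEFAULT_SPECTRAL_CONFIG`) reports at plateau, so
generator presets are directly comparable to published peak powers.

Condition and drug presets live in ``data/presets.toml`` (plain text,
editable); see :func:`load_presets`.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.signal import lfilter

from .recording import LFPRecording
from .spectral import DEFAULT_SPECTRAL_CONFIG

__all__ = [
    "ResonatorParams",
    "ProtocolTimeline",
    "DrugEffectPreset",
    "WashoutKinetics",
    "SliceParams",
    "ConditionPreset",
    "CohortConfig",
    "load_presets",
    "calibrate_resonator",
    "resonator_stationary_std",
    "generate_background",
    "generate_slice_recording",
    "draw_slice_params",
    "iter_cohort",
    "sample_cohort",
    "induction_protocol",
    "drug_protocol",
    "washout_protocol",
    "rewash_protocol",
]

#: Default synthesis rate (Hz). The gamma band (<90 Hz) is unaffected by
#: synthesizing at 1 kHz instead of an acquisition-grade 5 kHz, at 5x lower
#: cost; pass ``fs=5000`` to restore the acquisition rate.
DEFAULT_FS = 1000.0

#: Per-slice log-normal jitter (sigma of log) applied to drug-effect factors.
DEFAULT_EFFECT_JITTER = {"power": 0.15, "fwhm": 0.08, "frequency": 0.02}

# ENBW (Hz) of the default analysis estimator; converts a target measured
# peak power into a spectral density when calibrating the resonator drive.
_CAL_ENBW_HZ = 1.5 / DEFAULT_SPECTRAL_CONFIG.segment_length  # Hann taper


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResonatorParams:
    """Spectral-peak parameters of the gamma oscillator."""

    center_frequency: float  # Hz (f0)
    target_fwhm: float  # Hz (B)
    rms_amplitude: float = 0.0  # µV; used by standalone synthesis helpers

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not 0 < self.target_fwhm < self.center_frequency:
            raise ValueError("need 0 < target_fwhm < center_frequency")
        if self.rms_amplitude < 0:
            raise ValueError("rms_amplitude must be non-negative")


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered experimental events (minutes from recording start)."""

    events: tuple[tuple[float, str, str], ...]
    total_duration_min: float

    def __post_init__(self) -> None:
        if self.total_duration_min <= 0:
            raise ValueError("total_duration_min must be positive")
        object.__setattr__(self, "events", tuple(self.events))
        times = [t for t, _, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for t, kind, _ in self.events:
            if not 0 <= t <= self.total_duration_min:
                raise ValueError(f"event at {t} min outside recording duration")
            from .recording import EVENT_KINDS

            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")


@dataclass(frozen=True)
class DrugEffectPreset:
    """Steady-state multiplicative drug effect with wash-in kinetics."""

    power_factor: float = 1.0
    fwhm_factor: float = 1.0
    frequency_factor: float = 1.0
    washin_tau: float = 15.0  # min
    growth_factor: float = 1.0  # scales runaway growth rate (0 = arrest)
    fwhm_recovery_scale: float = 1.0  # scales bandwidth resync tau (<1 faster)

    def __post_init__(self) -> None:
        for name in ("power_factor", "fwhm_factor", "frequency_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.washin_tau <= 0:
            raise ValueError("washin_tau must be positive")
        if self.growth_factor < 0 or self.fwhm_recovery_scale <= 0:
            raise ValueError("invalid growth/recovery scaling")


@dataclass(frozen=True)
class WashoutKinetics:
    """Desynchronization / resynchronization kinetics (all times in min)."""

    tau: float = 9.4  # power decay and peak-drift time constant
    freq_factor: float = 1.162  # asymptotic peak-frequency drift during wash-out
    fwhm_factor: float = 4.33  # asymptotic bandwidth broadening during wash-out
    freq_recovery_tau: float = 37.7
    fwhm_recovery_tau: float = 19.6


@dataclass(frozen=True)
class SliceParams:
    """All generator parameters of one slice."""

    resonator: ResonatorParams
    plateau_power: float  # µV², measured-scale gamma peak power at plateau
    induction_tau: float = 25.0  # min
    background_exponent: float = 1.0  # 1/f^alpha
    background_amplitude: float = 8.0  # µV RMS
    growth_rate: float = 0.0  # fraction/min after plateau (MK-801 phenotype)
    growth_onset: float = 90.0  # min
    residual_fraction: float = 0.05  # oscillation floor during wash-out
    washout: WashoutKinetics = field(default_factory=WashoutKinetics)

    def __post_init__(self) -> None:
        if self.plateau_power <= 0:
            raise ValueError("plateau_power must be positive")
        if self.induction_tau <= 0:
            raise ValueError("induction_tau must be positive")
        if not 0 <= self.residual_fraction < 1:
            raise ValueError("residual_fraction must be in [0, 1)")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be non-negative")


@dataclass(frozen=True)
class ConditionPreset:
    """Slice-population distribution for one experimental condition."""

    center_frequency_hz: float
    center_frequency_sd_hz: float
    fwhm_hz: float
    fwhm_sd_hz: float
    fwhm_min_hz: float
    log_plateau_power_mean: float
    log_plateau_power_sd: float
    induction_tau_min: float
    growth_rate_per_min: float
    growth_rate_cv: float
    growth_onset_min: float
    residual_fraction: float
    washout_tau_min: float
    washout_freq_factor: float
    washout_fwhm_factor: float
    freq_recovery_tau_min: float
    fwhm_recovery_tau_min: float
    background_exponent: float
    background_rms_uv: float

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionPreset":
        return cls(**d)

    def location_params(self) -> SliceParams:
        """SliceParams at the distribution locations (all scales zero)."""
        return SliceParams(
            resonator=ResonatorParams(self.center_frequency_hz, self.fwhm_hz),
            plateau_power=math.exp(self.log_plateau_power_mean),
            induction_tau=self.induction_tau_min,
            background_exponent=self.background_exponent,
            background_amplitude=self.background_rms_uv,
            growth_rate=self.growth_rate_per_min,
            growth_onset=self.growth_onset_min,
            residual_fraction=self.residual_fraction,
            washout=WashoutKinetics(
                tau=self.washout_tau_min,
                freq_factor=self.washout_freq_factor,
                fwhm_factor=self.washout_fwhm_factor,
                freq_recovery_tau=self.freq_recovery_tau_min,
                fwhm_recovery_tau=self.fwhm_recovery_tau_min,
            ),
        )


@dataclass(frozen=True)
class CohortConfig:
    """A cohort: n slices drawn independently from a condition preset."""

    n_slices: int
    condition: str
    seed: int
    scale_overrides: dict = field(default_factory=dict)  # preset field -> value
    effect_jitter: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_JITTER))

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


# --------------------------------------------------------------------------
# preset loading
# --------------------------------------------------------------------------


def load_presets(path=None) -> dict:
    """Load the condition/drug calibration table.

    Returns ``{'conditions': {name: ConditionPreset}, 'drugs': {name:
    DrugEffectPreset}}``. With no ``path``, the table shipped with the package
    is used.
    """
    if path is None:
        raw = resources.files("gammakit").joinpath("data/presets.toml").read_bytes()
        doc = tomllib.loads(raw.decode())
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    conditions = {
        name: ConditionPreset.from_dict(d) for name, d in doc.get("conditions", {}).items()
    }
    drugs = {}
    for name, d in doc.get("drugs", {}).items():
        drugs[name] = DrugEffectPreset(
            power_factor=d.get("power_factor", 1.0),
            fwhm_factor=d.get("fwhm_factor", 1.0),
            frequency_factor=d.get("frequency_factor", 1.0),
            washin_tau=d.get("washin_tau_min", 15.0),
            growth_factor=d.get("growth_factor", 1.0),
            fwhm_recovery_scale=d.get("fwhm_recovery_scale", 1.0),
        )
    return {"conditions": conditions, "drugs": drugs}


# --------------------------------------------------------------------------
# resonator
# --------------------------------------------------------------------------


def calibrate_resonator(f0: float, fwhm: float, fs: float):
    """Two-pole resonator coefficients realizing a peak at ``f0`` with the
    requested half-power full width.

    Pole radius ``r = exp(-pi * fwhm / fs)`` sets the bandwidth; the pole
    angle is corrected so the response maximum (not the pole angle) lands on
    ``f0``. Returns ``(b, a)`` for :func:`scipy.signal.lfilter`.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 < f0 < fs / 2:
        raise ValueError("need 0 < f0 < fs/2 (aliasing)")
    if not 0 < fwhm < f0:
        raise ValueError("need 0 < fwhm < f0 (no resonance otherwise)")
    r = math.exp(-math.pi * fwhm / fs)
    w0 = 2 * math.pi * f0 / fs
    # peak of |H| sits where cos(w) = cos(theta) * (1 + r^2) / (2 r);
    # invert so the peak lands on w0
    cos_theta = math.cos(w0) * 2 * r / (1 + r * r)
    cos_theta = min(1.0, max(-1.0, cos_theta))
    a1 = -2 * r * cos_theta
    a2 = r * r
    return [1.0], [1.0, a1, a2]


def _ar2_gain_at(a, w: float) -> float:
    """|H(e^{jw})| of the all-pole filter 1/A(z)."""
    z = complex(math.cos(w), -math.sin(w))
    denom = a[0] + a[1] * z + a[2] * z * z
    return 1.0 / abs(denom)


def resonator_stationary_std(a, sigma_e: float = 1.0) -> float:
    """Stationary output std of the AR(2) filter driven by N(0, sigma_e²)."""
    phi1, phi2 = -a[1], -a[2]
    var = (
        sigma_e**2
        * (1 - phi2)
        / ((1 + phi2) * ((1 - phi2) ** 2 - phi1**2))
    )
    return math.sqrt(var)


def _drive_sigma_for_peak(a, w0: float, peak_power: float, fs: float) -> float:
    """Driving-noise sigma so the measured spectrum peaks at ``peak_power`` µV².

    The one-sided spectral density at the peak is ``2 sigma² |H|² / fs``; the
    tone-calibrated estimator reports density × ENBW at the peak bin.
    """
    if peak_power <= 0:
        return 0.0
    density = peak_power / _CAL_ENBW_HZ
    gain = _ar2_gain_at(a, w0)
    return math.sqrt(density * fs / 2.0) / gain


# --------------------------------------------------------------------------
# background
# --------------------------------------------------------------------------


def generate_background(
    duration_min: float,
    fs: float,
    alpha: float = 1.0,
    amplitude: float = 8.0,
    seed=0,
) -> np.ndarray:
    """Broadband 1/f^alpha background, scaled to ``amplitude`` µV RMS.

    Synthesized by spectral shaping of white Gaussian noise; the shape is
    flattened below 1 Hz so the variance stays finite for alpha >= 1.
    """
    if duration_min <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if not 0 <= alpha <= 2:
        raise ValueError("alpha must be in [0, 2]")
    n = int(round(duration_min * 60.0 * fs))
    if amplitude == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.maximum(freqs, 1.0) ** (-alpha / 2.0)
    shaped[0] = 0.0  # zero mean
    spec *= shaped
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd > 0:
        x *= amplitude / sd
    return x


# --------------------------------------------------------------------------
# protocol builders
# --------------------------------------------------------------------------


def induction_protocol(duration_min: float = 100.0) -> ProtocolTimeline:
    """Continuous agonist perfusion from t=0."""
    return ProtocolTimeline(((0.0, "induction_on", ""),), duration_min)


def drug_protocol(
    drug: str, drug_on_min: float = 100.0, duration_min: float = 160.0
) -> ProtocolTimeline:
    """Induction at t=0, drug applied at ``drug_on_min`` until the end."""
    return ProtocolTimeline(
        ((0.0, "induction_on", ""), (drug_on_min, "drug_on", drug)), duration_min
    )


def washout_protocol(
    off_min: float = 100.0, duration_min: float = 140.0
) -> ProtocolTimeline:
    """Induction at t=0, agonist wash-out at ``off_min``."""
    return ProtocolTimeline(
        ((0.0, "induction_on", ""), (off_min, "induction_off", "")), duration_min
    )


def rewash_protocol(
    off_min: float = 100.0,
    re_on_min: float = 140.0,
    duration_min: float = 170.0,
    drug: str | None = None,
    drug_on_min: float = 100.0,
) -> ProtocolTimeline:
    """Wash-out followed by re-wash-in, optionally with a drug present."""
    events = [(0.0, "induction_on", "")]
    if drug is not None:
        events.append((drug_on_min, "drug_on", drug))
    events.append((off_min, "induction_off", ""))
    events.append((re_on_min, "induction_on", ""))
    events.sort(key=lambda e: e[0])
    return ProtocolTimeline(tuple(events), duration_min)


# --------------------------------------------------------------------------
# single-slice synthesis
# --------------------------------------------------------------------------


def _exp_step(state: float, target: float, dt: float, tau: float) -> float:
    if tau <= 0 or not math.isfinite(tau):
        return state
    return state + (target - state) * (1.0 - math.exp(-dt / tau))


def generate_slice_recording(
    protocol: ProtocolTimeline,
    params: SliceParams,
    presets: dict[str, DrugEffectPreset] | None = None,
    fs: float = DEFAULT_FS,
    seed=0,
    slice_id: str = "",
    condition: str = "",
    block_s: float = 2.0,
) -> LFPRecording:
    """Synthesize one slice recording under a protocol.

    The oscillation is generated block-wise (2-s blocks) through the AR-2
    resonator with piecewise-constant coefficients; the driving-noise gain is
    recalibrated every block so the *measured* gamma peak power tracks the
    programmed envelope, decoupling spectral shape from power. Envelope and
    spectral trajectories follow the first-order kinetics described in the
    module docstring.
    """
    presets = presets or {}
    f0 = params.resonator.center_frequency
    if fs < 4 * f0:
        raise ValueError("fs must be at least 4x the resonator center frequency")
    for t, kind, payload in protocol.events:
        if kind in ("drug_on", "drug_off") and payload not in presets:
            raise KeyError(f"unknown drug preset {payload!r}")

    n_total = int(round(protocol.total_duration_min * 60.0 * fs))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drive = rng.standard_normal(n_total)
    osc = np.empty(n_total)

    wk = params.washout
    # kinetic state
    L = 0.0  # induction level (fraction of plateau)
    L_target = 0.0
    induction_on = False
    washed_out = False  # an induction_off has occurred
    growth_stopped = False
    G = 1.0  # runaway growth factor
    Wf = 1.0  # wash-out frequency-drift factor
    Wb = 1.0  # wash-out bandwidth-broadening factor
    drug_level: dict[str, float] = {}
    drug_target: dict[str, float] = {}

    events = sorted(protocol.events, key=lambda e: e[0])
    ev_i = 0
    n_blocks = int(math.ceil(n_total / (block_s * fs)))
    block_n = int(round(block_s * fs))
    dt_min = block_s / 60.0
    zi = np.zeros(2)
    b0 = params.resonator.target_fwhm

    pos = 0
    for k in range(n_blocks):
        t_min = k * block_s / 60.0
        while ev_i < len(events) and events[ev_i][0] <= t_min + 1e-12:
            _, kind, payload = events[ev_i]
            if kind == "induction_on":
                L_target = 1.0
                induction_on = True
            elif kind == "induction_off":
                L_target = params.residual_fraction
                induction_on = False
                washed_out = True
                growth_stopped = True
            elif kind == "induction_reduced":
                L_target = float(payload) if payload else 0.5
                induction_on = True
            elif kind == "drug_on":
                drug_level.setdefault(payload, 0.0)
                drug_target[payload] = 1.0
            elif kind == "drug_off":
                drug_level.setdefault(payload, 0.0)
                drug_target[payload] = 0.0
            ev_i += 1

        # drug wash-in / wash-out
        Dp = Db = Df = 1.0
        arrest = 1.0
        rec_scale = 1.0
        for name, w in drug_level.items():
            pre = presets[name]
            w = _exp_step(w, drug_target.get(name, 0.0), dt_min, pre.washin_tau)
            drug_level[name] = w
            Dp *= 1.0 + (pre.power_factor - 1.0) * w
            Db *= 1.0 + (pre.fwhm_factor - 1.0) * w
            Df *= 1.0 + (pre.frequency_factor - 1.0) * w
            arrest *= 1.0 + (pre.growth_factor - 1.0) * w
            rec_scale *= 1.0 + (pre.fwhm_recovery_scale - 1.0) * w

        # induction envelope: saturating rise, exponential wash-out decay
        tau_L = params.induction_tau if L_target >= L else wk.tau
        L = _exp_step(L, L_target, dt_min, tau_L)

        # runaway growth (MK-801 phenotype), arrested by growth_factor drugs
        if (
            induction_on
            and not growth_stopped
            and params.growth_rate > 0
            and t_min >= params.growth_onset
        ):
            G *= math.exp(params.growth_rate * arrest * dt_min)

        # wash-out spectral drift and post-re-wash-in recovery
        if washed_out and not induction_on:
            Wf = _exp_step(Wf, wk.freq_factor, dt_min, wk.tau)
            Wb = _exp_step(Wb, wk.fwhm_factor, dt_min, wk.tau)
        elif washed_out and induction_on:
            Wf = _exp_step(Wf, 1.0, dt_min, wk.freq_recovery_tau)
            Wb = _exp_step(Wb, 1.0, dt_min, wk.fwhm_recovery_tau * rec_scale)

        peak_power = params.plateau_power * L * G * Dp
        freq = min(f0 * Df * Wf, 0.45 * fs)
        bw = min(max(b0 * Db * Wb, 0.05), 0.9 * freq)

        b, a = calibrate_resonator(freq, bw, fs)
        w0 = 2 * math.pi * freq / fs
        sigma = _drive_sigma_for_peak(a, w0, peak_power, fs)

        stop = min(pos + block_n, n_total)
        y, zi = lfilter([sigma], a, drive[pos:stop], zi=zi)
        osc[pos:stop] = y
        pos = stop

    bg = generate_background(
        protocol.total_duration_min,
        fs,
        params.background_exponent,
        params.background_amplitude,
        seed=rng,
    )
    return LFPRecording(
        samples=osc + bg,
        fs=fs,
        slice_id=slice_id,
        condition=condition,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        events=list(protocol.events),
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def draw_slice_params(
    cond: ConditionPreset, rng: np.random.Generator, scale_overrides: dict | None = None
) -> SliceParams:
    """Draw one slice's parameters from a condition preset.

    Plateau peak power is log-normal; peak frequency and bandwidth carry
    Gaussian jitter (truncated to physical ranges); the runaway growth rate
    carries Gaussian jitter with the preset CV.
    """
    c = cond
    if scale_overrides:
        c = replace(c, **scale_overrides)
    f0 = float(
        np.clip(rng.normal(c.center_frequency_hz, c.center_frequency_sd_hz), 26.0, 72.0)
    )
    fwhm = float(
        np.clip(rng.normal(c.fwhm_hz, c.fwhm_sd_hz), c.fwhm_min_hz, 3 * c.fwhm_hz)
    )
    plateau = float(np.exp(rng.normal(c.log_plateau_power_mean, c.log_plateau_power_sd)))
    growth = c.growth_rate_per_min
    if growth > 0 and c.growth_rate_cv > 0:
        growth = max(0.0, float(rng.normal(growth, growth * c.growth_rate_cv)))
    return SliceParams(
        resonator=ResonatorParams(f0, fwhm),
        plateau_power=plateau,
        induction_tau=c.induction_tau_min,
        background_exponent=c.background_exponent,
        background_amplitude=c.background_rms_uv,
        growth_rate=growth,
        growth_onset=c.growth_onset_min,
        residual_fraction=c.residual_fraction,
        washout=WashoutKinetics(
            tau=c.washout_tau_min,
            freq_factor=c.washout_freq_factor,
            fwhm_factor=c.washout_fwhm_factor,
            freq_recovery_tau=c.freq_recovery_tau_min,
            fwhm_recovery_tau=c.fwhm_recovery_tau_min,
        ),
    )


def _jitter_drug_presets(
    presets: dict[str, DrugEffectPreset],
    rng: np.random.Generator,
    jitter: dict,
) -> dict[str, DrugEffectPreset]:
    out = {}
    for name, p in presets.items():
        out[name] = replace(
            p,
            power_factor=p.power_factor * math.exp(jitter.get("power", 0) * rng.standard_normal()),
            fwhm_factor=p.fwhm_factor * math.exp(jitter.get("fwhm", 0) * rng.standard_normal()),
            frequency_factor=p.frequency_factor
            * math.exp(jitter.get("frequency", 0) * rng.standard_normal()),
        )
    return out


def iter_cohort(
    config: CohortConfig,
    protocol: ProtocolTimeline,
    presets: dict | None = None,
    fs: float = DEFAULT_FS,
):
    """Yield ``n_slices`` independent recordings (lazily, one at a time).

    Slice parameters, drug-effect jitter and signal noise all derive from
    ``config.seed`` through a spawned seed tree, so identical configs
    reproduce byte-identical cohorts.
    """
    table = presets or load_presets()
    try:
        cond = table["conditions"][config.condition]
    except KeyError:
        raise KeyError(f"unknown condition preset {config.condition!r}") from None
    drugs = table["drugs"]
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_slices)
    for i, child in enumerate(children):
        param_ss, signal_ss = child.spawn(2)
        prng = np.random.default_rng(param_ss)
        params = draw_slice_params(cond, prng, config.scale_overrides)
        slice_drugs = _jitter_drug_presets(drugs, prng, config.effect_jitter)
        yield generate_slice_recording(
            protocol,
            params,
            slice_drugs,
            fs=fs,
            seed=np.random.default_rng(signal_ss),
            slice_id=f"{config.condition}-{i:02d}",
            condition=config.condition,
        )


def sample_cohort(
    config: CohortConfig,
    protocol: ProtocolTimeline,
    presets: dict | None = None,
    fs: float = DEFAULT_FS,
) -> list[LFPRecording]:
    """Materialized cohort (see :func:`iter_cohort`)."""
    return list(iter_cohort(config, protocol, presets, fs))
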