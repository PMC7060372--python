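"""In-memory container for a single-channel LFP recording.

A recording is the unit of analysis throughout the package: a vector of
voltage samples (µV) at a fixed sampling rate, plus the protocol timeline
(induction / wash-out / drug events, in minutes from recording start) and
provenance metadata (slice id, condition preset, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Event kinds understood by the simulator and the file format.
EVENT_KINDS = frozenset(
    {"induction_on", "induction_off", "induction_reduced", "drug_on", "drug_off"}
)


@dataclass
class LFPRecording:
    """Single-channel local field potential recording.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in µV.
    fs : float
        Sampling rate in Hz.
    events : list of (time_min, kind, payload)
        Protocol timeline. ``payload`` names a condition/drug preset (may be
        empty). Times are minutes from the start of the recording and must be
        non-decreasing.
    """

    samples: np.ndarray
    fs: float
    units: str = "uV"
    slice_id: str = ""
    condition: str = ""
    seed: int | None = None
    events: list[tuple[float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        times = [t for t, _, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        for _, kind, _ in self.events:
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind: {kind!r}")

    @property
    def duration_min(self) -> float:
        return self.samples.size / self.fs / 60.0

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)
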