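"""File formats and experiment orchestration.

Recording container: a flat binary array of float samples (``.dat``) with a
plain-text sidecar header (``.hdr``) holding the sampling rate, units,
provenance and the event timeline; a pure-CSV fallback (``time_s,value_uv``,
header metadata in ``#`` comment lines) is provided for interchange.

:func:`run_experiment` ties the stages together: simulate each cohort arm,
extract per-window gamma metrics, normalize to baseline, aggregate, and
compare drug vs control arms at the configured endpoint. All randomness flows
from the configured seed; every output names the config hash that produced it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import stats as stats_mod
from .recording import LFPRecording
from .spectral import METRIC_NAMES, SpectralConfig, compute_timecourse
from .synthetic import CohortConfig, ProtocolTimeline, iter_cohort, load_presets

__all__ = [
    "RecordingFormatError",
    "write_recording",
    "read_recording",
    "write_recording_csv",
    "read_recording_csv",
    "ExperimentConfig",
    "load_experiment_config",
    "run_experiment",
]

log = logging.getLogger("gammakit")

_HEADER_MAGIC = "gammakit-recording v1"


class RecordingFormatError(ValueError):
    """Raised for missing/garbled headers or inconsistent recording files."""


def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in (".dat", ".hdr"):
        p = p.with_suffix("")
    return p.with_suffix(".dat"), p.with_suffix(".hdr")


def write_recording(rec: LFPRecording, path) -> None:
    """Write ``<path>.dat`` (float64 little-endian) + ``<path>.hdr`` sidecar."""
    dat, hdr = _paths(path)
    np.asarray(rec.samples, dtype="<f8").tofile(dat)
    lines = [
        _HEADER_MAGIC,
        f"sampling_rate_hz: {rec.fs!r}",
        f"units: {rec.units}",
        f"n_samples: {rec.n_samples}",
        "dtype: float64-le",
        f"slice_id: {rec.slice_id}",
        f"condition: {rec.condition}",
        f"seed: {'' if rec.seed is None else rec.seed}",
        "events:",
    ]
    for t, kind, payload in rec.events:
        lines.append(f"{t!r},{kind},{payload}")
    hdr.write_text("\n".join(lines) + "\n")


def read_recording(path) -> LFPRecording:
    """Read a recording written by :func:`write_recording`."""
    dat, hdr = _paths(path)
    if not hdr.exists() or not dat.exists():
        raise RecordingFormatError(f"missing .hdr/.dat pair for {path}")
    lines = hdr.read_text().splitlines()
    if not lines or lines[0].strip() != _HEADER_MAGIC:
        raise RecordingFormatError("unrecognized header magic")
    fields: dict[str, str] = {}
    events: list[tuple[float, str, str]] = []
    in_events = False
    for line in lines[1:]:
        line = line.strip()
        if not line:
            continue
        if line == "events:":
            in_events = True
            continue
        if in_events:
            parts = line.split(",", 2)
            if len(parts) != 3:
                raise RecordingFormatError(f"garbled event line: {line!r}")
            events.append((float(parts[0]), parts[1], parts[2]))
        else:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    for required in ("sampling_rate_hz", "units", "n_samples"):
        if required not in fields:
            raise RecordingFormatError(f"header missing field {required!r}")
    if fields["units"] != "uV":
        raise RecordingFormatError(f"unsupported units {fields['units']!r} (expected uV)")
    n = int(fields["n_samples"])
    samples = np.fromfile(dat, dtype="<f8")
    if samples.size != n:
        raise RecordingFormatError(
            f"sample count mismatch: header {n}, data {samples.size}"
        )
    times = [t for t, _, _ in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise RecordingFormatError("non-monotone event times")
    seed = fields.get("seed", "")
    return LFPRecording(
        samples=samples,
        fs=float(fields["sampling_rate_hz"]),
        units=fields["units"],
        slice_id=fields.get("slice_id", ""),
        condition=fields.get("condition", ""),
        seed=int(seed) if seed else None,
        events=events,
    )


def write_recording_csv(rec: LFPRecording, path) -> None:
    """CSV fallback: metadata in ``#`` comments, then ``time_s,value_uv`` rows."""
    p = Path(path)
    with p.open("w") as fh:
        fh.write(f"# {_HEADER_MAGIC} (csv)\n")
        fh.write(f"# sampling_rate_hz: {rec.fs!r}\n")
        fh.write(f"# units: {rec.units}\n")
        fh.write(f"# slice_id: {rec.slice_id}\n")
        fh.write(f"# condition: {rec.condition}\n")
        fh.write(f"# seed: {'' if rec.seed is None else rec.seed}\n")
        for t, kind, payload in rec.events:
            fh.write(f"# event: {t!r},{kind},{payload}\n")
        fh.write("time_s,value_uv\n")
        t = np.arange(rec.n_samples) / rec.fs
        np.savetxt(fh, np.column_stack([t, rec.samples]), fmt="%.9g", delimiter=",")


def read_recording_csv(path) -> LFPRecording:
    p = Path(path)
    meta: dict[str, str] = {}
    events: list[tuple[float, str, str]] = []
    with p.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            key, _, val = body.partition(":")
            key, val = key.strip(), val.strip()
            if key == "event":
                t, kind, payload = val.split(",", 2)
                events.append((float(t), kind, payload))
            else:
                meta[key] = val
    if "sampling_rate_hz" not in meta:
        raise RecordingFormatError("csv header missing sampling_rate_hz")
    df = pd.read_csv(p, comment="#")
    seed = meta.get("seed", "")
    return LFPRecording(
        samples=df["value_uv"].to_numpy(),
        fs=float(meta["sampling_rate_hz"]),
        units=meta.get("units", "uV"),
        slice_id=meta.get("slice_id", ""),
        condition=meta.get("condition", ""),
        seed=int(seed) if seed else None,
        events=events,
    )


# --------------------------------------------------------------------------
# experiment orchestration
# --------------------------------------------------------------------------


@dataclass
class ExperimentArm:
    name: str
    condition: str
    n_slices: int
    protocol: ProtocolTimeline


@dataclass
class ExperimentConfig:
    seed: int
    out_dir: str
    arms: list[ExperimentArm]
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    baseline: tuple[float, float] = (90.0, 100.0)
    endpoint_at: float = 160.0
    endpoint_average_over: float | None = None
    compare: list[dict] = field(default_factory=list)
    fs: float = 1000.0
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _protocol_from_dict(d: dict) -> ProtocolTimeline:
    events = tuple(
        (float(e["time_min"]), e["kind"], str(e.get("payload", "")))
        for e in d.get("events", [])
    )
    return ProtocolTimeline(events, float(d["duration_min"]))


def load_experiment_config(path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "seed" not in doc:
        raise ValueError("experiment config must set an explicit seed")
    arms = [
        ExperimentArm(
            name=a["name"],
            condition=a["condition"],
            n_slices=int(a["n_slices"]),
            protocol=_protocol_from_dict(a["protocol"]),
        )
        for a in doc["arms"]
    ]
    spectral = SpectralConfig(**doc.get("spectral", {}))
    endpoint = doc.get("endpoint", {})
    return ExperimentConfig(
        seed=int(doc["seed"]),
        out_dir=doc.get("out_dir", "gammakit-run"),
        arms=arms,
        spectral=spectral,
        baseline=tuple(doc.get("baseline", (90.0, 100.0))),
        endpoint_at=float(endpoint.get("at", 160.0)),
        endpoint_average_over=endpoint.get("average_over"),
        compare=doc.get("compare", []),
        fs=float(doc.get("fs", 1000.0)),
        raw=doc,
    )


def run_experiment(cfg: ExperimentConfig, presets: dict | None = None) -> dict:
    """Simulate all arms, analyze, aggregate and compare; write CSV outputs.

    Deterministic given ``cfg.seed``. Returns the result tables
    (``features``, ``summaries``, ``comparisons``, ``endpoints``) and writes
    them plus a run log into ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = presets or load_presets()
    chash = cfg.config_hash

    features = []
    endpoints_rows = []
    summaries = []
    arm_endpoint_values: dict[str, dict[str, list[float]]] = {}

    for arm_i, arm in enumerate(cfg.arms):
        seed = int(np.random.SeedSequence([cfg.seed, arm_i]).generate_state(1)[0] % 2**31)
        log.info("arm %s: simulating %d slices (condition=%s, seed=%d)",
                 arm.name, arm.n_slices, arm.condition, seed)
        cc = CohortConfig(n_slices=arm.n_slices, condition=arm.condition, seed=seed)
        normalized = []
        values: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
        for rec in iter_cohort(cc, arm.protocol, presets, fs=cfg.fs):
            tc = compute_timecourse(rec, cfg.spectral)
            df = tc.to_frame()
            df.insert(0, "arm", arm.name)
            features.append(df)
            ntc = cohort_mod.normalize_to_baseline(tc, cfg.baseline)
            normalized.append(ntc)
            ep = cohort_mod.evaluate_endpoint(
                ntc, cfg.endpoint_at, cfg.endpoint_average_over
            )
            for m in METRIC_NAMES:
                values[m].append(ep[m])
            n_invalid = int((~np.asarray(tc.valid)).sum())
            if n_invalid:
                log.info("  slice %s: %d invalid windows", rec.slice_id, n_invalid)
        arm_endpoint_values[arm.name] = values
        gs = cohort_mod.aggregate_group(normalized)
        gs.table.insert(0, "arm", arm.name)
        summaries.append(gs.table)
        for m in METRIC_NAMES:
            vals = np.asarray(values[m], dtype=float)
            vals = vals[np.isfinite(vals)]
            endpoints_rows.append(
                {
                    "arm": arm.name,
                    "metric": m,
                    "endpoint_min": cfg.endpoint_at,
                    "mean": vals.mean() if vals.size else np.nan,
                    "sem": (vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                    "n": vals.size,
                }
            )

    comparisons = []
    if not cfg.compare:
        log.info("no comparisons configured; comparison step skipped")
    for comp in cfg.compare:
        metric = comp["metric"]
        a = np.asarray(arm_endpoint_values[comp["drug_arm"]][metric], dtype=float)
        b = np.asarray(arm_endpoint_values[comp["control_arm"]][metric], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        res = stats_mod.compare_groups(metric, a, b, absolute=bool(comp.get("absolute", False)))
        comparisons.append(
            {
                "metric": metric,
                "groups": f"{comp['drug_arm']} vs {comp['control_arm']}",
                "n": f"{a.size}/{b.size}",
                "statistic": res.statistic,
                "p": res.p_value,
                "test_name": res.test_name,
            }
        )

    tables = {
        "features": pd.concat(features, ignore_index=True),
        "summaries": pd.concat(summaries, ignore_index=True),
        "endpoints": pd.DataFrame(endpoints_rows),
        "comparisons": pd.DataFrame(comparisons),
    }
    for name, df in tables.items():
        path = out / f"{name}.csv"
        with path.open("w") as fh:
            fh.write(f"# gammakit config_hash={chash} seed={cfg.seed}\n")
            df.to_csv(fh, index=False)
    (out / "run.log").write_text(
        f"config_hash: {chash}\nseed: {cfg.seed}\narms: {[a.name for a in cfg.arms]}\n"
    )
    return tables
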