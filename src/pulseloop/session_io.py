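"""Readers, writers, configuration and the reproducible run pipeline.

EEG is carried as EDF (16-bit, physical microvolts) with firing events in
a ``time_s,kind`` CSV sidecar; engine logs (features, feedback, trials,
thresholds) are JSONL; run reports are JSON with input hashes and the
resolved configuration echoed, so every statistic in a report is traceable
to its inputs and seed.

The EDF writer emits plain EDF (one 1 s data record per second, int16
little-endian, per-channel physical scaling); recordings whose length is
not a whole number of seconds are zero-padded into the final record.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np

from .recording import EEGRecording

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording to EDF with per-channel physical scaling."""
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record per channel
    n_rec = int(np.ceil(rec.n_samples / spr))
    ns = rec.n_channels
    data = np.zeros((ns, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None]) + _EDF_DIG_MIN
    digital = digital.astype("<i2")

    with path.open("wb") as f:
        header_bytes = 256 + ns * 256
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate X X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(ns), 4))
        for lab in rec.labels:
            f.write(_pad(lab, 16))
        f.write(_pad("", 80) * ns)
        f.write(_pad("uV", 8) * ns)
        for v in pmin:
            f.write(_pad(f"{v:.10g}"[:8], 8))
        for v in pmax:
            f.write(_pad(f"{v:.10g}"[:8], 8))
        f.write(_pad(str(_EDF_DIG_MIN), 8) * ns)
        f.write(_pad(str(_EDF_DIG_MAX), 8) * ns)
        f.write(_pad("", 80) * ns)
        f.write(_pad(str(spr), 8) * ns)
        f.write(_pad("", 32) * ns)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())
    return path


def read_recording(path: str | Path, events: Iterable[tuple[float, str]] | None = None) -> EEGRecording:
    """Read an EDF file written by :func:`write_recording` (plain EDF, any
    integer record layout) back into physical microvolts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open("rb") as f:
        head = f.read(256)
        n_rec = int(head[236:244].decode().strip())
        dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig = f.read(ns * 256)

        # field offsets in bytes within the per-signal header region:
        # label 16*ns, transducer 80*ns, dim 8*ns, phys_min 8*ns, phys_max 8*ns,
        # dig_min 8*ns, dig_max 8*ns, prefilter 80*ns, samples 8*ns
        def region(start: int, width: int) -> list[str]:
            return [sig[start + i * width : start + (i + 1) * width].decode().strip()
                    for i in range(ns)]

        o = 0
        labels = region(o, 16); o += 16 * ns
        o += 80 * ns  # transducer
        o += 8 * ns   # dimension
        phys_min = np.array([float(v) for v in region(o, 8)]); o += 8 * ns
        phys_max = np.array([float(v) for v in region(o, 8)]); o += 8 * ns
        dig_min = np.array([float(v) for v in region(o, 8)]); o += 8 * ns
        dig_max = np.array([float(v) for v in region(o, 8)]); o += 8 * ns
        o += 80 * ns  # prefilter
        spr = np.array([int(v) for v in region(o, 8)])
        if len(set(spr)) != 1:
            raise ValueError("mixed per-channel rates are not supported")
        raw = np.frombuffer(f.read(n_rec * int(spr.sum()) * 2), dtype="<i2")

    spr0 = int(spr[0])
    raw = raw.reshape(n_rec, ns, spr0)
    digital = raw.transpose(1, 0, 2).reshape(ns, n_rec * spr0).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    rate = spr0 / dur
    return EEGRecording(data=data, rate=rate, labels=tuple(labels),
                        events=list(events) if events else [])


# ---------------------------------------------------------------------------
# Event CSV


def write_events(events: Iterable[tuple[float, str]], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["time_s", "kind"])
        for t, kind in events:
            w.writerow([f"{float(t):.6f}", kind])
    return path


def read_events(path: str | Path) -> list[tuple[float, str]]:
    path = Path(path)
    out: list[tuple[float, str]] = []
    with path.open(newline="") as f:
        r = csv.reader(f)
        header = next(r)
        if header[:2] != ["time_s", "kind"]:
            raise ValueError("event CSV must start with header time_s,kind")
        prev = -np.inf
        for row in r:
            t = float(row[0])
            if t < prev:
                raise ValueError("event rows must be time-ordered")
            prev = t
            out.append((t, row[1]))
    return out


# ---------------------------------------------------------------------------
# JSONL logs


def write_jsonl(records: Iterable[dict], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as f:
        for r in records:
            f.write(json.dumps(r, sort_keys=True) + "\n")
    return path


def read_jsonl(path: str | Path) -> list[dict]:
    with Path(path).open() as f:
        return [json.loads(line) for line in f if line.strip()]


# ---------------------------------------------------------------------------
# Run configuration


_KNOWN_KEYS = {
    "mode", "seed", "n_blocks", "shots_per_block", "isi_range_s",
    "calibration_s", "rate", "n_channels", "filter_order",
    "step_sigma_frac", "success_criterion", "window_scheme",
    "min_interval_s", "agent", "analysis", "paths",
}
_KNOWN_AGENT_KEYS = {"gain", "noise_sd", "baseline_amp", "lapse_prob"}
_KNOWN_ANALYSIS_KEYS = {"freqs_lo", "freqs_hi", "n_perm", "epoch_window_s", "tfr_channels"}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    mode: str = "theta-suppress"
    seed: int = 0
    n_blocks: int = 4
    shots_per_block: int = 10
    isi_range_s: tuple[float, float] = (6.0, 12.0)
    calibration_s: float = 60.0
    rate: float = 1000.0
    n_channels: int = 32
    filter_order: int = 180
    step_sigma_frac: float = 0.75
    success_criterion: float = 0.7
    window_scheme: str = "overlap4"
    min_interval_s: float = 3.0
    agent: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "RunConfig":
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if unknown_a := set(mapping.get("agent", {})) - _KNOWN_AGENT_KEYS:
            raise ValueError(f"unknown agent keys: {sorted(unknown_a)}")
        if unknown_n := set(mapping.get("analysis", {})) - _KNOWN_ANALYSIS_KEYS:
            raise ValueError(f"unknown analysis keys: {sorted(unknown_n)}")
        kwargs = dict(mapping)
        if "isi_range_s" in kwargs:
            kwargs["isi_range_s"] = tuple(kwargs["isi_range_s"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with Path(path).open() as f:
            mapping = yaml.safe_load(f) or {}
        return cls.from_mapping(mapping)

    def resolved(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["isi_range_s"] = list(self.isi_range_s)
        return d


# ---------------------------------------------------------------------------
# Pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate -> closed loop -> offline analysis -> report.

    Writes the EDF recording, event CSV, JSONL logs, the resolved config
    and a JSON report whose statistics carry the input hashes and seed.
    Returns the report path.  Deterministic: the same config yields a
    byte-identical report.
    """
    from . import analysis, synth
    from .feedback import acoustic_params

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    protocol = synth.Protocol(
        mode=config.mode, n_blocks=config.n_blocks,
        shots_per_block=config.shots_per_block, isi_range_s=config.isi_range_s,
        calibration_s=config.calibration_s, rate=config.rate,
        n_channels=config.n_channels, filter_order=config.filter_order,
        step_sigma_frac=config.step_sigma_frac,
        success_criterion=config.success_criterion,
    )
    agent = synth.AgentParams(**config.agent)
    session = synth.simulate_closed_loop_session(agent, protocol, seed=config.seed)

    edf = write_recording(session.recording, out / "recording.edf")
    ev = write_events(session.recording.events, out / "events.csv")
    write_jsonl(
        ({"time_s": t, "level": lv, "feature_db": f} for t, lv, f in session.feedback_log),
        out / "feedback.jsonl",
    )
    write_jsonl(
        (
            {"fire_time_s": tr.fire_time_s, "window_values": list(tr.window_values),
             "hits": tr.hits, "success": tr.success}
            for tr in session.trial_log
        ),
        out / "trials.jsonl",
    )
    write_jsonl(
        (
            {"threshold": st.threshold, "sigma": st.sigma, "mode": st.mode,
             "boundaries": list(st.boundaries)}
            for st in session.threshold_history
        ),
        out / "thresholds.jsonl",
    )
    (out / "config.json").write_text(json.dumps(config.resolved(), sort_keys=True, indent=2))

    # offline analysis on the simulated session
    band = protocol.band
    ep = analysis.epoch_preshot(session.recording, window_s=config.analysis.get("epoch_window_s", 6.0))
    target_idx = ep.channel_index(band.channel)
    sub = analysis.Epochs(
        data=ep.data[:, [target_idx], :], times=ep.times, rate=ep.rate,
        labels=(band.channel,), n_dropped=ep.n_dropped,
    )
    tfr = analysis.morlet_tfr(
        sub, freqs=np.arange(config.analysis.get("freqs_lo", 4.0),
                             config.analysis.get("freqs_hi", 30.0) + 1.0),
    )
    roi = analysis.RoiSpec("target", (band.channel,), (band.f_lo, band.f_hi),
                           analysis.RESPONDER_WINDOW)
    target_power = analysis.roi_log_power(tfr, roi)
    fc = analysis.dwpli_matrix(ep, (band.f_lo, band.f_hi))
    metrics = analysis.graph_metrics(analysis.binarize_top_proportion(fc), fc)

    report = {
        "config": config.resolved(),
        "inputs": {"recording_edf_sha256": _sha256(edf), "events_csv_sha256": _sha256(ev)},
        "seed": config.seed,
        "baseline": {"mu_db": session.baseline_mu, "sigma_db": session.baseline_sigma},
        "blocks": [
            {"success_rate": b.success_rate, "threshold_before": b.threshold_before,
             "threshold_after": b.threshold_after}
            for b in session.block_log
        ],
        "n_trials": len(session.trial_log),
        "n_epochs_dropped": ep.n_dropped,
        "target_band_log10_power": target_power,
        "global_fc": analysis.global_fc(fc),
        "graph_metrics": dataclasses.asdict(metrics),
        "feedback_levels_used": sorted({lv for _, lv, _ in session.feedback_log}),
        "acoustics": {str(l): dataclasses.asdict(acoustic_params(l)) for l in range(1, 6)},
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2))
    return report_path
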