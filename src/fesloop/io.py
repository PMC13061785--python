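"""File formats and run manifests: CSV streams, YAML configuration, EDF hand-off.

All CSV files are comma-separated with a mandatory header row, '.' decimal
and UTF-8 encoding.  Floats are written with ``repr`` precision so that
re-running a seeded simulation reproduces files byte for byte.
"""

from __future__ import annotations

import datetime
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controller import (
    PhaseDefinition,
    StimCommand,
    TaskConfig,
    build_gait_config,
    build_pedaling_config,
)
from .imu import AngleTrace, CycleSegmentation, ImuSample
from .stim import StimParams

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "write_angle_csv",
    "write_events_csv",
    "read_events_csv",
    "write_command_log",
    "read_command_log",
    "load_task_config",
    "dump_task_config",
    "write_manifest",
]

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# IMU / angle / events


def write_imu_csv(samples: Sequence[ImuSample], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"t": [s.t for s in samples],
         "ax": [s.ax for s in samples],
         "ay": [s.ay for s in samples]}
    )
    _write_csv(df, path)
    return path


def read_imu_csv(path: str | Path, strict: bool = False) -> list[ImuSample]:
    """Read a t,ax,ay stream.  Malformed rows are skipped with a warning
    count unless ``strict``; a file with no valid rows is an error."""
    import warnings

    df = pd.read_csv(path)
    missing = {"t", "ax", "ay"} - set(df.columns)
    if missing:
        raise ValueError(f"IMU CSV missing columns: {sorted(missing)}")
    samples = []
    bad = 0
    for row in df.itertuples(index=False):
        try:
            t, ax, ay = float(row.t), float(row.ax), float(row.ay)
            if not (np.isfinite(t) and np.isfinite(ax) and np.isfinite(ay)):
                raise ValueError("non-finite value")
            samples.append(ImuSample(t, ax, ay))
        except (TypeError, ValueError):
            if strict:
                raise
            bad += 1
    if bad:
        warnings.warn(f"skipped {bad} malformed IMU row(s)")
    if not samples:
        raise ValueError("IMU CSV contains no valid samples")
    return samples


def write_angle_csv(trace: AngleTrace, path: str | Path) -> Path:
    path = Path(path)
    _write_csv(pd.DataFrame({"t": trace.t, "theta": trace.theta}), path)
    return path


def write_events_csv(seg: CycleSegmentation, path: str | Path) -> Path:
    path = Path(path)
    periods = np.append(seg.periods, np.nan)  # last boundary starts no cycle
    df = pd.DataFrame(
        {"boundary_index": seg.boundaries,
         "boundary_time": seg.boundary_times,
         "period": periods[: seg.boundaries.size]}
    )
    _write_csv(df, path)
    return path


def read_events_csv(path: str | Path) -> CycleSegmentation:
    df = pd.read_csv(path)
    return CycleSegmentation(
        boundaries=df["boundary_index"].to_numpy(int),
        boundary_times=df["boundary_time"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# command log


def write_command_log(commands: Sequence[StimCommand], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "t": c.t,
            "phase": c.phase or "",
            "active_channels": "|".join(str(ch) for ch in sorted(c.active_channels)),
            "frequency_hz": c.params.frequency,
            "pulse_width_us": c.params.pulse_width,
            "intensity_pct": c.params.intensity,
        }
        for c in commands
    ]
    _write_csv(pd.DataFrame(rows), path)
    return path


def read_command_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["active_channels"] = df["active_channels"].apply(
        lambda s: frozenset(int(x) for x in str(s).split("|") if x)
    )
    return df


# ---------------------------------------------------------------------------
# task configuration (YAML)


def dump_task_config(config: TaskConfig, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "mode": config.mode,
        "phases": [
            {
                "name": p.name,
                "theta_min": p.theta_min,
                "theta_max": p.theta_max,
                "channels": sorted(p.channels),
                "muscles": {int(k): v for k, v in p.muscles.items()},
            }
            for p in config.phases
        ],
        "stim": {
            "frequency_hz": config.stim.frequency,
            "pulse_width_us": config.stim.pulse_width,
            "intensity_pct": config.stim.intensity,
            "waveform_sample_rate_hz": config.stim.waveform_sample_rate,
        },
        "min_dwell_s": config.min_dwell,
        "max_command_rate_hz": config.max_command_rate,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_task_config(path: str | Path) -> TaskConfig:
    doc = yaml.safe_load(Path(path).read_text())
    stim_doc = doc.get("stim", {})
    stim = StimParams(
        frequency=float(stim_doc.get("frequency_hz", 35.0)),
        pulse_width=float(stim_doc.get("pulse_width_us", 300.0)),
        intensity=float(stim_doc.get("intensity_pct", 75.0)),
        waveform_sample_rate=float(stim_doc.get("waveform_sample_rate_hz", 100_000.0)),
    )
    phases = [
        PhaseDefinition(
            name=p["name"],
            theta_min=float(p["theta_min"]),
            theta_max=float(p["theta_max"]),
            channels=frozenset(int(c) for c in p["channels"]),
            muscles={int(k): str(v) for k, v in p.get("muscles", {}).items()},
        )
        for p in doc["phases"]
    ]
    return TaskConfig(
        mode=doc["mode"],
        phases=phases,
        stim=stim,
        min_dwell=float(doc.get("min_dwell_s", 0.1)),
        max_command_rate=float(doc.get("max_command_rate_hz", 50.0)),
    )


def default_task_config(mode: str) -> TaskConfig:
    if mode == "pedaling":
        return build_pedaling_config()
    if mode == "gait":
        return build_gait_config()
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# manifest


def write_manifest(
    out_dir: str | Path,
    configs: dict,
    seeds: dict,
    inputs: Optional[dict] = None,
    outputs: Optional[dict] = None,
) -> Path:
    """Write the run manifest (YAML): config snapshot, seeds, paths, version.

    The manifest is the only output that carries a wall-clock timestamp;
    everything else is reproducible byte-for-byte from configs and seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _plain(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return _plain(asdict(obj))
        if isinstance(obj, dict):
            return {str(k): _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return [_plain(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    doc = {
        "tool": "fesloop",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seeds": _plain(seeds),
        "configs": _plain(configs),
        "inputs": _plain(inputs or {}),
        "outputs": _plain(outputs or {}),
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
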