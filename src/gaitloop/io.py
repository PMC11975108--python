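"""Readers and writers for the toolkit's on-disk formats.

All delimited files carry units in their headers (mm, mN, V, s; human-model
forces in N) to prevent cross-species unit mix-ups.  Numeric round-trips are
exact at the written precision (floats are written with repr-faithful
formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .hill import HillParameters, SimResult
from .histology import Channel, ChannelImage, FiberLabelMap, SegmentationParams
from .metrics import ForceTrace
from .protocol import CommandWaveform, HumanGaitTrace, ProtocolTimeline

__all__ = [
    "read_gait_trace_csv", "write_gait_trace_csv",
    "write_command_csv", "read_command_csv",
    "write_timeline_json", "timeline_table",
    "write_sim_result_csv", "read_force_trace_csv",
    "write_fiber_table_csv", "write_label_tiff", "read_channel_tiff",
    "load_segmentation_params", "load_hill_params", "load_architectures",
]

GAIT_HEADER = ["time_s", "fiber_length_mm", "excitation", "force_N"]
COMMAND_HEADER = ["time_s", "delta_length_mm", "voltage_V"]
FORCE_HEADER = ["time_s", "force_mN"]
SIM_HEADER = ["time_s", "activation", "norm_length", "force_mN"]


def read_gait_trace_csv(path: str | Path) -> HumanGaitTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAIT_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"gait trace CSV missing columns {missing}")
    return HumanGaitTrace(df["time_s"].to_numpy(), df["fiber_length_mm"].to_numpy(),
                          df["excitation"].to_numpy(), df["force_N"].to_numpy())


def write_gait_trace_csv(trace: HumanGaitTrace, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": trace.time_s, "fiber_length_mm": trace.fiber_length_mm,
        "excitation": trace.excitation, "force_N": trace.force_n,
    }).to_csv(path, index=False)


def write_command_csv(cmd: CommandWaveform, path: str | Path,
                      sidecar: dict | None = None) -> None:
    """Write the command CSV plus a JSON sidecar with protocol metadata."""
    path = Path(path)
    pd.DataFrame({
        "time_s": cmd.time_s, "delta_length_mm": cmd.delta_length_mm,
        "voltage_V": cmd.voltage_v,
    }).to_csv(path, index=False)
    meta = {"sample_rate_hz": cmd.sample_rate_hz,
            "stim_freq_hz": cmd.stim_freq_hz, **cmd.meta, **(sidecar or {})}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_command_csv(path: str | Path) -> CommandWaveform:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    rate = meta.get("sample_rate_hz")
    if rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / float(np.median(dt))
    return CommandWaveform(df["time_s"].to_numpy(), df["delta_length_mm"].to_numpy(),
                           df["voltage_V"].to_numpy(), float(rate),
                           stim_freq_hz=meta.get("stim_freq_hz"),
                           meta={k: v for k, v in meta.items()
                                 if k not in ("sample_rate_hz", "stim_freq_hz")})


def write_timeline_json(tl: ProtocolTimeline, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"protocol": tl.protocol, "total_span_s": tl.total_span_s,
         "events": tl.to_records()}, indent=2))


def timeline_table(tl: ProtocolTimeline) -> pd.DataFrame:
    return pd.DataFrame(tl.to_records())


def write_sim_result_csv(res: SimResult, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": res.time_s, "activation": res.activation,
        "norm_length": res.norm_length, "force_mN": res.force_mn,
    }).to_csv(path, index=False)


def read_force_trace_csv(path: str | Path,
                         markers_json: str | Path | None = None) -> ForceTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FORCE_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"force trace CSV missing columns {missing}")
    boundaries = None
    markers: dict = {}
    if markers_json is not None:
        info = json.loads(Path(markers_json).read_text())
        if "cycle_boundaries" in info:
            boundaries = tuple((float(a), float(z))
                               for a, z in info["cycle_boundaries"])
        markers = info.get("protocol_markers", {})
    return ForceTrace(df["time_s"].to_numpy(), df["force_mN"].to_numpy(),
                      boundaries, markers)


def write_fiber_table_csv(fmap: FiberLabelMap, path: str | Path) -> None:
    df = fmap.fibers.reset_index()[["fiber_id", "area_px", "layer_index",
                                    "dye_fraction", "positive", "excluded"]]
    df.to_csv(path, index=False)


def write_label_tiff(fmap: FiberLabelMap, path: str | Path) -> None:
    if fmap.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed the 16-bit TIFF range")
    tifffile.imwrite(path, fmap.labels.astype(np.uint16))


def read_channel_tiff(path: str | Path, channel: Channel | str) -> ChannelImage:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        raise ValueError("expected a single-channel TIFF; pass each channel "
                         "separately or split the stack first")
    data = np.asarray(arr, dtype=float)
    if np.issubdtype(arr.dtype, np.integer):
        data = data / np.iinfo(arr.dtype).max
    return ChannelImage(data, Channel(channel))


def load_segmentation_params(path: str | Path) -> SegmentationParams:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(SegmentationParams.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown segmentation parameters: {sorted(unknown)}")
    return SegmentationParams(**raw)


def load_architectures(path: str | Path) -> dict[str, "object"]:
    """Load per-muscle architecture constants from a YAML config.

    Returns a mapping of muscle name to :class:`MuscleArchitecture`.  See
    ``examples/architecture_example.yaml`` for the expected layout; the
    example values are representative, not measurements.
    """
    from .protocol import Muscle, MuscleArchitecture
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for name, fields in raw.items():
        out[name] = MuscleArchitecture(Muscle.coerce(name), **fields)
    return out


def load_hill_params(path: str | Path) -> HillParameters:
    text = Path(path).read_text()
    raw = (json.loads(text) if str(path).endswith(".json")
           else yaml.safe_load(text)) or {}
    valid = set(HillParameters.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown Hill parameters: {sorted(unknown)}")
    return HillParameters(**raw)
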