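"""File round-tripping, input validation and run manifests.

Formats are deliberately plain: multi-page TIFF (one page per channel, fixed
channel order) with a JSON sidecar for pixel size / seed / ground truth;
CSV for plate feature tables, spike-time tables and calcium ROI × frame
matrices; JSON for screen results and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import PipelineConfig, config_hash
from .synth import ArrayRecording, CalciumTraceSet, ImageField

__all__ = [
    "CHANNEL_ORDER",
    "write_field",
    "read_field",
    "write_plate_features",
    "read_plate_features",
    "write_spike_table",
    "read_spike_table",
    "write_calcium",
    "read_calcium",
    "validate_well",
    "validate_inputs",
    "RunManifest",
    "write_manifest",
]

CHANNEL_ORDER = ("DAPI", "MAP2", "FOS", "EGR1", "SYN1", "PSD95")

PLATE_COLUMNS = ["plate", "well", "row", "col", "condition", "compound_id",
                 "replicate", "nucleus_area", "nucleus_roundness",
                 "neurite_length", "n_segments", "frac_fos", "frac_egr1",
                 "frac_double", "nuclei_count"]


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_field(field: ImageField, path: str | Path,
                seed: Optional[int] = None) -> Path:
    """Write a field as multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    present = [ch for ch in CHANNEL_ORDER if ch in field.channels]
    stack = np.stack([field.channels[ch] for ch in present])
    tifffile.imwrite(path, stack)
    sidecar = {
        "channels": present,
        "pixel_size_um": field.pixel_size,
        "seed": seed,
        "ground_truth": _jsonable(field.ground_truth),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)
    return path


def read_field(path: str | Path) -> ImageField:
    path = Path(path)
    stack = tifffile.imread(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    channels = {ch: stack[i] for i, ch in enumerate(sidecar["channels"])}
    gt = sidecar.get("ground_truth")
    if gt is not None:
        for key in ("syn1_points", "psd95_points", "psd95_apposed"):
            if key in gt:
                gt[key] = np.asarray(gt[key])
    return ImageField(channels=channels,
                      pixel_size=sidecar["pixel_size_um"], ground_truth=gt)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_plate_features(df: pd.DataFrame, path: str | Path) -> Path:
    cols = [c for c in PLATE_COLUMNS if c in df.columns] + \
        [c for c in df.columns if c not in PLATE_COLUMNS]
    df[cols].to_csv(path, index=False)
    return Path(path)


def read_plate_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spike_table(rec: ArrayRecording, path: str | Path) -> Path:
    rows = [(ch, t) for ch, train in enumerate(rec.spike_trains or [])
            for t in train]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)
    return Path(path)


def read_spike_table(path: str | Path, n_channels: int, duration: float,
                     sampling_rate: float = 0.0,
                     grid_shape: tuple = (64, 64)) -> ArrayRecording:
    df = pd.read_csv(path)
    trains = [np.sort(df.loc[df["channel"] == ch, "time_s"].to_numpy())
              for ch in range(n_channels)]
    return ArrayRecording(n_channels=n_channels, grid_shape=grid_shape,
                          duration=duration, sampling_rate=sampling_rate,
                          spike_trains=trains)


def write_calcium(traces: CalciumTraceSet, path: str | Path) -> Path:
    df = pd.DataFrame(traces.traces,
                      columns=[f"f{j}" for j in range(traces.n_frames)])
    df.insert(0, "roi", np.arange(traces.traces.shape[0]))
    df.to_csv(path, index=False)
    return Path(path)


def read_calcium(path: str | Path, frame_interval: float) -> CalciumTraceSet:
    df = pd.read_csv(path)
    mat = df.drop(columns=["roi"]).to_numpy(dtype=float)
    return CalciumTraceSet(traces=mat, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_WELL_384 = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")
_WELL_96 = re.compile(r"^[A-H](0[1-9]|1[0-2])$")


def validate_well(well: str, plate_format: int = 384) -> bool:
    pat = _WELL_384 if plate_format == 384 else _WELL_96
    return bool(pat.match(well))


def validate_inputs(plate_features: Optional[pd.DataFrame] = None,
                    field: Optional[ImageField] = None,
                    calcium: Optional[CalciumTraceSet] = None,
                    calcium_schedule: Optional[tuple] = None,
                    spike_table: Optional[pd.DataFrame] = None,
                    plate_format: int = 384) -> list:
    """Validate inputs; returns a list of violation strings (empty = pass).

    Checks well-address grammar (A01–P24 for 384-well), stimulated /
    unstimulated pairing, required image channels, frame-count/schedule
    consistency and monotone per-channel spike times.
    """
    violations: list[str] = []
    if plate_features is not None:
        missing = [c for c in ("plate", "well", "condition", "compound_id",
                               "replicate") if c not in plate_features.columns]
        if missing:
            violations.append(f"feature table missing columns: {missing}")
        else:
            bad = sorted({w for w in plate_features["well"].unique()
                          if not validate_well(str(w), plate_format)})
            for w in bad:
                violations.append(f"invalid well address {w!r}")
            conds = set(plate_features["condition"].unique())
            for rep, rdf in plate_features.groupby("replicate"):
                have = set(rdf["condition"].unique())
                for missing_cond in {"stim", "unstim"} - have:
                    violations.append(
                        f"replicate {rep} lacks {missing_cond} plates")
            stim = plate_features[plate_features["condition"] == "stim"]
            unstim = plate_features[plate_features["condition"] == "unstim"]
            a = set(map(tuple, stim[["replicate", "plate", "well"]].to_numpy()))
            b = set(map(tuple,
                        unstim[["replicate", "plate", "well"]].to_numpy()))
            for orphan in sorted(a.symmetric_difference(b))[:10]:
                violations.append(f"unpaired plate well {orphan}")
    if field is not None:
        for ch in ("DAPI", "MAP2", "FOS", "EGR1"):
            if ch not in field.channels:
                violations.append(f"field missing channel {ch}")
    if calcium is not None and calcium_schedule is not None:
        interval, duration = calcium_schedule
        expected = duration / interval
        if calcium.n_frames != int(round(expected)) or \
                abs(expected - round(expected)) > 1e-9:
            violations.append(
                f"calcium trace has {calcium.n_frames} frames; declared "
                f"schedule ({interval} s over {duration} s) requires "
                f"{expected:g}")
    if spike_table is not None:
        for ch, cdf in spike_table.groupby("channel"):
            t = cdf["time_s"].to_numpy()
            if np.any(np.diff(t) < 0):
                violations.append(f"channel {ch} spike times not monotone")
    return violations


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    tool_version: str = __version__
    files: dict = field(default_factory=dict)   # path -> sha256
    timestamp: str = ""

    def content_dict(self) -> dict:
        """Everything except the timestamp (the reproducible part)."""
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: PipelineConfig, out_dir: str | Path,
                   files: list) -> RunManifest:
    out_dir = Path(out_dir)
    manifest = RunManifest(
        config_hash=config_hash(cfg), seed=cfg.seed,
        files={str(Path(f).name): _sha256(Path(f)) for f in files},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
    return manifest
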