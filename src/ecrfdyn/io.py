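"""Delimited-text formats, configs and run manifests.

Everything is plain inspectable text: stimulus logs and spike trains as CSV
with ``# key=value`` metadata header lines, LOR maps as a delimited matrix
with a lag header row and an orientation first column, models and run
configurations as YAML.  Numeric fields round-trip at full precision (floats
are written with repr-style %.17g formatting).
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .revcorr import LORMap
from .spikesim import (
    KernelSpec,
    NeuronModel,
    OrientationProfile,
    SpikeTrain,
    TemporalKernel,
)
from .stimgen import StimulusSequence, make_orientation_grid

__all__ = [
    "ParseError",
    "write_stimulus",
    "read_stimulus",
    "write_spikes",
    "read_spikes",
    "write_map",
    "read_map",
    "model_to_dict",
    "model_from_dict",
    "write_model",
    "read_model",
    "RunConfig",
    "write_config",
    "read_config",
    "write_manifest",
]


class ParseError(ValueError):
    """A schema violation in a delimited-text file, naming row and column."""


def _fmt(x: float) -> str:
    return "%.17g" % float(x)


def _meta_lines(meta: dict) -> list:
    return [f"# {k}={v}" for k, v in meta.items()]


def _read_meta_and_rows(path: Path):
    meta = {}
    rows = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            elif line:
                rows.append(line)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    reader = csv.reader(rows)
    header = next(reader)
    return meta, header, list(reader)


def _parse_float(value: str, row: int, column: str, path, allow_empty: bool = False):
    if value == "":
        if allow_empty:
            return float("nan")
        raise ParseError(f"{path}: row {row}: column '{column}' is empty")
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(f"{path}: row {row}: column '{column}' is not numeric: {value!r}") from exc


def _parse_int(value: str, row: int, column: str, path):
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"{path}: row {row}: column '{column}' is not an integer: {value!r}") from exc


# ---------------------------------------------------------------------------
# Stimulus logs
# ---------------------------------------------------------------------------

_STIM_COLUMNS = ["trial", "onset_ms", "duration_ms", "orientation_deg", "phase_deg", "is_blank"]


def write_stimulus(sequence: StimulusSequence, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "ecrfdyn-stimulus-v1",
        "trial_ms": _fmt(sequence.trial_ms),
        "frame_ms": _fmt(sequence.frame_ms),
        "n_trials": sequence.n_trials,
        "step_deg": _fmt(sequence.grid.step_deg),
        "p_blank": _fmt(sequence.p_blank),
        "phases": ";".join(_fmt(p) for p in sequence.phases),
        "seed": "none" if sequence.seed is None else sequence.seed,
    }
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(_meta_lines(meta)) + "\n")
        writer = csv.writer(fh)
        writer.writerow(_STIM_COLUMNS)
        for i in range(sequence.n_frames):
            blank = bool(sequence.is_blank[i])
            writer.writerow([
                int(sequence.trial[i]),
                _fmt(sequence.onset_ms[i]),
                _fmt(sequence.duration_ms[i]),
                "" if blank else _fmt(sequence.orientation_deg[i]),
                "" if blank else _fmt(sequence.phase_deg[i]),
                int(blank),
            ])


def read_stimulus(path) -> StimulusSequence:
    path = Path(path)
    meta, header, rows = _read_meta_and_rows(path)
    if header != _STIM_COLUMNS:
        raise ParseError(f"{path}: unexpected header {header}")
    n = len(rows)
    trial = np.empty(n, dtype=np.int64)
    onset = np.empty(n)
    duration = np.empty(n)
    orientation = np.empty(n)
    phase = np.empty(n)
    blank = np.empty(n, dtype=bool)
    for i, row in enumerate(rows):
        if len(row) != len(_STIM_COLUMNS):
            raise ParseError(f"{path}: row {i}: expected {len(_STIM_COLUMNS)} fields, got {len(row)}")
        trial[i] = _parse_int(row[0], i, "trial", path)
        onset[i] = _parse_float(row[1], i, "onset_ms", path)
        duration[i] = _parse_float(row[2], i, "duration_ms", path)
        blank[i] = bool(_parse_int(row[5], i, "is_blank", path))
        orientation[i] = _parse_float(row[3], i, "orientation_deg", path, allow_empty=blank[i])
        phase[i] = _parse_float(row[4], i, "phase_deg", path, allow_empty=blank[i])
    seed = None if meta.get("seed", "none") == "none" else int(meta["seed"])
    return StimulusSequence(
        trial=trial,
        onset_ms=onset,
        duration_ms=duration,
        orientation_deg=orientation,
        phase_deg=phase,
        is_blank=blank,
        trial_ms=float(meta["trial_ms"]),
        n_trials=int(meta["n_trials"]),
        frame_ms=float(meta["frame_ms"]),
        grid=make_orientation_grid(float(meta["step_deg"])),
        p_blank=float(meta["p_blank"]),
        phases=tuple(float(p) for p in meta["phases"].split(";")),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

_SPIKE_COLUMNS = ["trial", "spike_time_ms"]


def write_spikes(spikes: SpikeTrain, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "ecrfdyn-spikes-v1",
        "trial_ms": _fmt(spikes.trial_ms),
        "n_trials": spikes.n_trials,
        "seed": "none" if spikes.seed is None else spikes.seed,
        "model": spikes.description or "unspecified",
    }
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(_meta_lines(meta)) + "\n")
        writer = csv.writer(fh)
        writer.writerow(_SPIKE_COLUMNS)
        for t, s in zip(spikes.trial, spikes.time_ms):
            writer.writerow([int(t), _fmt(s)])


def read_spikes(path) -> SpikeTrain:
    path = Path(path)
    meta, header, rows = _read_meta_and_rows(path)
    if header != _SPIKE_COLUMNS:
        raise ParseError(f"{path}: unexpected header {header}")
    n = len(rows)
    trial = np.empty(n, dtype=np.int64)
    time = np.empty(n)
    for i, row in enumerate(rows):
        if len(row) != 2:
            raise ParseError(f"{path}: row {i}: expected 2 fields, got {len(row)}")
        trial[i] = _parse_int(row[0], i, "trial", path)
        time[i] = _parse_float(row[1], i, "spike_time_ms", path)
    seed = None if meta.get("seed", "none") == "none" else int(meta["seed"])
    return SpikeTrain(
        trial=trial,
        time_ms=time,
        n_trials=int(meta["n_trials"]),
        trial_ms=float(meta["trial_ms"]),
        seed=seed,
        description=meta.get("model", ""),
    )


# ---------------------------------------------------------------------------
# LOR maps
# ---------------------------------------------------------------------------

def write_map(lmap: LORMap, path) -> None:
    """Matrix text: header row of lag values, first column of orientations."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "ecrfdyn-lormap-v1",
        "pseudo_count": _fmt(lmap.pseudo_count),
        "baseline_sd": "none" if lmap.baseline_sd is None else _fmt(lmap.baseline_sd),
        "phase": "none" if lmap.phase is None else _fmt(lmap.phase),
    }
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(_meta_lines(meta)) + "\n")
        writer = csv.writer(fh)
        writer.writerow(["orientation_deg"] + [_fmt(l) for l in lmap.lags])
        for i, ori in enumerate(lmap.orientations):
            writer.writerow([_fmt(ori)] + [_fmt(v) for v in lmap.values[i]])


def read_map(path) -> LORMap:
    path = Path(path)
    meta, header, rows = _read_meta_and_rows(path)
    if header[0] != "orientation_deg":
        raise ParseError(f"{path}: unexpected header {header[:2]}...")
    lags = np.array([float(h) for h in header[1:]])
    orientations = np.empty(len(rows))
    values = np.empty((len(rows), len(lags)))
    for i, row in enumerate(rows):
        if len(row) != len(lags) + 1:
            raise ParseError(f"{path}: row {i}: expected {len(lags)+1} fields, got {len(row)}")
        orientations[i] = _parse_float(row[0], i, "orientation_deg", path)
        for j, v in enumerate(row[1:]):
            values[i, j] = _parse_float(v, i, f"lag_{lags[j]:g}", path)
    baseline_sd = None if meta.get("baseline_sd", "none") == "none" else float(meta["baseline_sd"])
    phase = None if meta.get("phase", "none") == "none" else float(meta["phase"])
    return LORMap(
        orientations=orientations,
        lags=lags,
        values=values,
        pseudo_count=float(meta["pseudo_count"]),
        baseline_sd=baseline_sd,
        phase=phase,
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def model_to_dict(model: NeuronModel) -> dict:
    return {
        "name": model.name,
        "baseline_rate_hz": model.baseline_rate_hz,
        "kernels": [
            {
                "component": k.component,
                "amplitude": k.temporal.amplitude,
                "mu_ms": k.temporal.mu_ms,
                "sd_ms": k.temporal.sd_ms,
                "orientation": {
                    "kind": k.orientation.kind,
                    "peak_deg": k.orientation.peak_deg,
                    "hwhh_deg": k.orientation.hwhh_deg,
                },
            }
            for k in model.kernels
        ],
    }


def model_from_dict(d: dict) -> NeuronModel:
    kernels = tuple(
        KernelSpec(
            component=k["component"],
            temporal=TemporalKernel(
                amplitude=float(k["amplitude"]),
                mu_ms=float(k["mu_ms"]),
                sd_ms=float(k["sd_ms"]),
            ),
            orientation=OrientationProfile(
                kind=k["orientation"]["kind"],
                peak_deg=float(k["orientation"].get("peak_deg", 0.0)),
                hwhh_deg=float(k["orientation"].get("hwhh_deg", 30.0)),
            ),
        )
        for k in d.get("kernels", [])
    )
    return NeuronModel(
        baseline_rate_hz=float(d["baseline_rate_hz"]),
        kernels=kernels,
        name=str(d.get("name", "")),
    )


def write_model(model: NeuronModel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=True)


def read_model(path) -> NeuronModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Run configuration and manifests
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a simulate -> revcorr -> components run."""

    seed: int = 0
    # stimulus
    step_deg: float = 20.0
    frame_ms: float = 20.0
    trial_ms: float = 10_000.0
    n_trials: int = 40
    p_blank: float = 1.0 / 19.0
    phases: tuple = (0.0, 180.0)
    # analysis
    lag_step_ms: float = 5.0
    max_lag_ms: float = 200.0
    pseudo_count: float = 1.0
    z_threshold: float = 2.0
    band_half_width_deg: float = 20.0
    # model
    model: Optional[dict] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = list(self.phases)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phases" in d:
            d["phases"] = tuple(d["phases"])
        return cls(**d)

    # derived substreams so every stage has its own reproducible seed
    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def write_config(config: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def write_manifest(path, **entries) -> None:
    """JSON run manifest (seeds, config hashes, output names)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
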