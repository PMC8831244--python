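"""Readers/writers and pipeline configuration.

Traces travel as two-column CSV (``time_s,value``) with a JSON sidecar
(``<name>.json``) holding sampling rate and annotations; movies as
multi-page TIFF with a JSON sidecar (frame rate, pixel size, anesthesia
frame); hypnograms as ``epoch_index,state`` CSV with W/N/R codes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .photometry import Hypnogram
from .traces import FluorescenceTrace
from .twophoton import ImagingMovie

__all__ = ["read_trace", "write_trace", "read_movie", "write_movie",
           "read_hypnogram", "write_hypnogram", "PipelineConfig"]

_STATE_CODES = {"W": "wake", "N": "NREM", "R": "REM"}
_CODE_OF = {v: k for k, v in _STATE_CODES.items()}


def _sidecar(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_trace(path, trace: FluorescenceTrace) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False)
    meta = {"sampling_rate": trace.sampling_rate, "t0": trace.t0,
            "annotations": [list(a) for a in trace.annotations]}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> FluorescenceTrace:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value")
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"{side}: missing sidecar with fields sampling_rate, t0, "
            "annotations")
    meta = json.loads(side.read_text())
    fs = float(meta["sampling_rate"])
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column not strictly increasing")
        if not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: non-uniform timestamps for "
                             f"sampling_rate={fs}")
    return FluorescenceTrace(
        values=df["value"].to_numpy(dtype=float), sampling_rate=fs,
        t0=float(meta.get("t0", t[0] if len(t) else 0.0)),
        annotations=[tuple(a) for a in meta.get("annotations", [])])


def write_movie(path, movie: ImagingMovie) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.frames))
    meta = {"frame_rate": movie.frame_rate,
            "pixel_size_um": movie.pixel_size_um,
            "anesthesia_off_frame": int(movie.anesthesia_off_frame)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_movie(path) -> ImagingMovie:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"{side}: missing sidecar with required fields frame_rate, "
            "pixel_size_um, anesthesia_off_frame")
    meta = json.loads(side.read_text())
    for key in ("frame_rate", "pixel_size_um", "anesthesia_off_frame"):
        if key not in meta:
            raise ValueError(f"{side}: missing required field {key!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImagingMovie(frames=frames, frame_rate=float(meta["frame_rate"]),
                        pixel_size_um=float(meta["pixel_size_um"]),
                        anesthesia_off_frame=int(
                            meta["anesthesia_off_frame"]))


def write_hypnogram(path, hyp: Hypnogram) -> None:
    pd.DataFrame({"epoch_index": np.arange(len(hyp.states)),
                  "state": [_CODE_OF[s] for s in hyp.states]}).to_csv(
        Path(path), index=False)


def read_hypnogram(path, epoch_length: float = 1.0) -> Hypnogram:
    df = pd.read_csv(Path(path))
    if not {"epoch_index", "state"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns epoch_index,state")
    bad = set(df["state"]) - set(_STATE_CODES)
    if bad:
        raise ValueError(f"{path}: unknown state codes {sorted(bad)}")
    df = df.sort_values("epoch_index")
    return Hypnogram(states=[_STATE_CODES[s] for s in df["state"]],
                     epoch_length=epoch_length)


@dataclasses.dataclass
class PipelineConfig:
    """YAML/JSON-round-trippable pipeline configuration.

    Unknown keys are rejected on load so typos never silently fall back
    to defaults.
    """

    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    # signal processing
    bin_width_s: float = 0.1
    savgol_window_s: float = 4.0
    savgol_polyorder: int = 3
    detrend_anchor_s: float = 30.0
    baseline_window_s: float = 10.0
    exclude_below_r2: float = 0.5
    # locomotion
    mm_per_change: float = 2.0
    bout_min_changes: int = 65
    bout_run_window_s: float = 5.0
    bout_quiet_window_s: float = 1.0
    # line scan
    lowpass_cutoff_hz: float = 20.0
    membrane_threshold_frac: float = 0.5
    max_dye_latency_s: float = 0.05
    # two-photon
    search_start_s: float = 120.0
    search_end_s: float = 360.0
    smooth_sigma_px: float = 2.0
    psf_size_px: int = 39
    psf_sigma_px: float = 20.0
    rl_iterations: int = 10
    roi_diameter_px: float = 12.0
    n_active_rois: int = 10
    n_inactive_rois: int = 10

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys "
                             f"{sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=1))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
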