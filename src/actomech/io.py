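"""File formats, configuration, and run summaries.

Trajectories travel as delimited text with a commented unit header;
image stacks as multi-page TIFF with the pixel size and frame interval
recorded in ImageJ-style metadata; configuration as YAML with strict
key checking (unknown keys are an error, so typos cannot silently fall
back to defaults); every CLI run writes a machine-readable JSON
summary with the resolved configuration, seed, and package version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import ImageStack, TrajectorySet

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_stack",
    "read_stack",
    "load_config",
    "DEFAULT_CONFIG",
    "write_summary",
]

_TRAJ_HEADER = (
    "# trajectory table: id, frame, t [s], x [um], y [um], "
    "theta [rad, nematic], length [um]"
)


def write_trajectories(traj: TrajectorySet, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_TRAJ_HEADER + "\n")
        fh.write(f"# frame_interval_s: {traj.frame_interval}\n")
        fh.write(f"# pixel_size_um: {traj.pixel_size}\n")
        traj.data.to_csv(fh, index=False)


def read_trajectories(path: Union[str, Path]) -> TrajectorySet:
    path = Path(path)
    frame_interval, pixel_size = 1.0, 1.0
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "frame_interval_s:" in line:
                frame_interval = float(line.split(":")[1])
            elif "pixel_size_um:" in line:
                pixel_size = float(line.split(":")[1])
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return TrajectorySet(df, frame_interval=frame_interval, pixel_size=pixel_size)


def write_stack(stack: ImageStack, path: Union[str, Path]) -> None:
    tifffile.imwrite(
        Path(path),
        stack.frames.astype(np.float32),
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={
            "unit": "um",
            "finterval": stack.frame_interval,
            "axes": "TYX",
        },
    )


def read_stack(
    path: Union[str, Path],
    pixel_size: Optional[float] = None,
    frame_interval: Optional[float] = None,
) -> ImageStack:
    with tifffile.TiffFile(Path(path)) as tf:
        frames = tf.asarray()
        meta = tf.imagej_metadata or {}
        if pixel_size is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
        if frame_interval is None:
            frame_interval = meta.get("finterval")
    if pixel_size is None:
        raise ValueError(
            "pixel_size missing from TIFF metadata; pass it explicitly"
        )
    if frame_interval is None:
        frame_interval = 1.0
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(
        frames.astype(float), pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Defaults mirror the analysis conventions: 32-px PIV windows at 0.5
#: overlap, 3.5-um orientation windows at 0.8 overlap, 40 two-point
#: bins over 3-20 um with first-10-lag averaging, 3-frame link gap,
#: 0.1-um immobility floor, 40% autocorrelation fit fraction.
DEFAULT_CONFIG: Dict[str, Dict] = {
    "units": {"pixel_size": None, "frame_interval": 1.0},
    "generate": {
        "kind": "brownian",
        "n_traj": 300,
        "n_steps": 600,
        "dt": 1.0,
        "D": 0.01,
        "hurst": 0.5,
        "scale": 1.0,
        "pattern": "stripes",
        "size_px": 256,
        "params": {},
        "amplitude": 0.5,
        "tau_v": 22.0,
        "t_max": 150.0,
        "noise_sd": 0.0,
    },
    "simulate": {
        "c_actin": 200.0,
        "r_arp": 0.01,
        "r_motor": 0.0025,
        "n_motors": None,
        "domain": [1.0, 1.0, 0.5],
        "arrangement": "biased",
        "volume_exclusion": True,
        "binding": True,
        "walking": True,
        "n_record": 100,
        "record_interval": 0.005,
        "z_density_bins": 10,
    },
    "track": {
        "min_area": 4,
        "threshold_mode": "otsu",
        "max_disp": 1.0,
        "max_gap": 3,
        "preprocess": True,
        "smooth_width": 0.1,
        "bg_width": 0.5,
    },
    "strain": {
        "window": 32,
        "overlap": 0.5,
        "cumulative": True,
        "pre_frames": 5,
        "post_frames": 50,
        "frame_interval": 3.0,
    },
    "order": {"window_um": 3.5, "overlap": 0.8},
    "pores": {"frame": 0},
    "rdf": {"dr": 0.2, "r_max": 5.0, "center_subsample": 2000},
    "msd": {"kind": "translational", "fit_min": None, "fit_max": None},
    "vanhove": {"lag": 1, "kind": "translational", "bins": 50},
    "ngp": {"lags": [1, 2, 5, 10, 20], "kind": "translational"},
    "tpc": {"r_min": 3.0, "r_max": 20.0, "n_bins": 40, "n_lags": 10},
    "rheo": {"bead_radius": 0.25, "temperature": 298.0},
    "autocorr": {"max_lag_frac": 0.5, "fit_frac": 0.4},
    "kvfit": {"t_start": 0.0},
    "kinematics": {"immobile_floor": 0.1},
    "seed": 0,
}


def _merge_strict(defaults: Dict, user: Dict, path="") -> Dict:
    out = dict(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict) and key != "params":
            out[key] = _merge_strict(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path: Optional[Union[str, Path]] = None, overrides: Optional[Dict] = None) -> Dict:
    """Load a YAML config merged over the defaults; unknown keys raise."""
    user: Dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge_strict(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge_strict(cfg, overrides)
    return cfg


def write_summary(path: Union[str, Path], command: str, config: Dict, results: Dict) -> None:
    from . import __version__

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    payload = {
        "command": command,
        "version": __version__,
        "config": _clean(config),
        "results": _clean(results),
    }
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
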