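"""CSV/TIFF/YAML interchange for traces, force curves, masks and configs."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .hertz import ForceCurve
from .osmotic import CellVolumeTrace

logger = logging.getLogger("cytomech")

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_force_curves_csv",
    "read_force_curves_csv",
    "write_stack",
    "read_stack",
    "load_config_file",
    "dump_config_file",
]


def write_traces_csv(traces: list[CellVolumeTrace], path: str | Path) -> None:
    """Write volume traces as tidy CSV: cell_id, t_s, volume_m3, step_label."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "t_s": tr.time,
                    "volume_m3": tr.volume,
                    "step_label": tr.step_index,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path, sampling_interval: float = 2.0) -> list[CellVolumeTrace]:
    """Read traces written by :func:`write_traces_csv`.

    Rows that fail numeric parsing are skipped with a log entry rather
    than aborting the run.
    """
    raw = pd.read_csv(path, dtype=str)
    for col in ("t_s", "volume_m3", "step_label"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    bad = raw[["t_s", "volume_m3", "step_label"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: skipped %d unparseable rows", path, int(bad.sum()))
        raw = raw[~bad]
    traces = []
    for cell_id, sub in raw.groupby("cell_id", sort=False):
        sub = sub.sort_values("t_s")
        traces.append(
            CellVolumeTrace(
                cell_id=str(cell_id),
                time=sub["t_s"].to_numpy(float),
                volume=sub["volume_m3"].to_numpy(float),
                step_index=sub["step_label"].to_numpy(int),
                sampling_interval=sampling_interval,
            )
        )
    return traces


def write_force_curves_csv(curves: list[ForceCurve], path: str | Path) -> None:
    """Tidy CSV of force curves: cell_id, tip_radius_m, z_m, force_N."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": c.cell_id,
                "tip_radius_m": c.tip_radius,
                "z_m": c.z,
                "force_N": c.force,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_force_curves_csv(path: str | Path) -> list[ForceCurve]:
    raw = pd.read_csv(path)
    curves = []
    for cell_id, sub in raw.groupby("cell_id", sort=False):
        curves.append(
            ForceCurve(
                z=sub["z_m"].to_numpy(float),
                force=sub["force_N"].to_numpy(float),
                tip_radius=float(sub["tip_radius_m"].iloc[0]),
                cell_id=str(cell_id),
            )
        )
    return curves


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (frames, H, W) float stack as 16-bit multi-page TIFF."""
    arr = np.asarray(stack)
    lo, hi = float(arr.min()), float(arr.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(
        path, ((arr - lo) * scale).astype(np.uint16), photometric="minisblack"
    )


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_config_file(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
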