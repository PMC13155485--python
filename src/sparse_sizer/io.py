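"""File-format plumbing: TIFF + JSON-sidecar speckle stacks, CSV tables.

A speckle stack on disk is a multi-page TIFF (t, y, x) plus a sidecar JSON
next to it (same stem, ``.json``) carrying the acquisition metadata the
analysis needs: ``frame_rate_hz``, ``exposure_s``, ``pixel_pitch_mm``,
``channel`` and ``polarization_axis_deg``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .metrics import AutocorrCurve, MetricVector, FrameStack

__all__ = [
    "SIDECAR_KEYS",
    "write_stack",
    "read_stack",
    "metrics_to_csv",
    "g2_to_csv",
]

SIDECAR_KEYS = (
    "frame_rate_hz",
    "exposure_s",
    "pixel_pitch_mm",
    "channel",
    "polarization_axis_deg",
)


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_stack(stack: FrameStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "exposure_s": stack.exposure,
        "pixel_pitch_mm": stack.pixel_pitch,
        "channel": stack.channel,
        "polarization_axis_deg": stack.polarization_axis_deg,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> FrameStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in SIDECAR_KEYS:
        if key not in meta:
            raise KeyError(f"sidecar {sidecar} is missing required key {key!r}")
    frames = tifffile.imread(path)
    return FrameStack(
        frames=frames,
        frame_rate=float(meta["frame_rate_hz"]),
        exposure=float(meta["exposure_s"]),
        pixel_pitch=float(meta["pixel_pitch_mm"]),
        channel=str(meta["channel"]),
        polarization_axis_deg=float(meta["polarization_axis_deg"]),
    )


def metrics_to_csv(mv: MetricVector, path) -> None:
    pd.DataFrame(
        [
            {
                "X1": mv.X1,
                "X2": mv.X2,
                "X3": mv.X3,
                "X4_mm": mv.X4,
                "t_max_s": mv.t_max,
                "peak_radial_fraction": mv.peak_radial_fraction,
            }
        ]
    ).to_csv(path, index=False)


def g2_to_csv(curves: dict[str, AutocorrCurve], path) -> None:
    frames = []
    for name, c in curves.items():
        frames.append(pd.DataFrame({"channel": name, "lag_s": c.lags, "g2": c.g2}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
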