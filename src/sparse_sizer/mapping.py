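"""Serpentine-scan assembly of metric and particle-size maps.

Each scan point contributes one co/cross stack pair; metric extraction and
size prediction run per point, and the results are placed on a regular grid
by stage coordinate (serpentine acquisition order is irrelevant — placement
is coordinate-driven).  Unvisited or failed points stay NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import io as sio
from .metrics import extract_metrics
from .sizing import ModelSet, predict_size

__all__ = ["ScanPoint", "ScanManifest", "SizeMap", "run_scan_analysis", "export_map"]

GRID_FIELDS = ("a", "X1", "X2", "X3", "X4", "cluster_id", "flags")


@dataclass(frozen=True)
class ScanPoint:
    stage_x: float  # mm
    stage_y: float  # mm
    co_path: str
    cross_path: str


@dataclass
class ScanManifest:
    points: list[ScanPoint]
    pitch: float  # mm
    serpentine: bool = True

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        coords = {(p.stage_x, p.stage_y) for p in self.points}
        if len(coords) != len(self.points):
            raise ValueError("duplicate stage coordinates in manifest")

    @classmethod
    def from_json(cls, path) -> "ScanManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            points=[ScanPoint(**p) for p in d["points"]],
            pitch=float(d["pitch"]),
            serpentine=bool(d.get("serpentine", True)),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "pitch": self.pitch,
                    "serpentine": self.serpentine,
                    "points": [vars(p) for p in self.points],
                },
                indent=1,
            )
        )


@dataclass
class SizeMap:
    grids: dict[str, np.ndarray]
    pitch: float  # mm
    origin: tuple[float, float]  # mm, first scan point
    failures: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.grids.values()}
        if len(shapes) != 1:
            raise ValueError("all map grids must share one shape")


def _grid_index(value: float, origin: float, pitch: float) -> int:
    q = (value - origin) / pitch
    idx = int(round(q))
    if abs(q - idx) > 0.25:
        raise ValueError(
            f"stage coordinate {value} mm is off-grid (pitch {pitch} mm, origin {origin} mm)"
        )
    return idx


def run_scan_analysis(
    manifest: ScanManifest,
    models: ModelSet,
    reader=sio.read_stack,
    **metric_kw,
) -> SizeMap:
    """Per-point metrics → size prediction → coordinate-driven map assembly.

    Points that fail (unreadable stack, degenerate metrics) are recorded as
    missing with the reason; if more than 20% fail, a prominent warning
    summarizes the failures.
    """
    if not manifest.points:
        raise ValueError("empty scan manifest")
    origin = (manifest.points[0].stage_x, manifest.points[0].stage_y)
    cols, rows = [], []
    for p in manifest.points:
        cols.append(_grid_index(p.stage_x, origin[0], manifest.pitch))
        rows.append(_grid_index(p.stage_y, origin[1], manifest.pitch))
    c0, r0 = min(cols), min(rows)
    nx = max(cols) - c0 + 1
    ny = max(rows) - r0 + 1
    grids = {name: np.full((ny, nx), np.nan) for name in GRID_FIELDS}
    failures: list[dict] = []

    for p, col, row in zip(manifest.points, cols, rows):
        i, j = row - r0, col - c0
        try:
            co = reader(p.co_path)
            cross = reader(p.cross_path)
            mv = extract_metrics(co, cross, **metric_kw)
            est = predict_size(mv, models)
        except (OSError, ValueError, KeyError) as exc:
            failures.append({"x": p.stage_x, "y": p.stage_y, "reason": str(exc)})
            continue
        grids["a"][i, j] = est.radius_a
        grids["X1"][i, j] = mv.X1
        grids["X2"][i, j] = mv.X2
        grids["X3"][i, j] = mv.X3
        grids["X4"][i, j] = mv.X4
        grids["cluster_id"][i, j] = est.cluster_id
        grids["flags"][i, j] = float(est.extrapolation_flag)

    if failures and len(failures) > 0.2 * len(manifest.points):
        warnings.warn(
            f"{len(failures)}/{len(manifest.points)} scan points failed: "
            + "; ".join(f["reason"] for f in failures[:5]),
            RuntimeWarning,
            stacklevel=2,
        )
    return SizeMap(grids=grids, pitch=manifest.pitch, origin=origin, failures=failures)


def export_map(size_map: SizeMap, out_dir, formats=("tiff", "csv", "png")) -> dict[str, Path]:
    """Write the map as float32 TIFFs (+pitch metadata), a CSV long table
    and a PNG panel (viridis, fixed limits from finite data).

    Missing points are NaN in TIFF/CSV — never zero-filled.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "tiff" in formats:
        for name, grid in size_map.grids.items():
            p = out_dir / f"map_{name}.tiff"
            tifffile.imwrite(
                p,
                grid.astype(np.float32),
                metadata={
                    "pitch_mm": size_map.pitch,
                    "origin_mm": list(size_map.origin),
                },
            )
            written[f"tiff:{name}"] = p
    if "csv" in formats:
        ny, nx = size_map.grids["a"].shape
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        rows = {
            "x_mm": size_map.origin[0] + jj.ravel() * size_map.pitch,
            "y_mm": size_map.origin[1] + ii.ravel() * size_map.pitch,
        }
        for name, grid in size_map.grids.items():
            rows[name] = grid.ravel()
        p = out_dir / "map_points.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written["csv"] = p
    if "png" in formats:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fields = ["a", "X1", "X2", "X3", "X4"]
        fig, axes = plt.subplots(1, len(fields), figsize=(3.2 * len(fields), 3))
        for ax, name in zip(np.atleast_1d(axes), fields):
            grid = size_map.grids[name]
            finite = grid[np.isfinite(grid)]
            vmin, vmax = (finite.min(), finite.max()) if finite.size else (0, 1)
            im = ax.imshow(grid, cmap="viridis", vmin=vmin, vmax=vmax, origin="upper")
            ax.set_title(name)
            fig.colorbar(im, ax=ax, shrink=0.8)
        p = out_dir / "map_panel.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["png"] = p
    return written


def load_map_tiff(path) -> np.ndarray:
    """Round-trip reader for a single exported map plane."""
    return tifffile.imread(path)
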