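"""On-disk formats: trajectory CSV, mask stacks, and deterministic results.

Trajectory CSV dialect: comma-separated, UTF-8, mandatory header with
columns ``frame,id,x,y`` and optionally ``time_s``; coordinates in cm, or
in px with a ``px_per_cm`` calibration passed to the reader.  Without a
time column a ``frame_rate`` (Hz) must be declared.  Results are written
bit-stably: fixed column order, floats at 9 significant digits, JSON with a
config echo and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import TrajectoryTable
from .errors import BinarizationError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_mask_stack",
    "write_mask_stack",
    "write_results",
    "read_results_json",
]

FLOAT_FMT = "%.9g"


def read_trajectory_csv(
    path: str | Path,
    px_per_cm: float | None = None,
    frame_rate: float | None = None,
    allow_gaps: bool = False,
) -> TrajectoryTable:
    """Read a tracker-export CSV into a validated :class:`TrajectoryTable`.

    ``px_per_cm=None`` means the file is already in cm.  If the file lacks a
    ``time_s`` column, times are ``frame / frame_rate``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["frame", "id", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if "time_s" not in df.columns:
        if frame_rate is None:
            raise FormatError(
                f"{path.name}: no time_s column and no frame_rate declared"
            )
        df["time_s"] = df["frame"].astype(float) / frame_rate
    scale = px_per_cm if px_per_cm else 1.0
    out = pd.DataFrame({
        "frame": df["frame"].astype(int),
        "id": df["id"].astype(str),
        "time_s": df["time_s"].astype(float),
        "x_cm": df["x"].astype(float) / scale,
        "y_cm": df["y"].astype(float) / scale,
    })
    table = TrajectoryTable.from_dataframe(out, allow_gaps=allow_gaps)
    logger.info("read %s: %d rows, %d individuals, dt=%g s (sha %s)",
                path.name, len(out), len(table.ids), table.dt, _digest(path))
    return table


def write_trajectory_csv(table: TrajectoryTable, path: str | Path) -> None:
    """Write a trajectory in the package's CSV dialect (cm, with time_s)."""
    df = table.data.rename(columns={"x_cm": "x", "y_cm": "y"})
    df[["frame", "id", "time_s", "x", "y"]].to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_mask_stack(
    path: str | Path,
    threshold: float | None = None,
    frame_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read a TIFF stack or a directory of PNG/TIFF frames as boolean masks.

    Directory contents are taken in lexicographic order.  Non-binary pixel
    values raise unless a ``threshold`` is configured.  Returns
    ``(masks, times_s)``; times come from ``frame_rate`` (default 1 Hz).
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FormatError(f"{path}: no PNG/TIFF frames found")
        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"{path}: inconsistent frame dimensions {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a 2D/3D stack, got shape {arr.shape}")

    if arr.dtype == bool:
        masks = arr
    else:
        vals = np.unique(arr)
        if threshold is None:
            if len(vals) <= 2:
                masks = arr > vals.min()
            else:
                raise BinarizationError(
                    f"{path}: {len(vals)} distinct pixel values; "
                    "configure a threshold to binarize"
                )
        else:
            a = arr.astype(float)
            if a.max() > 1:
                a = a / a.max()
            masks = a > threshold
    rate = frame_rate or 1.0
    times = np.arange(masks.shape[0]) / rate
    return masks.astype(bool), times


def write_mask_stack(masks: np.ndarray, path: str | Path) -> None:
    """Write boolean masks as an 8-bit TIFF stack (0/255)."""
    import tifffile

    tifffile.imwrite(path, (np.asarray(masks, bool) * np.uint8(255)),
                     photometric="minisblack")


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {c: _to_jsonable(obj[c].tolist()) for c in obj.columns}
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    return obj


def write_results(
    results,
    path: str | Path,
    format: str = "tsv",
    config: RunConfig | None = None,
) -> None:
    """Write pipeline outputs deterministically.

    TSV: ``results`` must be a DataFrame (or dict of columns); fixed column
    order, floats at 9 significant digits, so identical inputs give
    byte-identical files.  JSON: any nested structure; includes a config
    echo and the package version.
    """
    path = Path(path)
    if format == "tsv":
        df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
                  lineterminator="\n")
    elif format == "json":
        payload = {
            "package_version": __version__,
            "config": config.to_dict() if config is not None else None,
            "results": _to_jsonable(results),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise FormatError(f"unknown results format {format!r}")


def read_results_json(path: str | Path) -> dict:
    """Parse a results JSON written by :func:`write_results`."""
    return json.loads(Path(path).read_text())


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]
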