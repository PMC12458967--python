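"""Core in-memory containers shared across the analysis modules.

Tabular data lives in pandas DataFrames wrapped in thin dataclasses that
carry the extra scalars (sampling interval, worm id, ...) and enforce the
invariants the pipelines rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, IntegrityError, ParameterError, SamplingError

#: canonical trajectory column order
TRAJECTORY_COLUMNS = ["frame", "id", "time_s", "x_cm", "y_cm"]

DT_TOL = 1e-6  # seconds; tolerance on sampling-interval uniformity


def _validate_trajectory(df: pd.DataFrame, allow_gaps: bool) -> float:
    """Validate a trajectory frame and return the sampling interval.

    Raises IntegrityError on duplicate (frame, id) pairs or non-finite
    coordinates and SamplingError on non-uniform sampling.  With
    ``allow_gaps`` individuals may have missing frames as long as all times
    sit on one uniform grid.
    """
    dup = df.duplicated(subset=["frame", "id"])
    if dup.any():
        bad = df.loc[dup, ["frame", "id"]].head(5).to_records(index=False)
        raise IntegrityError(f"duplicate (frame, id) pairs, e.g. {list(bad)}")
    if not np.isfinite(df[["x_cm", "y_cm", "time_s"]].to_numpy()).all():
        raise IntegrityError("non-finite coordinates or times; drop missing rows instead")

    dts: list[float] = []
    for ind, sub in df.groupby("id", sort=False):
        t = sub["time_s"].to_numpy()
        t = np.sort(t)
        if len(t) < 2:
            continue
        d = np.diff(t)
        if (d <= 0).any():
            raise SamplingError(f"time not strictly increasing for individual {ind!r}")
        dts.append(d.min())
    if not dts:
        # single-frame table: fall back to the global frame/time mapping
        dts = [0.0]
    dt = float(min(dts))
    if dt > 0:
        for ind, sub in df.groupby("id", sort=False):
            t = np.sort(sub["time_s"].to_numpy())
            d = np.diff(t)
            if allow_gaps:
                # every diff must be an integer multiple of dt
                mult = d / dt
                off = np.abs(mult - np.round(mult)) * dt
                if (off > DT_TOL).any():
                    raise SamplingError(
                        f"individual {ind!r}: times not on a uniform {dt} s grid"
                    )
            else:
                if (np.abs(d - dt) > DT_TOL).any():
                    frames = np.sort(sub["frame"].to_numpy())
                    gaps = frames[:-1][np.abs(d - dt) > DT_TOL]
                    raise SamplingError(
                        f"individual {ind!r}: non-uniform sampling, gap(s) after "
                        f"frame(s) {gaps.tolist()} (expected dt={dt} s)"
                    )
    return dt


@dataclass
class TrajectoryTable:
    """Per-frame, per-individual arena positions with uniform sampling.

    ``data`` has columns ``frame, id, time_s, x_cm, y_cm``, one row per
    individual per frame, sorted by (time_s, id).  Missing detections are
    absent rows, never sentinel coordinates.  ``dt`` is the sampling
    interval in seconds.
    """

    data: pd.DataFrame
    dt: float

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, allow_gaps: bool = False) -> "TrajectoryTable":
        missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
        if missing:
            raise IntegrityError(f"trajectory missing columns: {missing}")
        df = df[TRAJECTORY_COLUMNS].copy()
        df["id"] = df["id"].astype(str)
        dt = _validate_trajectory(df, allow_gaps=allow_gaps)
        df = df.sort_values(["time_s", "id"], kind="mergesort").reset_index(drop=True)
        return cls(data=df, dt=dt)

    @property
    def ids(self) -> list[str]:
        return sorted(self.data["id"].unique())

    @property
    def n_frames(self) -> int:
        return self.data["frame"].nunique()

    @property
    def duration_s(self) -> float:
        t = self.data["time_s"]
        return float(t.max() - t.min()) + self.dt

    def window(self, t0: float, t1: float) -> "TrajectoryTable":
        """Rows with t0 <= time < t1 (half-open window)."""
        sub = self.data[(self.data["time_s"] >= t0) & (self.data["time_s"] < t1)]
        return TrajectoryTable(data=sub.reset_index(drop=True), dt=self.dt)


@dataclass
class MidlineSeries:
    """Per-frame ordered midline polylines for one worm.

    ``coords`` is (n_frames, n_points, 2) in the stated units; frames whose
    point counts differ are stored as a list instead.  ``meta`` carries
    ground-truth generator parameters when synthetic.
    """

    coords: np.ndarray | list[np.ndarray]
    times_s: np.ndarray
    units: str = "cm"
    px_per_cm: float | None = None
    worm_id: str = "worm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if len(self.coords) != n:
            raise IntegrityError(
                f"{len(self.coords)} frames of coordinates but {n} frame times"
            )
        for frame in self.coords:
            pts = np.asarray(frame, float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise GeometryError("each midline needs >=3 (x, y) points")
            if (np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0).any():
                raise GeometryError("midline has coincident consecutive points")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)


@dataclass
class PostureAngleSeries:
    """Mean-subtracted posture-angle vectors for one worm.

    ``angles`` is (n_frames, n_segments); each row sums to zero.  Dropped
    frames (coiled, failed segmentation) are listed in ``dropped`` as
    (frame index, reason).
    """

    angles: np.ndarray
    times_s: np.ndarray
    body_length: np.ndarray
    worm_id: str = "worm"
    representation: str = "angles"
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, float))
        if self.angles.shape[0] != len(self.times_s):
            raise IntegrityError("angle rows and frame times disagree")
        if self.angles.size:
            row_means = self.angles.mean(axis=1)
            if np.abs(row_means).max() > 1e-10:
                raise IntegrityError("posture rows must be mean-subtracted")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_segments(self) -> int:
        return self.angles.shape[1]


@dataclass
class EigenmodeBasis:
    """Orthonormal posture modes fitted on pooled frames.

    ``modes`` is (n_modes, n_segments); ``variance_fraction`` covers *all*
    covariance eigenvalues (sums to 1), not only the retained modes.
    """

    mean: np.ndarray
    modes: np.ndarray
    variance_fraction: np.ndarray
    n_frames_fit: int
    n_worms_fit: int

    def __post_init__(self) -> None:
        g = self.modes @ self.modes.T
        if not np.allclose(g, np.eye(len(self.modes)), atol=1e-10):
            raise IntegrityError("modes are not orthonormal")
        vf = np.asarray(self.variance_fraction, float)
        if vf.size and ((vf < -1e-12).any() or np.any(np.diff(vf) > 1e-12)):
            raise IntegrityError("variance fractions must be nonnegative, descending")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class AmplitudeSeries:
    """Per-frame mode projections a_1(t), ..., a_m(t) for one worm."""

    amplitudes: np.ndarray
    times_s: np.ndarray
    worm_id: str = "worm"

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, float))
        if not np.isfinite(self.amplitudes).all():
            raise IntegrityError("amplitudes must be finite")
        if self.amplitudes.shape[0] != len(self.times_s):
            raise IntegrityError("amplitude rows and frame times disagree")

    def radii(self) -> np.ndarray:
        """Per-frame distance from the origin in the (a1, a2) plane."""
        return np.hypot(self.amplitudes[:, 0], self.amplitudes[:, 1])


@dataclass
class ArenaGeometry:
    """Circular arena with an interior aversion-zone disc.

    Coordinates are in the arena frame: origin at the arena centre, y up,
    centimetres.  The zone is the closed disc of ``zone_radius_cm`` around
    ``zone_center_cm`` (boundary counts as inside).
    """

    arena_radius_cm: float
    zone_center_cm: tuple[float, float] = (0.0, 0.0)
    zone_radius_cm: float = 4.0

    def __post_init__(self) -> None:
        if self.zone_radius_cm <= 0:
            raise ParameterError("zone radius must be positive")
        cx, cy = self.zone_center_cm
        if np.hypot(cx, cy) + self.zone_radius_cm > self.arena_radius_cm + 1e-9:
            raise GeometryError("aversion zone must lie fully inside the arena")

    def in_zone(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.zone_center_cm
        return np.hypot(np.asarray(x) - cx, np.asarray(y) - cy) <= self.zone_radius_cm
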