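"""Run configuration.

A single flat record of every tunable the pipelines accept, so a run is fully
described by (inputs, config, seed).  TOML files are read with the standard
library; lossless round-tripping uses JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Parameters
    ----------
    n_points
        Number of equally spaced arc-length points the midline is resampled
        to; the posture vector has ``n_points - 1`` tangent angles.
    n_modes
        Number of posture eigenmodes retained for amplitude projection.
    representation
        ``"angles"`` (mean-subtracted tangent angles, default) or
        ``"curvature"`` (arc-length derivative of the tangent angle).
    density_bins
        Bins per axis of the square joint-amplitude histogram.
    density_span
        Half-width of the density grid; ``None`` auto-scales to 1.1x the
        largest absolute amplitude.
    zone_radius_cm
        Radius of the aversion zone around the repellent pad (cm).
    window_s
        Optional ``(t0, t1)`` analysis window in seconds, ``None`` = full
        recording.  The early-response window used for the citronella assay
        is ``(0, 240)``.
    rolling_k
        Window (frames, odd) of the centered rolling average applied to the
        nearest-neighbour series.
    antennation_distance_cm, antennation_min_duration_s, antennation_gap_s
        Contact-event detection thresholds: maximum inter-individual
        distance, minimum dwell time, and the refractory gap below which two
        runs are merged.  Conventions, not measured values.
    prune_frac
        Skeleton spur branches shorter than this fraction of the body length
        are pruned.
    smooth_sigma_px
        Gaussian sigma (in skeleton points, ~pixels) used to smooth the
        ordered skeleton polyline before resampling; 0 disables.
    mask_threshold
        Threshold applied to grayscale mask stacks; ``None`` requires the
        stack to be already binary.
    seed
        Seed for every stochastic step of a run.
    """

    n_points: int = 49
    n_modes: int = 2
    representation: str = "angles"
    density_bins: int = 51
    density_span: float | None = None
    zone_radius_cm: float = 4.0
    window_s: tuple[float, float] | None = None
    rolling_k: int = 5
    antennation_distance_cm: float = 0.5
    antennation_min_duration_s: float = 1.0
    antennation_gap_s: float = 0.5
    prune_frac: float = 0.10
    smooth_sigma_px: float = 2.0
    mask_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ParameterError(f"n_points must be >= 8, got {self.n_points}")
        if self.representation not in ("angles", "curvature"):
            raise ParameterError(
                f"representation must be 'angles' or 'curvature', got {self.representation!r}"
            )
        if self.rolling_k < 1 or self.rolling_k % 2 == 0:
            raise ParameterError(f"rolling_k must be odd and >= 1, got {self.rolling_k}")
        if self.window_s is not None:
            t0, t1 = self.window_s
            if not t0 < t1:
                raise ParameterError(f"window_s must satisfy t0 < t1, got {self.window_s}")
            self.window_s = (float(t0), float(t1))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["window_s"] is not None:
            d["window_s"] = list(d["window_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("window_s") is not None:
            d["window_s"] = tuple(d["window_s"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def digest(self) -> str:
        """Stable hash of the config, logged with every pipeline run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
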