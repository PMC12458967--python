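"""Synthetic worm midlines and ant arena trajectories with known ground truth.

The worm generator drives the body with a travelling tangent-angle wave,

    theta(s, t) = A * cos(2*pi*kappa*s/L - omega*t + phi0) + eps,

sampled at segment midpoints and integrated to a midline of exact arc
length L, so the posture pipeline's recovery of A is checkable in closed
form: for sigma = 0 and integer kappa the first two posture modes span the
(cos, sin) plane and every frame sits on a circle of radius A*sqrt(N/2),
N the number of tangent samples.

The ant generator is a reflected Gaussian random walk in a circular arena
with two optional drifts: repulsion away from the aversion-zone centre
(strength ``lambda_repel``, active inside a shell of 1.5x the zone radius)
and attraction toward the centroid of the other ants (strength ``g_social``).
Both default to zero, which leaves the walk's stationary distribution
approximately uniform over the arena — the calibration the occupancy
statistic is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import ArenaGeometry, MidlineSeries, TrajectoryTable
from .errors import GeometryError, ParameterError

__all__ = [
    "WaveParams",
    "ArenaSimParams",
    "simulate_worm_midlines",
    "rasterize_midline",
    "simulate_ant_arena",
    "simulate_antennation_dyad",
]


@dataclass
class WaveParams:
    """Travelling-wave parameters for the worm midline generator.

    ``n_segments`` counts the tangent-angle samples; the emitted midline has
    ``n_segments + 1`` points at arc step ``length_cm / n_segments``.  The
    defaults describe a crawling adult: 1 cm body, 0.5 Hz undulation
    (omega = pi rad/s), one wavelength on the body, 20 Hz video for 60 s.
    """

    amplitude: float = 0.6          # A, radians
    wavenumber: float = 1.0         # kappa, wavelengths per body length
    omega: float = np.pi            # rad/s
    phase0: float = 0.0             # phi0, rad
    length_cm: float = 1.0          # L
    n_segments: int = 48            # N tangent samples
    frame_rate: float = 20.0        # Hz
    duration_s: float = 60.0
    sigma: float = 0.0              # angle noise SD, rad
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.wavenumber <= 0:
            raise ParameterError("wavenumber must be > 0")
        if self.n_segments < 8:
            raise ParameterError("n_segments must be >= 8")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.length_cm <= 0 or self.frame_rate <= 0 or self.duration_s <= 0:
            raise ParameterError("length, frame rate and duration must be positive")


def simulate_worm_midlines(params: WaveParams) -> MidlineSeries:
    """Generate one worm's midline movie from a travelling tangent-angle wave.

    Angles are evaluated at segment midpoints s_i = (i + 1/2) L / N and the
    midline is the cumulative sum of unit tangents scaled by L/N, anchored at
    the origin — arc length is exactly L in every frame.  Ground-truth
    parameters are embedded in the output metadata.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = int(round(p.duration_s * p.frame_rate))
    times = np.arange(n_frames) / p.frame_rate
    s_mid = (np.arange(p.n_segments) + 0.5) * p.length_cm / p.n_segments

    phase = 2 * np.pi * p.wavenumber * s_mid[None, :] / p.length_cm \
        - p.omega * times[:, None] + p.phase0
    theta = p.amplitude * np.cos(phase)
    if p.sigma > 0:
        theta = theta + rng.normal(0.0, p.sigma, size=theta.shape)

    step = p.length_cm / p.n_segments
    dx = step * np.cos(theta)
    dy = step * np.sin(theta)
    coords = np.zeros((n_frames, p.n_segments + 1, 2))
    coords[:, 1:, 0] = np.cumsum(dx, axis=1)
    coords[:, 1:, 1] = np.cumsum(dy, axis=1)

    meta = {"generator": "traveling_wave", **p.__dict__}
    return MidlineSeries(coords=coords, times_s=times, units="cm", meta=meta)


def rasterize_midline(
    midline: np.ndarray,
    body_width_cm: float,
    image_size_px: tuple[int, int],
    px_per_cm: float,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Paint a midline polyline as a binary mask of the given body width.

    Foreground is every pixel whose centre lies within half the body width
    of the (densely resampled) polyline.  The image origin maps to
    ``center`` in midline coordinates (default: the polyline centroid), so
    the worm is drawn mid-frame.

    Raises GeometryError if the thickened midline does not fit in the image.
    """
    pts = np.asarray(midline, float)
    if center is None:
        center = pts.mean(axis=0)
    h, w = image_size_px
    # midline cm -> pixel coordinates (col, row), y up -> row down
    col = (pts[:, 0] - center[0]) * px_per_cm + (w - 1) / 2.0
    row = (h - 1) / 2.0 - (pts[:, 1] - center[1]) * px_per_cm
    half_w = body_width_cm * px_per_cm / 2.0
    if (col.min() < half_w or col.max() > w - 1 - half_w
            or row.min() < half_w or row.max() > h - 1 - half_w):
        raise GeometryError("midline (plus body width) exits the field of view")

    # dense resample of the polyline at quarter-pixel steps
    seg = np.diff(np.stack([col, row], axis=1), axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_dense = max(int(np.ceil(arc[-1] / 0.25)), 2)
    t = np.linspace(0, arc[-1], n_dense)
    dense = np.stack([np.interp(t, arc, col), np.interp(t, arc, row)], axis=1)

    tree = cKDTree(dense)
    rr, cc = np.mgrid[0:h, 0:w]
    pix = np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float)
    dist, _ = tree.query(pix, k=1)
    return (dist <= half_w).reshape(h, w)


@dataclass
class ArenaSimParams:
    """Parameters of the ant arena random walk.

    Defaults emulate a small observation arena: 9 cm radius, a 4 cm
    aversion zone at the centre, 10 ants sampled every 0.5 s for 10 min at
    0.3 cm per step (~0.6 cm/s).  ``lambda_repel`` and ``g_social`` are the
    drift magnitudes (cm per step) of zone avoidance and social attraction.
    """

    arena_radius_cm: float = 9.0
    zone_center_cm: tuple[float, float] = (0.0, 0.0)
    zone_radius_cm: float = 4.0
    n_ants: int = 10
    step_cm: float = 0.3
    lambda_repel: float = 0.0
    g_social: float = 0.0
    dt_s: float = 0.5
    duration_s: float = 600.0
    seed: int = 0
    repulsion_shell: float = 1.5    # repulsion active within shell * zone radius

    def __post_init__(self) -> None:
        if self.lambda_repel < 0 or self.g_social < 0:
            raise ParameterError("drift strengths must be >= 0")
        if self.n_ants < 1:
            raise ParameterError("need at least one ant")
        # validates zone containment too
        self.geometry = ArenaGeometry(
            self.arena_radius_cm, self.zone_center_cm, self.zone_radius_cm
        )


def _reflect_into_disc(pos: np.ndarray, radius: float) -> np.ndarray:
    """Radially mirror positions that stepped outside the arena boundary."""
    r = np.linalg.norm(pos, axis=-1, keepdims=True)
    out = r[..., 0] > radius
    if out.any():
        # reflect overshoot back across the circle: r -> 2R - r
        new_r = np.where(r > radius, np.maximum(2 * radius - r, 1e-9), r)
        pos = pos * (new_r / r)
        # pathological huge steps could reflect past the centre; clip
        r2 = np.linalg.norm(pos, axis=-1, keepdims=True)
        pos = np.where(r2 > radius, pos * (radius / r2) * 0.999, pos)
    return pos


def simulate_ant_arena(params: ArenaSimParams) -> TrajectoryTable:
    """Simulate ants as drifting random walkers in a circular arena.

    Per step each ant moves by an isotropic Gaussian step (SD ``step_cm``),
    plus ``lambda_repel`` cm away from the zone centre when inside the
    repulsion shell, plus ``g_social`` cm toward the centroid of the other
    ants; steps ending outside the arena are mirrored back inside.
    Positions are emitted every ``dt_s``; identical params + seed give
    identical tables.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_steps = int(round(p.duration_s / p.dt_s))
    zc = np.asarray(p.zone_center_cm, float)
    shell = p.repulsion_shell * p.zone_radius_cm

    # uniform initial positions in the arena disc
    pos = np.empty((p.n_ants, 2))
    filled = 0
    while filled < p.n_ants:
        cand = rng.uniform(-p.arena_radius_cm, p.arena_radius_cm, size=(p.n_ants, 2))
        ok = cand[np.linalg.norm(cand, axis=1) <= p.arena_radius_cm]
        take = min(len(ok), p.n_ants - filled)
        pos[filled:filled + take] = ok[:take]
        filled += take

    frames = np.empty((n_steps, p.n_ants, 2))
    for k in range(n_steps):
        step = rng.normal(0.0, p.step_cm, size=(p.n_ants, 2))
        if p.lambda_repel > 0:
            away = pos - zc
            d = np.linalg.norm(away, axis=1, keepdims=True)
            active = (d[:, 0] < shell) & (d[:, 0] > 1e-12)
            unit = np.where(d > 1e-12, away / np.maximum(d, 1e-12), 0.0)
            step[active] += p.lambda_repel * unit[active]
        if p.g_social > 0 and p.n_ants > 1:
            total = pos.sum(axis=0, keepdims=True)
            centroid_others = (total - pos) / (p.n_ants - 1)
            toward = centroid_others - pos
            d = np.linalg.norm(toward, axis=1, keepdims=True)
            unit = np.where(d > 1e-12, toward / np.maximum(d, 1e-12), 0.0)
            step += p.g_social * unit
        pos = _reflect_into_disc(pos + step, p.arena_radius_cm)
        frames[k] = pos

    ids = [f"ant{i:02d}" for i in range(p.n_ants)]
    rec = {
        "frame": np.repeat(np.arange(n_steps), p.n_ants),
        "id": np.tile(ids, n_steps),
        "time_s": np.repeat(np.arange(n_steps) * p.dt_s, p.n_ants),
        "x_cm": frames[:, :, 0].ravel(),
        "y_cm": frames[:, :, 1].ravel(),
    }
    return TrajectoryTable.from_dataframe(pd.DataFrame(rec))


def simulate_antennation_dyad(
    n_bouts: int,
    bout_duration_s: float = 2.0,
    gap_s: float = 8.0,
    contact_distance_cm: float = 0.3,
    apart_distance_cm: float = 3.0,
    dt_s: float = 0.5,
    seed: int = 0,
    jitter_cm: float = 0.0,
) -> TrajectoryTable:
    """Two ants with a programmed schedule of approach bouts.

    During each bout the dyad sits ``contact_distance_cm`` apart for
    ``bout_duration_s``; between bouts they sit ``apart_distance_cm`` apart
    for ``gap_s``.  The known bout count makes event detection testable.
    """
    if n_bouts < 0:
        raise ParameterError("n_bouts must be >= 0")
    rng = np.random.default_rng(seed)
    bout_f = max(int(round(bout_duration_s / dt_s)), 1)
    gap_f = max(int(round(gap_s / dt_s)), 1)
    sep = [apart_distance_cm] * gap_f
    for _ in range(n_bouts):
        sep += [contact_distance_cm] * bout_f + [apart_distance_cm] * gap_f
    sep = np.asarray(sep)
    n = len(sep)
    if jitter_cm > 0:
        sep = sep + rng.normal(0, jitter_cm, size=n)
    x0 = -sep / 2.0
    x1 = sep / 2.0
    rec = {
        "frame": np.repeat(np.arange(n), 2),
        "id": np.tile(["a", "b"], n),
        "time_s": np.repeat(np.arange(n) * dt_s, 2),
        "x_cm": np.stack([x0, x1], axis=1).ravel(),
        "y_cm": np.zeros(2 * n),
    }
    return TrajectoryTable.from_dataframe(pd.DataFrame(rec))
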