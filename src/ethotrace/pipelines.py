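"""End-to-end orchestration of the worm and ant analyses.

These are the library equivalents of "analyze this experiment": each takes
validated inputs plus a :class:`~ethotrace.config.RunConfig` and returns a
dictionary of containers/tables ready for :mod:`ethotrace.report` or
:func:`ethotrace.io.write_results`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import antspatial, eigenworm, posture
from .config import RunConfig
from .containers import ArenaGeometry, MidlineSeries, PostureAngleSeries, TrajectoryTable
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["analyze_worm_groups", "analyze_ant_trial", "compare_ant_clustering"]


def _as_posture(item, cfg: RunConfig) -> PostureAngleSeries:
    if isinstance(item, PostureAngleSeries):
        return item
    if isinstance(item, MidlineSeries):
        return posture.midlines_to_posture(
            item, n_points=cfg.n_points, representation=cfg.representation
        )
    raise ParameterError(f"cannot analyze object of type {type(item).__name__}")


def analyze_worm_groups(
    groups: dict[str, list], config: RunConfig | None = None
) -> dict:
    """Posture -> pooled PCA -> amplitudes -> radial statistic -> t-test.

    ``groups`` maps a group label to a list of worms (MidlineSeries or
    PostureAngleSeries).  The PCA is fitted on the pooled frames of all
    groups so amplitudes share one mode plane; with exactly two groups a
    two-sided t-test on the per-worm mean radii is included.
    """
    cfg = config or RunConfig()
    postures = {g: [_as_posture(w, cfg) for w in worms] for g, worms in groups.items()}
    pooled = [p for worms in postures.values() for p in worms]
    basis = eigenworm.fit_posture_pca(pooled, n_modes=cfg.n_modes)
    logger.info("PCA fit on %d frames from %d worms (config %s)",
                basis.n_frames_fit, basis.n_worms_fit, cfg.digest())

    amplitudes = {g: [eigenworm.project_amplitudes(basis, p) for p in worms]
                  for g, worms in postures.items()}
    radial = pd.concat(
        [eigenworm.radial_summary_table(amps, g) for g, amps in amplitudes.items()],
        ignore_index=True,
    )
    densities = {}
    for g, amps in amplitudes.items():
        a = np.vstack([x.amplitudes[:, :2] for x in amps])
        densities[g] = eigenworm.joint_density(
            a[:, 0], a[:, 1], n_bins=cfg.density_bins, span=cfg.density_span
        )

    out = {
        "config": cfg,
        "basis": basis,
        "postures": postures,
        "amplitudes": amplitudes,
        "radial_summary": radial,
        "densities": densities,
    }
    labels = list(groups)
    if len(labels) == 2:
        ra = radial.loc[radial["group"] == labels[0], "radial_mean"].to_numpy()
        rb = radial.loc[radial["group"] == labels[1], "radial_mean"].to_numpy()
        out["radial_test"] = eigenworm.compare_radial_groups(ra, rb)
        # reconstructed two-mode shapes at each group's mean radius
        phases = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        out["reconstructions"] = {
            g: eigenworm.reconstruct_shapes(
                basis, float(radial.loc[radial["group"] == g, "radial_mean"].mean()),
                phases)
            for g in labels
        }
    return out


def analyze_ant_trial(
    traj: TrajectoryTable,
    geometry: ArenaGeometry,
    config: RunConfig | None = None,
) -> dict:
    """All single-trial arena statistics for one tracked recording."""
    cfg = config or RunConfig()
    occ = antspatial.zone_occupancy(traj, geometry)
    out = {
        "config": cfg,
        "occupancy": occ,
        "nn_series": antspatial.mean_nn_series(traj),
        "antennation": antspatial.detect_antennation(
            traj,
            contact_distance_cm=cfg.antennation_distance_cm,
            min_duration_s=cfg.antennation_min_duration_s,
            gap_s=cfg.antennation_gap_s,
        ),
    }
    out["nn_rolling"] = antspatial.rolling_average(out["nn_series"], cfg.rolling_k)
    if cfg.window_s is not None:
        out["occupancy_window"] = antspatial.windowed_occupancy(
            traj, geometry, cfg.window_s
        )
    logger.info("ant trial: %d ants, occupancy %.4f, %d antennation events",
                len(traj.ids), occ.trial_mean, out["antennation"].count)
    return out


def compare_ant_clustering(
    series_by_trial: dict[str, antspatial.ClusterSeries],
    group_of: dict[str, str],
    treated_label: str,
    config: RunConfig | None = None,
    method: str = "lmm",
) -> dict:
    """Group-by-time clustering comparison plus the difference series.

    ``method="lmm"`` fits the mixed model with the permutation fallback;
    ``"permutation"`` uses the exact trial-label test directly.  The
    difference series averages the trials of each group at matching
    timestamps before smoothing.
    """
    cfg = config or RunConfig()
    test = antspatial.compare_groups(
        method, series_by_trial=series_by_trial, group_of=group_of,
        treated_label=treated_label, seed=cfg.seed,
    )

    def _group_mean(label: str) -> antspatial.ClusterSeries:
        members = [cs for t, cs in series_by_trial.items() if group_of[t] == label]
        stacked = pd.concat([m.data for m in members]).groupby("time_s", as_index=False).agg(
            mean_nn_cm=("mean_nn_cm", "mean"), n_ants=("n_ants", "mean"))
        return antspatial.ClusterSeries(data=stacked, dt=members[0].dt, kind="raw")

    control_label = next(g for g in set(group_of.values()) if g != treated_label)
    diff = antspatial.difference_series(
        _group_mean(treated_label), _group_mean(control_label), k=cfg.rolling_k
    )
    return {"config": cfg, "test": test, "difference": diff,
            "treated": treated_label, "control": control_label}
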