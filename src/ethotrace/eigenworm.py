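"""Posture PCA ("eigenworms"), amplitude projection and the radial statistic.

Crawling nematodes undulate with a travelling body wave; in the plane of
the first two posture eigenmodes a wave of amplitude A traces a ring of
radius ~ A*sqrt(N/2) (N angle samples), so the per-worm time-averaged
radius r_bar = <sqrt(a1^2 + a2^2)> is a direct readout of wave amplitude.
Group comparisons are two-sample t-tests on the per-worm r_bar values.

The PCA is fitted on the POOLED frames of all worms entering a comparison,
so both groups' amplitudes live in one common mode plane and their radii
are commensurable.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import AmplitudeSeries, EigenmodeBasis, PostureAngleSeries
from .errors import EmptyDensityError, ParameterError, StatisticsError
from .stats import TestResult, t_test

logger = logging.getLogger(__name__)

__all__ = [
    "fit_posture_pca",
    "project_amplitudes",
    "joint_density",
    "radial_statistic",
    "radial_summary_table",
    "reconstruct_shapes",
    "compare_radial_groups",
]


def _fix_sign(modes: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-|entry| positive, ties by
    lowest index (np.argmax already takes the first maximum)."""
    out = modes.copy()
    for i, m in enumerate(out):
        j = int(np.argmax(np.abs(m)))
        if m[j] < 0:
            out[i] = -m
    return out


def fit_posture_pca(
    series_list: list[PostureAngleSeries] | list[np.ndarray],
    n_modes: int = 2,
) -> EigenmodeBasis:
    """PCA of pooled posture-angle frames.

    Centering subtracts the pooled mean posture; modes come from the SVD of
    the centered data matrix (equivalent to the covariance
    eigendecomposition, which the test suite uses as an independent check).
    Variance fractions are reported over *all* eigenvalues and sum to 1.
    """
    mats = [s.angles if isinstance(s, PostureAngleSeries) else np.atleast_2d(s)
            for s in series_list]
    dims = {m.shape[1] for m in mats}
    if len(dims) != 1:
        raise ParameterError(f"inconsistent posture dimensions: {sorted(dims)}")
    dim = dims.pop()
    if not 1 <= n_modes <= dim:
        raise ParameterError(f"n_modes must be in [1, {dim}], got {n_modes}")
    X = np.vstack(mats)
    n = X.shape[0]
    if n <= dim:
        warnings.warn(
            f"only {n} pooled frames for {dim} dimensions; basis is rank-deficient",
            RuntimeWarning,
            stacklevel=2,
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data; right singular vectors are the modes
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s ** 2  # proportional to covariance eigenvalues
    total = ev.sum()
    if total <= 0:
        vf = np.zeros(Vt.shape[0])
        warnings.warn("zero posture covariance; all variance fractions are 0",
                      RuntimeWarning, stacklevel=2)
    else:
        vf = ev / total
    modes = _fix_sign(Vt[:n_modes])
    return EigenmodeBasis(
        mean=mean,
        modes=modes,
        variance_fraction=vf,
        n_frames_fit=n,
        n_worms_fit=len(mats),
    )


def project_amplitudes(
    basis: EigenmodeBasis, series: PostureAngleSeries
) -> AmplitudeSeries:
    """Project one worm's frames onto the fitted modes: a_i(t) = m_i . (x(t) - mean)."""
    if series.n_segments != basis.modes.shape[1]:
        raise ParameterError(
            f"posture dimension {series.n_segments} does not match basis "
            f"dimension {basis.modes.shape[1]}"
        )
    amps = (series.angles - basis.mean) @ basis.modes.T
    return AmplitudeSeries(amplitudes=amps, times_s=series.times_s,
                           worm_id=series.worm_id)


def joint_density(
    a1: np.ndarray,
    a2: np.ndarray,
    bin_edges: tuple[np.ndarray, np.ndarray] | None = None,
    n_bins: int = 51,
    span: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint (a1, a2) histogram normalized to parts-per-million of all points.

    Returns (density_ppm, x_edges, y_edges).  Points outside the grid are
    excluded (and logged), so the in-grid mass can be below 1e6.  Default
    grid: square, symmetric about 0, spanning ±1.1x the largest |a|,
    51x51 bins.
    """
    a1 = np.asarray(a1, float).ravel()
    a2 = np.asarray(a2, float).ravel()
    total = a1.size
    if total == 0:
        raise EmptyDensityError("cannot form a density from zero points")
    if bin_edges is None:
        if span is None:
            span = 1.1 * max(np.abs(a1).max(), np.abs(a2).max(), 1e-12)
        edges = np.linspace(-span, span, n_bins + 1)
        bin_edges = (edges, edges)
    counts, xe, ye = np.histogram2d(a1, a2, bins=bin_edges)
    inside = counts.sum()
    if inside < total:
        logger.warning("%d of %d amplitude points fall outside the density grid",
                       total - int(inside), total)
    return counts / total * 1e6, xe, ye


def radial_statistic(amp: AmplitudeSeries) -> float:
    """Per-worm mean radial distance r_bar = mean_t sqrt(a1^2 + a2^2)."""
    if amp.amplitudes.shape[0] < 1:
        raise StatisticsError("no frames to average")
    if amp.amplitudes.shape[1] < 2:
        raise ParameterError("radial statistic needs at least two modes")
    return float(amp.radii().mean())


def radial_summary_table(amps: list[AmplitudeSeries], group: str):
    """Per-worm radial summary rows: worm id, n frames, r_bar, group label."""
    import pandas as pd

    rows = [
        {"worm_id": a.worm_id, "n_frames": a.amplitudes.shape[0],
         "radial_mean": radial_statistic(a), "group": group}
        for a in amps
    ]
    return pd.DataFrame(rows, columns=["worm_id", "n_frames", "radial_mean", "group"])


def reconstruct_shapes(
    basis: EigenmodeBasis,
    radius: float,
    phases: np.ndarray,
) -> np.ndarray:
    """Unit-length midlines from two-mode postures at fixed mode-plane radius.

    For each phase phi the angle vector is
    ``radius * (cos(phi) m1 + sin(phi) m2) + mean``, integrated to a midline
    of unit body length.  Smaller radius -> smaller peak curvature, which is
    what makes the ring radius interpretable as wave amplitude.
    Returns (len(phases), n_segments + 1, 2).
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    if basis.n_modes < 2:
        raise ParameterError("need at least two modes to reconstruct")
    phases = np.atleast_1d(np.asarray(phases, float))
    m1, m2 = basis.modes[0], basis.modes[1]
    n_seg = len(m1)
    step = 1.0 / n_seg
    out = np.zeros((len(phases), n_seg + 1, 2))
    for k, phi in enumerate(phases):
        theta = radius * (np.cos(phi) * m1 + np.sin(phi) * m2) + basis.mean
        out[k, 1:, 0] = np.cumsum(step * np.cos(theta))
        out[k, 1:, 1] = np.cumsum(step * np.sin(theta))
    return out


def compare_radial_groups(
    radial_a: np.ndarray,
    radial_b: np.ndarray,
    variant: str = "welch",
) -> TestResult:
    """Two-sided two-sample t-test on per-worm mean radial distances.

    Welch (unequal variances) by default; ``variant="student"`` pools.
    """
    return t_test(radial_a, radial_b, paired=False, sided="two", variant=variant,
                  name="radial r_bar group comparison")
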