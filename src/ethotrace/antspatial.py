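"""Arena statistics for ant behavioral assays.

Four readouts of olfaction-driven behavior from tracked positions:

* aversion-zone occupancy — per-ant fraction of its tracked frames spent
  inside the closed 4 cm disc around the repellent pad, averaged over ants;
  optionally restricted to a time window (the early response, e.g. the
  first four minutes, is where avoidance differences are largest);
* antennation events — maximal runs of inter-individual distance below a
  contact threshold lasting at least a minimum duration, nearby runs merged;
* social clustering — per-frame mean nearest-neighbour distance, smoothed
  with a centered rolling average, and the treated-minus-control difference
  series;
* group comparisons — paired/independent t-tests, a random-intercept linear
  mixed model for the clustering time series, and an exact trial-label
  permutation test as the calibrated fallback when the LMM's independence
  assumptions are untenable (tracked positions are autocorrelated).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ArenaGeometry, TrajectoryTable
from .errors import (
    AlignmentError,
    DesignError,
    FitError,
    ParameterError,
    StatisticsError,
)
from .stats import TestResult, t_test

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancySummary",
    "ClusterSeries",
    "AntennationEvents",
    "zone_occupancy",
    "windowed_occupancy",
    "mean_nn_series",
    "rolling_average",
    "difference_series",
    "detect_antennation",
    "fit_clustering_lmm",
    "permutation_slope_test",
    "compare_groups",
]


@dataclass
class OccupancySummary:
    """Per-ant zone occupancy and the trial mean."""

    per_ant: pd.DataFrame          # columns id, frames_present, frames_in_zone, fraction
    trial_mean: float
    window_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        f = self.per_ant["fraction"]
        if ((f < 0) | (f > 1)).any():
            raise StatisticsError("occupancy fractions must lie in [0, 1]")


@dataclass
class ClusterSeries:
    """Per-frame mean nearest-neighbour distance (cm), possibly smoothed."""

    data: pd.DataFrame             # columns time_s, mean_nn_cm, n_ants
    dt: float
    kind: str = "raw"              # raw | rolling | difference
    k: int | None = None
    edge_policy: str | None = None


@dataclass
class AntennationEvents:
    """Detected contact events per dyad and the trial-level count."""

    events: pd.DataFrame           # columns dyad, start_s, end_s, duration_s, min_distance_cm
    count: int
    thresholds: dict = field(default_factory=dict)


# -- occupancy ------------------------------------------------------------


def zone_occupancy(traj: TrajectoryTable, geometry: ArenaGeometry) -> OccupancySummary:
    """Fraction of each ant's tracked time spent inside the aversion zone.

    The denominator is the frames where the ant is present (tracking
    dropouts are excluded from numerator and denominator alike); the trial
    statistic is the mean of the per-ant fractions.  Boundary counts as
    inside (closed disc).
    """
    rows = []
    for ind, sub in traj.data.groupby("id", sort=True):
        n = len(sub)
        if n == 0:
            logger.warning("ant %r has zero frames; excluded", ind)
            continue
        inside = int(geometry.in_zone(sub["x_cm"].to_numpy(), sub["y_cm"].to_numpy()).sum())
        rows.append({"id": ind, "frames_present": n, "frames_in_zone": inside,
                     "fraction": inside / n})
    if not rows:
        raise StatisticsError("no ants with any tracked frames")
    df = pd.DataFrame(rows, columns=["id", "frames_present", "frames_in_zone", "fraction"])
    return OccupancySummary(per_ant=df, trial_mean=float(df["fraction"].mean()))


def windowed_occupancy(
    traj: TrajectoryTable, geometry: ArenaGeometry, window: tuple[float, float]
) -> OccupancySummary:
    """Zone occupancy restricted to frames with t0 <= t < t1."""
    t0, t1 = window
    if not t0 < t1:
        raise ParameterError(f"window must satisfy t0 < t1, got {window}")
    sub = traj.window(t0, t1)
    if len(sub.data) == 0:
        raise StatisticsError(f"window [{t0}, {t1}) contains no frames")
    out = zone_occupancy(sub, geometry)
    out.window_s = (float(t0), float(t1))
    return out


# -- clustering -----------------------------------------------------------


def mean_nn_series(traj: TrajectoryTable) -> ClusterSeries:
    """Per-frame mean nearest-neighbour distance across present ants.

    For each ant present in a frame, the distance to its nearest other
    present ant; the frame value is the mean over ants.  Frames with fewer
    than two ants yield a missing value (NaN), not zero.
    """
    times, values, counts = [], [], []
    any_pair = False
    for t, sub in traj.data.groupby("time_s", sort=True):
        xy = sub[["x_cm", "y_cm"]].to_numpy()
        n = len(xy)
        times.append(t)
        counts.append(n)
        if n < 2:
            values.append(np.nan)
            continue
        any_pair = True
        # explicit pairwise distances so results match a brute-force
        # enumeration bit-for-bit (no BLAS dot-product shortcuts)
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt(diff[:, :, 0] ** 2 + diff[:, :, 1] ** 2)
        np.fill_diagonal(d, np.inf)
        values.append(float(d.min(axis=1).mean()))
    if not any_pair:
        raise StatisticsError("never >= 2 ants present simultaneously")
    df = pd.DataFrame({"time_s": times, "mean_nn_cm": values, "n_ants": counts})
    return ClusterSeries(data=df, dt=traj.dt, kind="raw")


def rolling_average(series: ClusterSeries, k: int = 5,
                    edge_policy: str = "partial") -> ClusterSeries:
    """Centered moving mean over k frames, ignoring missing values.

    ``edge_policy="partial"`` (default) averages whatever part of the window
    exists at the series edges, preserving length; ``"strict"`` emits NaN
    wherever the window is incomplete.
    """
    if k < 1 or k % 2 == 0:
        raise ParameterError(f"k must be odd and >= 1, got {k}")
    if edge_policy not in ("partial", "strict"):
        raise ParameterError(f"edge_policy must be partial|strict, got {edge_policy!r}")
    s = series.data["mean_nn_cm"]
    min_periods = 1 if edge_policy == "partial" else k
    sm = s.rolling(window=k, center=True, min_periods=min_periods).mean()
    df = series.data.copy()
    df["mean_nn_cm"] = sm
    return ClusterSeries(data=df, dt=series.dt, kind="rolling", k=k,
                         edge_policy=edge_policy)


def difference_series(
    treated: ClusterSeries, control: ClusterSeries, k: int = 5
) -> ClusterSeries:
    """Rolling-averaged treated minus control, aligned on timestamps.

    Positive values mean the treated group is more separated (larger
    nearest-neighbour distances).  Series are inner-joined on time; no
    common timestamps is an alignment error.
    """
    a = rolling_average(treated, k).data.set_index("time_s")["mean_nn_cm"]
    b = rolling_average(control, k).data.set_index("time_s")["mean_nn_cm"]
    joined = pd.concat([a.rename("treated"), b.rename("control")], axis=1,
                       join="inner")
    if joined.empty:
        raise AlignmentError("series share no common timestamps")
    df = pd.DataFrame({
        "time_s": joined.index.to_numpy(),
        "mean_nn_cm": (joined["treated"] - joined["control"]).to_numpy(),
        "n_ants": np.nan,
    })
    return ClusterSeries(data=df, dt=treated.dt, kind="difference", k=k)


# -- antennation ----------------------------------------------------------


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    out = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_antennation(
    traj: TrajectoryTable,
    contact_distance_cm: float = 0.5,
    min_duration_s: float = 1.0,
    gap_s: float = 0.5,
) -> AntennationEvents:
    """Count contact events between ant dyads.

    An event is a maximal run of frames with inter-individual distance at or
    below ``contact_distance_cm`` whose dwell time (frames x dt) reaches
    ``min_duration_s``; runs separated by less than ``gap_s`` are merged
    before the duration filter.  This is a distance-and-duration proxy for
    antennation (no heading criterion); thresholds are conventions.
    """
    if contact_distance_cm <= 0 or min_duration_s <= 0 or gap_s < 0:
        raise ParameterError("antennation thresholds must be positive")
    dt = traj.dt
    if dt <= 0:
        raise ParameterError("trajectory has no usable sampling interval")
    piv_x = traj.data.pivot(index="time_s", columns="id", values="x_cm")
    piv_y = traj.data.pivot(index="time_s", columns="id", values="y_cm")
    ids = list(piv_x.columns)
    if len(ids) < 2:
        raise StatisticsError("antennation detection needs >= 2 individuals")
    times = piv_x.index.to_numpy()
    gap_frames = int(np.floor(gap_s / dt + 1e-9))
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        dx = piv_x.iloc[:, i].to_numpy() - piv_x.iloc[:, j].to_numpy()
        dy = piv_y.iloc[:, i].to_numpy() - piv_y.iloc[:, j].to_numpy()
        dist = np.hypot(dx, dy)
        contact = np.where(np.isfinite(dist), dist <= contact_distance_cm, False)
        runs = _runs(contact)
        # merge runs separated by fewer than gap_frames off-contact frames
        merged: list[list[int]] = []
        for s0, s1 in runs:
            if merged and s0 - merged[-1][1] < gap_frames:
                merged[-1][1] = s1
            else:
                merged.append([s0, s1])
        for s0, s1 in merged:
            dwell = (s1 - s0) * dt
            if dwell + 1e-12 >= min_duration_s:
                rows.append({
                    "dyad": f"{ids[i]}-{ids[j]}",
                    "start_s": float(times[s0]),
                    "end_s": float(times[s1 - 1]),
                    "duration_s": float(dwell),
                    "min_distance_cm": float(np.nanmin(dist[s0:s1])),
                })
    df = pd.DataFrame(rows, columns=["dyad", "start_s", "end_s", "duration_s",
                                     "min_distance_cm"])
    return AntennationEvents(
        events=df,
        count=len(df),
        thresholds={"contact_distance_cm": contact_distance_cm,
                    "min_duration_s": min_duration_s, "gap_s": gap_s},
    )


# -- group comparisons ----------------------------------------------------


def _long_format(series_by_trial: dict[str, ClusterSeries],
                 group_of: dict[str, str]) -> pd.DataFrame:
    """Stack per-trial cluster series into a long frame with scaled time."""
    parts = []
    for trial, cs in series_by_trial.items():
        d = cs.data.dropna(subset=["mean_nn_cm"]).copy()
        t = d["time_s"].to_numpy()
        span = t.max() - t.min()
        d["time_scaled"] = (t - t.min()) / (span if span > 0 else 1.0)
        d["trial"] = trial
        d["group"] = group_of[trial]
        parts.append(d)
    return pd.concat(parts, ignore_index=True)


def fit_clustering_lmm(
    series_by_trial: dict[str, ClusterSeries],
    group_of: dict[str, str],
    treated_label: str,
) -> TestResult:
    """Random-intercept linear mixed model for the clustering time series.

    Model: mean NN distance ~ group + time + group x time with a random
    intercept per trial, fitted by maximum likelihood; the reported p-value
    is the Wald test of the group x time interaction (does separation grow
    differently over time in the treated group).  Within-trial residuals are
    treated as independent, which tracked positions violate — prefer
    :func:`permutation_slope_test` when calibration matters.
    """
    import statsmodels.formula.api as smf

    df = _long_format(series_by_trial, group_of)
    df["is_treated"] = (df["group"] == treated_label).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("mean_nn_cm ~ is_treated * time_scaled", df,
                                groups=df["trial"])
            fit = model.fit(reml=False, method="lbfgs")
    except Exception as exc:  # pragma: no cover - depends on optimizer
        raise FitError(
            f"mixed model failed to converge ({exc}); "
            "permutation_slope_test is the fallback"
        ) from exc
    if not fit.converged:
        raise FitError("mixed model did not converge; "
                       "permutation_slope_test is the fallback")
    term = "is_treated:time_scaled"
    coef = float(fit.params[term])
    z = float(fit.tvalues[term])
    p = float(fit.pvalues[term])
    return TestResult(
        name="clustering LMM (group x time interaction)",
        statistic=z,
        df=float(df.shape[0] - len(fit.params)),
        sided="two",
        p_value=p,
        group_summaries=[
            {"group": g, "n": int((df["group"] == g).sum()),
             "mean": float(df.loc[df["group"] == g, "mean_nn_cm"].mean()),
             "sd": float(df.loc[df["group"] == g, "mean_nn_cm"].std(ddof=1))}
            for g in sorted(set(group_of.values()))
        ],
        notes=["Wald z on group x time; within-trial independence assumed"],
        estimates={"interaction": coef, **{k: float(v) for k, v in fit.params.items()}},
    )


def _trial_slopes(series_by_trial: dict[str, ClusterSeries]) -> dict[str, float]:
    slopes = {}
    for trial, cs in series_by_trial.items():
        d = cs.data.dropna(subset=["mean_nn_cm"])
        t = d["time_s"].to_numpy()
        y = d["mean_nn_cm"].to_numpy()
        if len(t) < 2:
            raise StatisticsError(f"trial {trial!r} has <2 usable frames")
        span = t.max() - t.min()
        ts = (t - t.min()) / (span if span > 0 else 1.0)
        slopes[trial] = float(np.polyfit(ts, y, 1)[0])
    return slopes


def permutation_slope_test(
    series_by_trial: dict[str, ClusterSeries],
    group_of: dict[str, str],
    treated_label: str,
    max_exact: int = 20000,
    n_perm: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Exact trial-label permutation test for a group x time effect.

    The statistic is the difference in group means of per-trial OLS slopes
    of the clustering series against scaled time.  All label assignments
    are enumerated when their number is at most ``max_exact``; otherwise
    ``n_perm`` Monte-Carlo draws are used.  Exact under exchangeability of
    trials, regardless of within-trial autocorrelation.
    """
    slopes = _trial_slopes(series_by_trial)
    trials = sorted(slopes)
    labels = np.array([group_of[t] == treated_label for t in trials])
    n_treat = int(labels.sum())
    if n_treat == 0 or n_treat == len(trials):
        raise DesignError("both groups need at least one trial")
    vals = np.array([slopes[t] for t in trials])

    def stat(mask: np.ndarray) -> float:
        return float(vals[mask].mean() - vals[~mask].mean())

    obs = stat(labels)
    from math import comb

    n_assign = comb(len(trials), n_treat)
    if n_assign <= max_exact:
        stats_all = np.array([
            stat(np.isin(np.arange(len(trials)), idx))
            for idx in itertools.combinations(range(len(trials)), n_treat)
        ])
        p = float(np.mean(np.abs(stats_all) >= np.abs(obs) - 1e-12))
        note = f"exact enumeration over {n_assign} assignments"
    else:
        rng = np.random.default_rng(seed)
        stats_all = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(labels)
            stats_all[b] = stat(perm)
        p = float((1 + np.sum(np.abs(stats_all) >= np.abs(obs) - 1e-12)) / (1 + n_perm))
        note = f"Monte-Carlo with {n_perm} permutations"
    return TestResult(
        name="clustering permutation test (slope difference)",
        statistic=obs,
        df=float(len(trials) - 2),
        sided="two",
        p_value=p,
        group_summaries=[
            {"group": treated_label, "n": n_treat,
             "mean": float(vals[labels].mean()),
             "sd": float(vals[labels].std(ddof=1)) if n_treat > 1 else 0.0},
            {"group": "other", "n": len(trials) - n_treat,
             "mean": float(vals[~labels].mean()),
             "sd": float(vals[~labels].std(ddof=1)) if len(trials) - n_treat > 1 else 0.0},
        ],
        notes=[note],
        estimates={"slope_difference": obs},
    )


def compare_groups(design: str, **kwargs) -> TestResult:
    """Dispatch the assay-appropriate group comparison.

    design="paired_t": one-tailed paired t (x=treated, y=control,
    sided="greater"|"less"); design="independent_t": two-tailed independent
    Student t; design="lmm": mixed model on clustering series with the
    permutation fallback on non-convergence; design="permutation": the
    calibrated trial-label permutation test directly.
    """
    if design == "paired_t":
        return t_test(kwargs["x"], kwargs["y"], paired=True,
                      sided=kwargs.get("sided", "greater"),
                      variant="student", name=kwargs.get("name", "paired t-test"))
    if design == "independent_t":
        return t_test(kwargs["x"], kwargs["y"], paired=False, sided="two",
                      variant=kwargs.get("variant", "student"),
                      name=kwargs.get("name", "independent t-test"))
    if design in ("lmm", "permutation"):
        args = {k: kwargs[k] for k in ("series_by_trial", "group_of", "treated_label")}
        if design == "permutation":
            return permutation_slope_test(**args, seed=kwargs.get("seed", 0))
        try:
            return fit_clustering_lmm(**args)
        except FitError as exc:
            if kwargs.get("fallback", "permutation") == "permutation":
                res = permutation_slope_test(**args, seed=kwargs.get("seed", 0))
                res.notes.append(f"LMM fallback used: {exc}")
                return res
            raise
    raise ParameterError(f"unknown design {design!r}")
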