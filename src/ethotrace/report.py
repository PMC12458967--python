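"""Run report: figure panels and a markdown summary from computed outputs.

A pure consumer — it never recomputes or alters numbers.  Given the worm
and/or ant pipeline outputs it renders the standard panels (amplitude
density heatmap in ppm, per-worm radial scatter with mean ± SD, two-mode
shape gallery, occupancy bars, antennation counts, difference-area plot)
and a deterministic markdown table of the numeric results.  Missing whole
assays are marked absent; a run with neither assay is an error.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import ReportError
from .stats import format_p

__all__ = ["render_report"]

_F = "%.9g"


def _fmt(x) -> str:
    return _F % float(x)


def _worm_panels(worm: dict, out_dir: Path, lines: list[str]) -> None:
    required = ["radial_summary", "densities"]
    absent = [k for k in required if k not in worm]
    if absent:
        raise ReportError(f"worm output missing pieces: {absent}")

    lines.append("## Worm posture assay\n")
    for g, (dens, xe, ye) in sorted(worm["densities"].items()):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pcolormesh(xe, ye, dens.T, cmap="viridis")
        ax.set_xlabel("$a_1$")
        ax.set_ylabel("$a_2$")
        ax.set_title(f"{g}: amplitude density (ppm)")
        fig.savefig(out_dir / f"density_{g}.png", dpi=120)
        plt.close(fig)

    rs = worm["radial_summary"]
    fig, ax = plt.subplots(figsize=(4, 4))
    for i, (g, sub) in enumerate(rs.groupby("group", sort=True)):
        x = np.full(len(sub), i) + np.linspace(-0.1, 0.1, len(sub))
        ax.plot(x, sub["radial_mean"], "o", alpha=0.7)
        m, s = sub["radial_mean"].mean(), sub["radial_mean"].std(ddof=1)
        ax.errorbar([i], [m], yerr=[s], fmt="_", color="black", capsize=6,
                    markersize=18)
    ax.set_xticks(range(rs["group"].nunique()))
    ax.set_xticklabels(sorted(rs["group"].unique()))
    ax.set_ylabel(r"$\langle\sqrt{a_1^2+a_2^2}\rangle$ per worm")
    fig.savefig(out_dir / "radial_scatter.png", dpi=120)
    plt.close(fig)

    lines.append("Per-group mean radial distance (mean ± SD over worms):\n")
    for g, sub in rs.groupby("group", sort=True):
        lines.append(
            f"- {g}: {_fmt(sub['radial_mean'].mean())} ± "
            f"{_fmt(sub['radial_mean'].std(ddof=1))} (n={len(sub)})"
        )
    if "radial_test" in worm:
        t = worm["radial_test"]
        lines.append(
            f"\nRadial group comparison: t = {_fmt(t.statistic)}, "
            f"df = {_fmt(t.df)}, p = {format_p(t.p_value)} ({t.sided}-sided)\n"
        )
    if "reconstructions" in worm:
        fig, axes = plt.subplots(1, len(worm["reconstructions"]),
                                 figsize=(4 * len(worm["reconstructions"]), 4))
        axes = np.atleast_1d(axes)
        for ax, (g, shapes) in zip(axes, sorted(worm["reconstructions"].items())):
            for mid in shapes:
                ax.plot(mid[:, 0], mid[:, 1], lw=1)
            ax.set_aspect("equal")
            ax.set_title(f"{g}: two-mode shapes")
        fig.savefig(out_dir / "reconstructions.png", dpi=120)
        plt.close(fig)


def _ant_panels(ant: dict, out_dir: Path, lines: list[str]) -> None:
    lines.append("## Ant arena assay\n")
    if "occupancy" in ant:
        occ = ant["occupancy"]  # dict label -> OccupancySummary
        labels = sorted(occ)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.bar(range(len(labels)), [occ[g].trial_mean for g in labels])
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels)
        ax.set_ylabel("mean zone occupancy fraction")
        fig.savefig(out_dir / "occupancy.png", dpi=120)
        plt.close(fig)
        for g in labels:
            lines.append(f"- {g}: mean zone occupancy {_fmt(occ[g].trial_mean)} "
                         f"({len(occ[g].per_ant)} ants)")
        lines.append("")
    if "antennation" in ant:
        ev = ant["antennation"]  # dict label -> AntennationEvents
        lines.append("Antennation events: " + ", ".join(
            f"{g} = {ev[g].count}" for g in sorted(ev)) + "\n")
    if "difference" in ant:
        d = ant["difference"].data
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.fill_between(d["time_s"], d["mean_nn_cm"], 0, alpha=0.6)
        ax.axhline(0, color="black", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("Δ mean NN distance (cm)")
        fig.savefig(out_dir / "difference_area.png", dpi=120)
        plt.close(fig)
        lines.append(
            f"Difference series (treated − control): mean "
            f"{_fmt(np.nanmean(d['mean_nn_cm']))} cm over "
            f"{len(d)} time points\n"
        )
    for key in ("occupancy_test", "antennation_test", "clustering_test"):
        if key in ant:
            t = ant[key]
            lines.append(f"- {t.name}: statistic = {_fmt(t.statistic)}, "
                         f"p = {format_p(t.p_value)}")
    lines.append("")


def render_report(
    worm: dict | None = None,
    ant: dict | None = None,
    out_dir: str | Path = "report",
) -> Path:
    """Render all available panels; returns the path of the markdown summary.

    Two runs with identical inputs produce byte-identical markdown (figures
    are best-effort deterministic but not byte-compared).
    """
    if worm is None and ant is None:
        raise ReportError("nothing to report: both worm and ant outputs absent")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# ethotrace run report\n"]
    if worm is not None:
        _worm_panels(worm, out_dir, lines)
    else:
        lines.append("## Worm posture assay\n\n(absent)\n")
    if ant is not None:
        _ant_panels(ant, out_dir, lines)
    else:
        lines.append("## Ant arena assay\n\n(absent)\n")
    lines.append("---\np-values are unadjusted per-assay tests; no "
                 "multiple-testing correction is applied.\n")
    md = out_dir / "report.md"
    md.write_text("\n".join(lines))
    return md
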