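"""Shared statistical primitives.

The t statistics are computed from their textbook formulas with the t
distribution supplied by scipy; the test suite cross-checks p-values
against scipy.stats' own ttest routines as an independent reference.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DesignError, StatisticsError

__all__ = ["TestResult", "t_test", "format_p"]


@dataclass
class TestResult:
    """Outcome of a hypothesis test with enough context to report it."""

    name: str
    statistic: float
    df: float
    sided: str                      # "two" | "greater" | "less"
    p_value: float
    group_summaries: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    estimates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatisticsError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "sided": self.sided,
            "p_value": self.p_value,
            "p_display": format_p(self.p_value),
            "group_summaries": self.group_summaries,
            "notes": self.notes,
            "estimates": self.estimates,
        }


def format_p(p: float, sig: int = 3) -> str:
    """p to 3 significant digits, never rendered as 0 (floored with '<')."""
    floor = sys.float_info.min
    if p <= 0:
        return f"< {floor:.3g}"
    return f"{p:.{sig}g}"


def _summary(x: np.ndarray, label: str) -> dict:
    return {
        "group": label,
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
    }


def t_test(
    x,
    y,
    paired: bool = False,
    sided: str = "two",
    variant: str = "student",
    name: str = "t-test",
) -> TestResult:
    """One- or two-sided t-test, paired or independent, Student or Welch.

    ``sided="greater"`` tests mean(x) > mean(y), ``"less"`` the reverse.
    Zero-variance degenerate inputs are flagged in ``notes`` and p is
    resolved by the sign of the observed difference rather than left NaN.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if sided not in ("two", "greater", "less"):
        raise StatisticsError(f"sided must be two|greater|less, got {sided!r}")
    if variant not in ("student", "welch"):
        raise StatisticsError(f"variant must be student|welch, got {variant!r}")
    if len(x) < 2 or len(y) < 2:
        raise StatisticsError("each group needs n >= 2")
    notes: list[str] = []

    if paired:
        if len(x) != len(y):
            raise DesignError(f"paired design needs equal lengths ({len(x)} vs {len(y)})")
        d = x - y
        n = len(d)
        sd = d.std(ddof=1)
        df = float(n - 1)
        if sd == 0:
            notes.append("zero-variance differences; p by sign convention")
            t_stat = np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
        else:
            t_stat = d.mean() / (sd / np.sqrt(n))
        label = "paired"
    else:
        n1, n2 = len(x), len(y)
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        diff = x.mean() - y.mean()
        if variant == "student":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = float(n1 + n2 - 2)
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            if se > 0:
                df = (v1 / n1 + v2 / n2) ** 2 / (
                    (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                )
            else:
                df = float(n1 + n2 - 2)
        if se == 0:
            notes.append("zero pooled variance; p by sign convention")
            t_stat = np.inf * np.sign(diff) if diff != 0 else 0.0
        else:
            t_stat = diff / se
        label = variant

    if np.isinf(t_stat):
        sf = 0.0 if t_stat > 0 else 1.0
    else:
        sf = float(sps.t.sf(t_stat, df))
    if sided == "two":
        p = 2 * min(sf, 1 - sf)
        if np.isinf(t_stat):
            p = 0.0
        elif t_stat == 0 and notes:
            p = 1.0
    elif sided == "greater":
        p = sf
    else:
        p = 1 - sf
    p = float(min(max(p, 0.0), 1.0))

    stat_out = float(t_stat) if np.isfinite(t_stat) else float(np.sign(t_stat) * np.inf)
    return TestResult(
        name=f"{name} ({label}, {sided}-sided)" if name == "t-test" else name,
        statistic=stat_out,
        df=float(df),
        sided=sided,
        p_value=p,
        group_summaries=[_summary(x, "x"), _summary(y, "y")],
        notes=notes,
    )
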