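"""Statistics across plaque groups along the development sequence.

Groups are ordered control -> diffuse -> compact -> classic_cored ->
core.  Adjacent pairs are compared with the classical pooled-variance
two-sample Student's t-test (no multiple-testing correction), p-values
annotated with significance stars (< 0.05 *, < 0.01 **, < 0.001 ***).
The correlation between the protein and beta-sheet ratios is quantified
by the Pearson coefficient R; distributions are summarized as boxplot
five-number summaries with the 1.5 IQR outlier rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra_core import InputError

__all__ = [
    "GROUP_ORDER",
    "PairTest",
    "BoxplotSummary",
    "StatsReport",
    "stars_for",
    "ttest_ladder",
    "pearson_r",
    "summarize_boxplot",
    "build_stats_report",
    "leave_one_out_medians",
]

GROUP_ORDER = ("control", "diffuse", "compact", "classic_cored", "core")
STAR_THRESHOLDS = (0.05, 0.01, 0.001)


def stars_for(p: float, thresholds=STAR_THRESHOLDS) -> str:
    if not np.isfinite(p):
        return ""
    return "*" * sum(p < t for t in thresholds)


@dataclass
class PairTest:
    group_a: str
    group_b: str
    t: float
    p: float
    stars: str
    flag: str = ""


def ttest_ladder(
    groups: dict[str, np.ndarray] | list[tuple[str, np.ndarray]],
    all_pairs: bool = False,
    welch: bool = False,
) -> list[PairTest]:
    """Two-sided Student's t-tests between groups in the given order.

    By default only adjacent pairs of the ordered sequence are tested;
    ``all_pairs`` tests every pair.  ``welch`` switches to the unequal-
    variance variant.  Degenerate comparisons (a group with n < 2, or
    zero pooled variance) report NaN with a flag instead of failing.
    """
    items = list(groups.items()) if isinstance(groups, dict) else list(groups)
    if len(items) < 2:
        raise InputError("need at least two groups")
    pairs = (
        [(i, j) for i in range(len(items)) for j in range(i + 1, len(items))]
        if all_pairs
        else [(i, i + 1) for i in range(len(items) - 1)]
    )
    results = []
    for i, j in pairs:
        name_a, a = items[i]
        name_b, b = items[j]
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        flag = ""
        if a.size < 2 or b.size < 2:
            t = p = float("nan")
            flag = "degenerate_n"
        elif np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                t, p = 0.0, 1.0
            else:
                t = p = float("nan")
                flag = "zero_variance"
        else:
            t, p = sps.ttest_ind(a, b, equal_var=not welch)
            t, p = float(t), float(p)
        results.append(PairTest(name_a, name_b, t, p, stars_for(p), flag))
    return results


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation in [-1, 1]; NaN for degenerate input
    (n < 3 or zero variance in either argument)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3 or np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)
    n: int = 0


def summarize_boxplot(values: np.ndarray) -> BoxplotSummary:
    """Five-number summary with linear-interpolation quartiles; whiskers
    extend to the extreme values within 1.5 IQR of the quartiles and
    points beyond are reported as outliers."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise InputError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=[float(o) for o in np.sort(outliers)],
        n=int(v.size),
    )


@dataclass
class StatsReport:
    """Per-metric group distributions, ladder tests, correlation and
    boxplot summaries for one cohort."""

    metrics: list[str]
    groups: dict[str, dict[str, list[float]]]  # metric -> group -> values
    ladder: dict[str, list[PairTest]]
    pearson: float
    boxplots: dict[str, dict[str, BoxplotSummary]]

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {
                "metrics": self.metrics,
                "groups": self.groups,
                "ladder": {
                    m: [asdict(t) for t in tests] for m, tests in self.ladder.items()
                },
                "pearson_r": self.pearson,
                "boxplots": {
                    m: {g: asdict(b) for g, b in gs.items()}
                    for m, gs in self.boxplots.items()
                },
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as f:
                f.write(payload)
        return payload


def build_stats_report(
    df: pd.DataFrame,
    metrics: tuple[str, ...] = ("protein_ratio", "beta_ratio", "d2_height_diff"),
    group_col: str = "group",
    all_pairs: bool = False,
) -> StatsReport:
    """Cohort statistics from a tidy per-spectrum metrics table.

    ``df`` holds one row per analyzed spectrum with a ``group`` column
    (control / diffuse / compact / classic_cored / core) and one column
    per metric.  The Pearson correlation between the protein and
    beta-sheet ratios uses only plaque and core spectra, not controls.
    """
    present = [g for g in GROUP_ORDER if g in set(df[group_col])]
    groups_out: dict[str, dict[str, list[float]]] = {}
    ladder: dict[str, list[PairTest]] = {}
    boxplots: dict[str, dict[str, BoxplotSummary]] = {}
    for metric in metrics:
        per_group = {
            g: df.loc[df[group_col] == g, metric].dropna().to_numpy()
            for g in present
        }
        groups_out[metric] = {g: [float(x) for x in v] for g, v in per_group.items()}
        ladder[metric] = ttest_ladder(
            [(g, per_group[g]) for g in present], all_pairs=all_pairs
        )
        boxplots[metric] = {
            g: summarize_boxplot(v) for g, v in per_group.items() if v.size
        }
    plaque_like = df[df[group_col] != "control"]
    r = pearson_r(
        plaque_like["protein_ratio"].to_numpy(),
        plaque_like["beta_ratio"].to_numpy(),
    )
    return StatsReport(
        metrics=list(metrics),
        groups=groups_out,
        ladder=ladder,
        pearson=r,
        boxplots=boxplots,
    )


def leave_one_out_medians(
    df: pd.DataFrame,
    case_col: str = "case",
    group_col: str = "group",
    metric: str = "beta_ratio",
) -> pd.DataFrame:
    """Case-influence summary: per-group median shift when each case is
    left out in turn."""
    rows = []
    for case in sorted(df[case_col].unique()):
        rest = df[df[case_col] != case]
        for g in sorted(df[group_col].unique()):
            full_med = df.loc[df[group_col] == g, metric].median()
            loo_med = rest.loc[rest[group_col] == g, metric].median()
            rows.append(
                {
                    "left_out": case,
                    "group": g,
                    "median": full_med,
                    "loo_median": loo_med,
                    "shift": loo_med - full_med,
                }
            )
    return pd.DataFrame(rows)
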