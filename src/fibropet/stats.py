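"""Longitudinal biomarkers and group statistics.

Assembles per-animal time series of CT and PET metrics, computes the
progression score (change in mean lung density between day 9 and day 23),
group fold changes, early-marker predictive correlations, and nonparametric
group comparisons (Mann-Whitney for two groups, Kruskal-Wallis for more),
and writes the study report tables/plots.

Fold changes on mean lung density are computed on the HU + 1000 scale (a
physical-density proxy proportional to g/mL for water-like tissue), since a
ratio of signed HU values is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Imaging sessions are paired across consecutive days (FDG the day before
#: CT/FMISO); analyses merge them onto the nominal session day.
_NOMINAL = {0: 0, 8: 9, 9: 9, 15: 16, 16: 16, 22: 23, 23: 23}


def nominal_day(day: int) -> int:
    """Map an acquisition day onto its nominal session day (8->9, 15->16, 22->23)."""
    return _NOMINAL.get(int(day), int(day))


@dataclass
class AnimalTimeline:
    """Ordered per-animal records of (day, metric) pairs for one modality metric."""

    animal_id: str
    group: str
    days: Sequence[int]
    mld_hu: Sequence[float]

    def __post_init__(self):
        if list(self.days) != sorted(set(self.days)):
            raise ValueError(f"{self.animal_id}: days must be strictly increasing")

    def mld_at(self, day: int, tolerance: int = 1) -> float:
        """MLD at a study day, accepting the nearest session within +-tolerance."""
        days = np.asarray(self.days)
        diffs = np.abs(days - day)
        i = int(np.argmin(diffs))
        if diffs[i] > tolerance:
            raise KeyError(f"animal {self.animal_id}: no imaging day within "
                           f"+-{tolerance} of day {day} (have {list(self.days)})")
        return float(self.mld_hu[i])


@dataclass(frozen=True)
class ProgressionScore:
    """Signed change in mean lung density; positive means progression."""

    animal_id: str
    delta_ct_hu: float
    start_day: int
    end_day: int


def delta_ct(timeline: AnimalTimeline, start_day: int = 9, end_day: int = 23) -> ProgressionScore:
    """Progression score: MLD(end) - MLD(start) in HU."""
    return ProgressionScore(
        animal_id=timeline.animal_id,
        delta_ct_hu=timeline.mld_at(end_day) - timeline.mld_at(start_day),
        start_day=start_day, end_day=end_day,
    )


def group_fold_change(values_a: Sequence[float], values_b: Sequence[float],
                      scale: str = "linear") -> float:
    """Ratio of group means, mean(A) / mean(B).

    ``scale="HU+1000"`` shifts both groups by +1000 before averaging and is
    mandatory for mean-lung-density fold changes (HU is a signed scale with
    an arbitrary zero at water).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold change needs non-empty groups")
    if scale == "HU+1000":
        a, b = a + 1000.0, b + 1000.0
    elif scale != "linear":
        raise ValueError(f"scale must be 'linear' or 'HU+1000', got {scale!r}")
    denom = float(b.mean())
    if denom == 0:
        raise ValueError("fold change undefined: denominator group mean is zero")
    return float(a.mean()) / denom


def predictive_correlation(early: Sequence[float], outcome: Sequence[float],
                           method: str = "pearson") -> Tuple[float, float, int]:
    """Correlate an early per-animal marker with a later outcome.

    Pairs with missing values are dropped; returns (r, two-sided p, n).
    """
    x = np.asarray(early, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape:
        raise ValueError("early and outcome vectors must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate correlation: zero variance in one variable")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), n


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(*samples: Sequence[float]) -> Tuple[float, str]:
    """Nonparametric group comparison.

    Two groups: two-sided Mann-Whitney U (exact for small tie-free samples).
    More than two: Kruskal-Wallis.  Returns (p, stars).
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all observations tied: no evidence against H0
        return 1.0, ""
    if len(arrays) == 2:
        a, b = arrays
        ties = np.unique(pooled).size < pooled.size
        method = "auto" if ties else ("exact" if max(a.size, b.size) <= 25 else "auto")
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    else:
        p = float(sps.kruskal(*arrays).pvalue)
    p = min(p, 1.0)
    return p, significance_stars(p)


# ---------------------------------------------------------------------------
# Study-level assembly


def timelines_from_metrics(metrics: pd.DataFrame) -> Dict[str, AnimalTimeline]:
    """Per-animal MLD timelines from the tidy per-scan metrics table."""
    ct = metrics[metrics["tracer"] == "CT"]
    out = {}
    for (animal, group), sub in ct.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("nominal_day")
        out[animal] = AnimalTimeline(animal_id=animal, group=group,
                                     days=sub["nominal_day"].tolist(),
                                     mld_hu=sub["mld_hu"].tolist())
    return out


def progression_table(metrics: pd.DataFrame, start_day: int = 9, end_day: int = 23) -> pd.DataFrame:
    """Per-animal progression scores with group labels."""
    rows = []
    for animal, tl in timelines_from_metrics(metrics).items():
        score = delta_ct(tl, start_day, end_day)
        rows.append(dict(animal_id=animal, group=tl.group, delta_ct_hu=score.delta_ct_hu))
    return pd.DataFrame(rows).sort_values("animal_id").reset_index(drop=True)


def _metric_columns(df: pd.DataFrame) -> List[str]:
    skip = {"animal_id", "group", "day", "nominal_day", "tracer"}
    return [c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])]


def group_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SEM of every metric per (group, nominal day, tracer)."""
    cols = _metric_columns(metrics)
    recs = []
    for (group, day, tracer), sub in metrics.groupby(["group", "nominal_day", "tracer"], sort=True):
        for col in cols:
            vals = sub[col].dropna()
            if len(vals) == 0:
                continue
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            recs.append(dict(group=group, nominal_day=day, tracer=tracer, metric=col,
                             mean=float(vals.mean()), sem=sem, n=int(len(vals))))
    return pd.DataFrame(recs)


def study_fold_changes(metrics: pd.DataFrame, day: int = 23) -> pd.DataFrame:
    """The study's headline fold changes at the established-fibrosis session.

    Disease effect: BLM-vehicle over NaCl for (MLD+1000), lung FDG %ID/g and
    lung FMISO %ID/g.  Therapy effect: vehicle over each treated arm for the
    same three quantities (a fold *decrease*).
    """
    def vals(group, tracer, col):
        sub = metrics[(metrics["group"] == group) & (metrics["tracer"] == tracer)
                      & (metrics["nominal_day"] == day)]
        return sub[col].dropna().to_numpy()

    quantities = [("MLD", "CT", "mld_hu", "HU+1000"),
                  ("FDG %ID/g", "FDG", "pid_lung", "linear"),
                  ("FMISO %ID/g", "FMISO", "pid_lung", "linear")]
    rows = []
    for label, tracer, col, scale in quantities:
        blm = vals("BLM", tracer, col)
        nacl = vals("NaCl", tracer, col)
        if blm.size and nacl.size:
            rows.append(dict(contrast="BLM / NaCl", quantity=label,
                             fold=group_fold_change(blm, nacl, scale), scale=scale))
        for arm in ("BLM+pirfenidone", "BLM+nintedanib"):
            tr = vals(arm, tracer, col)
            if blm.size and tr.size:
                rows.append(dict(contrast=f"BLM / {arm}", quantity=label,
                                 fold=group_fold_change(blm, tr, scale), scale=scale))
    return pd.DataFrame(rows)


def early_marker_correlations(metrics: pd.DataFrame, group: str = "BLM",
                              early_day: int = 9) -> pd.DataFrame:
    """Correlate day-9 markers (MLD, FDG, FMISO uptake) with progression."""
    prog = progression_table(metrics).set_index("animal_id")
    prog = prog[prog["group"] == group]
    rows = []
    markers = [("MLD", "CT", "mld_hu"), ("FDG %ID/g", "FDG", "pid_lung"),
               ("FMISO %ID/g", "FMISO", "pid_lung")]
    for label, tracer, col in markers:
        sub = metrics[(metrics["group"] == group) & (metrics["tracer"] == tracer)
                      & (metrics["nominal_day"] == early_day)]
        sub = sub.set_index("animal_id")
        common = [a for a in prog.index if a in sub.index]
        if len(common) < 3:
            continue
        r, p, n = predictive_correlation(sub.loc[common, col].to_numpy(),
                                         prog.loc[common, "delta_ct_hu"].to_numpy())
        rows.append(dict(marker=f"D{early_day} {label}", outcome="delta_ct_D9_D23",
                         group=group, r=r, p=p, n=n, stars=significance_stars(p)))
    return pd.DataFrame(rows)


def build_report(metrics: pd.DataFrame, out_dir, make_plots: bool = True) -> Dict[str, object]:
    """Emit the study report bundle.

    Writes per-scan metrics, group summaries (mean +- SEM), the fold-change
    table and early-marker correlation table as CSV, plus time-course and
    correlation plots.  Missing scans are flagged (count of absent
    group x day x tracer cells) but do not abort the run; the report is
    deterministic for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: List[str] = []

    metrics = metrics.sort_values(["group", "animal_id", "nominal_day", "tracer"]).reset_index(drop=True)
    expected_days = sorted(metrics["nominal_day"].unique())
    for group, sub in metrics.groupby("group"):
        for day in expected_days:
            for tracer in ("CT", "FDG", "FMISO"):
                if not ((sub["nominal_day"] == day) & (sub["tracer"] == tracer)).any():
                    warnings.append(f"missing cell: {group} day {day} {tracer}")

    summary = group_summary(metrics)
    folds = study_fold_changes(metrics)
    try:
        corr = early_marker_correlations(metrics)
    except (ValueError, KeyError) as e:
        warnings.append(f"correlation table unavailable: {e}")
        corr = pd.DataFrame()

    metrics.to_csv(out / "per_scan_metrics.csv", index=False)
    summary.to_csv(out / "group_summary.csv", index=False)
    folds.to_csv(out / "fold_changes.csv", index=False)
    corr.to_csv(out / "correlations.csv", index=False)

    if make_plots:
        _plot_time_courses(summary, out)
        if not corr.empty:
            _plot_correlations(metrics, out)

    return {"summary": summary, "fold_changes": folds, "correlations": corr,
            "warnings": warnings, "n_warnings": len(warnings)}


def _plot_time_courses(summary: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("CT", "mld_hu", "Mean lung density (HU)"),
              ("FDG", "pid_lung", "FDG lung uptake (%ID/g)"),
              ("FMISO", "pid_lung", "FMISO lung uptake (%ID/g)")]
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    for ax, (tracer, metric, label) in zip(axes, panels):
        sub = summary[(summary["tracer"] == tracer) & (summary["metric"] == metric)]
        for group, g in sub.groupby("group"):
            g = g.sort_values("nominal_day")
            ax.errorbar(g["nominal_day"], g["mean"], yerr=g["sem"], marker="o",
                        capsize=3, label=group)
        ax.set_xlabel("study day")
        ax.set_ylabel(label)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "time_courses.png", dpi=120)
    plt.close(fig)


def _plot_correlations(metrics: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prog = progression_table(metrics).set_index("animal_id")
    prog = prog[prog["group"] == "BLM"]
    markers = [("CT", "mld_hu", "D9 MLD (HU)"), ("FDG", "pid_lung", "D9 FDG (%ID/g)"),
               ("FMISO", "pid_lung", "D9 FMISO (%ID/g)")]
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    for ax, (tracer, col, label) in zip(axes, markers):
        sub = metrics[(metrics["group"] == "BLM") & (metrics["tracer"] == tracer)
                      & (metrics["nominal_day"] == 9)].set_index("animal_id")
        common = [a for a in prog.index if a in sub.index]
        x = sub.loc[common, col]
        y = prog.loc[common, "delta_ct_hu"]
        ax.scatter(x, y, s=18)
        ax.set_xlabel(label)
        ax.set_ylabel("deltaCT D9-D23 (HU)")
    fig.tight_layout()
    fig.savefig(out / "early_marker_correlations.png", dpi=120)
    plt.close(fig)
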