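"""Aggregate match results into detection-performance statistics.

Rates follow the usual point-detection conventions: the true positive rate is
TP / (TP + FN) (fraction of ground-truth objects found), the false negative
rate is its complement, and the false discovery rate is FP / (FP + TP)
(fraction of clicks that hit nothing). True negative rates are not defined
for point detection — the non-target area is not a countable set.

FDR is undefined for blank trials (no selections) and such trials are
excluded from FDR averages rather than treated as 0/0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Selection
from .matching import MatchResult

__all__ = [
    "TrialMetrics",
    "GridDistribution",
    "score_trial",
    "score_matches",
    "aggregate_rates",
    "per_trial_rates",
    "distance_from_center",
    "grid_cell_of",
    "grid_distribution",
    "grid_cell_side",
    "targets_found_relationship",
    "timing_summaries",
]


@dataclass
class TrialMetrics:
    """TP/FP/FN counts and rates for one participant-trial (or a pool)."""

    trial_id: str
    participant_id: str
    tp: int
    fp: int
    fn: int

    @property
    def n_targets(self) -> int:
        return self.tp + self.fn

    @property
    def n_selections(self) -> int:
        return self.tp + self.fp

    @property
    def blank(self) -> bool:
        return self.n_selections == 0

    @property
    def tp_rate(self) -> float:
        return self.tp / self.n_targets if self.n_targets else float("nan")

    @property
    def fn_rate(self) -> float:
        return 1.0 - self.tp_rate

    @property
    def fdr(self) -> float | None:
        """FP / (FP + TP); None when the trial has no selections."""
        if self.n_selections == 0:
            return None
        return self.fp / self.n_selections


def score_trial(match: MatchResult) -> TrialMetrics:
    return TrialMetrics(trial_id=match.trial_id,
                        participant_id=match.participant_id,
                        tp=match.tp, fp=match.fp, fn=match.fn)


def score_matches(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """One row of counts and rates per participant-trial."""
    rows = []
    for m in matches:
        tm = score_trial(m)
        rows.append({
            "participant_id": tm.participant_id, "trial_id": tm.trial_id,
            "tp": tm.tp, "fp": tm.fp, "fn": tm.fn,
            "n_targets": tm.n_targets, "n_selections": tm.n_selections,
            "tp_rate": tm.tp_rate, "fn_rate": tm.fn_rate,
            "fdr": tm.fdr if tm.fdr is not None else np.nan,
            "blank": tm.blank,
        })
    return pd.DataFrame(rows)


def aggregate_rates(metrics: pd.DataFrame, level: str = "pooled") -> pd.DataFrame:
    """Pool counts and recompute rates at the requested level.

    ``pooled``: one row from summed counts over everything (count-weighted,
    so pooled tp_rate = sum TP / sum (TP+FN), not a mean of rates).
    ``trial`` / ``participant``: summed counts per trial / participant, plus
    the unweighted mean of per-record rates (``mean_tp_rate`` etc.), which is
    what trial-level regressions consume.
    """
    if metrics.empty:
        raise ValueError("no scored records to aggregate")

    def _summarize(grp: pd.DataFrame) -> dict:
        tp, fp, fn = int(grp["tp"].sum()), int(grp["fp"].sum()), int(grp["fn"].sum())
        out = {
            "tp": tp, "fp": fp, "fn": fn,
            "tp_rate": tp / (tp + fn) if tp + fn else np.nan,
            "fdr": fp / (fp + tp) if fp + tp else np.nan,
            "mean_tp_rate": grp["tp_rate"].mean(),
            "mean_fn_rate": grp["fn_rate"].mean(),
            "mean_fdr": grp["fdr"].mean(),  # blank trials are NaN -> excluded
            "n_targets": grp["n_targets"].iloc[0] if grp["n_targets"].nunique() == 1
                         else grp["n_targets"].mean(),
            "n_records": len(grp),
        }
        out["fn_rate"] = 1.0 - out["tp_rate"]
        return out

    if level == "pooled":
        return pd.DataFrame([_summarize(metrics)], index=["pooled"])
    if level in ("trial", "participant"):
        key = f"{level}_id"
        rows = {k: _summarize(g) for k, g in metrics.groupby(key)}
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis(key)
    raise ValueError(f"unknown aggregation level: {level!r}")


def per_trial_rates(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-trial averages across participants (rows = trials)."""
    return aggregate_rates(metrics, level="trial")


def distance_from_center(x, y, image_side: float = 800.0):
    """Euclidean distance from the image center (side/2, side/2) in pixels."""
    half = image_side / 2.0
    return np.hypot(np.asarray(x) - half, np.asarray(y) - half)


def grid_cell_of(x: float, y: float, image_side: float = 800.0) -> int:
    """3x3 grid cell (1..9) of a point; cell 1 is the bottom-left corner.

    Cells are numbered row-major from the bottom-left, so cell 5 is the
    center and cell 8 the top-middle. Points on the far edge fold into the
    last row/column.
    """
    if not (0 <= x <= image_side and 0 <= y <= image_side):
        raise ValueError(f"point ({x}, {y}) outside image of side {image_side}")
    col = min(2, int(3 * x / image_side))
    row = min(2, int(3 * y / image_side))
    return 3 * row + col + 1


def grid_cell_side(image_side: float = 800.0) -> int:
    """Displayed grid-cell side length: floor(side / 3) (266 for 800 px)."""
    return int(image_side // 3)


def grid_distribution(points, image_side: float = 800.0) -> "GridDistribution":
    counts = [0] * 9
    for x, y in points:
        counts[grid_cell_of(x, y, image_side) - 1] += 1
    return GridDistribution(counts=counts)


@dataclass
class GridDistribution:
    """Counts of points per 3x3 grid cell, cell 1 = bottom-left."""

    counts: list[int]

    @property
    def total(self) -> int:
        return sum(self.counts)

    def fractions(self) -> list[float]:
        n = self.total
        return [c / n if n else float("nan") for c in self.counts]


def targets_found_relationship(trial_rates: pd.DataFrame) -> dict:
    """Correlations of per-trial miss and false-discovery rates with target count.

    Expects per-trial averaged metrics (see ``per_trial_rates``). Returns
    Pearson r and p for (fn_rate, n_targets) and (fdr, n_targets), plus the
    per-trial scatter table of targets present vs mean targets found.
    """
    if len(trial_rates) < 3:
        raise ValueError("need at least 3 trials for a correlation")
    n = trial_rates["n_targets"].astype(float)
    out: dict = {}
    for name, col in (("fn_rate", "mean_fn_rate"), ("fdr", "mean_fdr")):
        y = trial_rates[col].astype(float)
        ok = ~(n.isna() | y.isna())
        if y[ok].nunique() <= 1 or n[ok].nunique() <= 1:
            out[name] = {"r": float("nan"), "p": float("nan"),
                         "n": int(ok.sum()), "degenerate": True}
        else:
            r, p = stats.pearsonr(n[ok], y[ok])
            out[name] = {"r": float(r), "p": float(p),
                         "n": int(ok.sum()), "degenerate": False}
    found = trial_rates["tp_rate"] * n  # pooled per-trial rate x target count
    out["scatter"] = pd.DataFrame({
        "n_targets": n, "mean_targets_found": found,
    }).reset_index()
    return out


def timing_summaries(selections: Sequence[Selection]) -> pd.DataFrame:
    """Median/mean first-click time, inter-click interval, completion time."""
    first, intervals, completion = [], [], []
    by_cell: dict[tuple[str, str], list[float]] = {}
    for s in selections:
        by_cell.setdefault((s.participant_id, s.trial_id), []).append(s.t)
    for ts in by_cell.values():
        ts = sorted(ts)
        first.append(ts[0])
        completion.append(ts[-1])
        intervals.extend(b - a for a, b in zip(ts, ts[1:]))
    rows = []
    for name, vals in (("first_selection", first),
                       ("inter_selection", intervals),
                       ("completion", completion)):
        if vals:
            rows.append({"measure": name, "median": float(np.median(vals)),
                         "mean": float(np.mean(vals)), "n": len(vals)})
        else:
            rows.append({"measure": name, "median": np.nan,
                         "mean": np.nan, "n": 0})
    return pd.DataFrame(rows)
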