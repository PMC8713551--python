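"""What drives the order in which found targets are clicked.

The analysis correlates the within-trial click order of true-positive
selections with the within-trial size rank of the selected instance
(1 = largest). Because trials have different numbers of targets, even
arbitrary within-trial ranks correlate positively with click order — small
trials produce both small orders and small ranks — so an arbitrary-rank
baseline (ranks of i.i.d. random draws) is computed and the two dependent,
overlapping correlations are compared with Williams' t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationComparison",
    "build_order_dataset",
    "rank_within_trial",
    "arbitrary_ranks",
    "order_feature_correlation",
    "arbitrary_rank_baseline",
    "compare_size_vs_arbitrary",
    "williams_test",
    "color_match_by_order",
]


@dataclass
class CorrelationComparison:
    """Williams' test for two dependent correlations sharing a variable."""

    r12: float     # e.g. corr(order, size rank)
    r13: float     # e.g. corr(order, arbitrary rank)
    r23: float     # corr(size rank, arbitrary rank)
    n: int
    t: float
    df: int
    p: float


def rank_within_trial(values, descending: bool = True) -> np.ndarray:
    """Average ranks of values; with ``descending`` rank 1 is the largest."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty set")
    return stats.rankdata(-values if descending else values, method="average")


def arbitrary_ranks(trial_instances: dict[str, list[str]],
                    rng: np.random.Generator) -> dict[str, float]:
    """Rank an i.i.d. uniform draw per instance, descending within trial.

    ``trial_instances`` maps trial_id -> instance ids. Returns instance_id ->
    arbitrary rank (a uniform random permutation of 1..n per trial).
    """
    out: dict[str, float] = {}
    for tid in sorted(trial_instances):
        ids = trial_instances[tid]
        draws = rng.random(len(ids))
        ranks = rank_within_trial(draws, descending=True)
        out.update(zip(ids, ranks))
    return out


def build_order_dataset(scored: pd.DataFrame, max_order: int = 10) -> pd.DataFrame:
    """True-positive click-order records for the order analysis.

    Keeps TP rows only, from (participant, trial) cells with at least two TP
    selections; re-numbers the order over TP clicks (an interleaved false
    positive does not advance the order) and truncates at ``max_order``.
    ``size_rank`` is the within-trial rank of the selected instance's area
    over *all* instances of the trial (1 = largest, ties averaged); the raw
    click index is kept as ``raw_order`` for sensitivity checks.
    """
    size_rank: dict[str, float] = {}
    for _, grp in scored.dropna(subset=["instance_id"]).drop_duplicates(
            "instance_id").groupby("trial_id"):
        ranks = rank_within_trial(grp["area"].to_numpy())
        size_rank.update(zip(grp["instance_id"], ranks))

    tp = scored[scored["role"] == "TP"].copy()
    records = []
    for (pid, tid), grp in tp.groupby(["participant_id", "trial_id"]):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("order_index")
        for k, (_, row) in enumerate(grp.iterrows(), start=1):
            if k > max_order:
                break
            records.append({
                "participant_id": pid, "trial_id": tid,
                "instance_id": row["instance_id"],
                "order": k, "raw_order": row["order_index"],
                "size_rank": size_rank[row["instance_id"]],
                "area": row["area"], "t": row["t"],
                "clarity": row["clarity"], "color_match": row["color_match"],
                "n_targets": row["n_targets"],
            })
    return pd.DataFrame(records, columns=[
        "participant_id", "trial_id", "instance_id", "order", "raw_order",
        "size_rank", "area", "t", "clarity", "color_match", "n_targets"])


def _with_arbitrary(records: pd.DataFrame, scored: pd.DataFrame,
                    rng: np.random.Generator) -> pd.Series:
    """Arbitrary rank per record, drawn over all instances of each trial."""
    trial_instances = {
        str(tid): sorted(grp["instance_id"].dropna().unique())
        for tid, grp in scored.groupby("trial_id")
    }
    ranks = arbitrary_ranks(trial_instances, rng)
    return records["instance_id"].map(ranks)


def order_feature_correlation(records: pd.DataFrame,
                              feature: str) -> tuple[float, float]:
    """Spearman correlation of click order with a per-record feature."""
    if len(records) < 4:
        raise ValueError("need at least 4 order records")
    x = records["order"].to_numpy(dtype=float)
    y = records[feature].to_numpy(dtype=float)
    if np.nanstd(y) == 0 or np.nanstd(x) == 0:
        raise ValueError(f"feature {feature!r} (or order) is constant; "
                         "correlation undefined")
    res = stats.spearmanr(x, y, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


def arbitrary_rank_baseline(records: pd.DataFrame, scored: pd.DataFrame,
                            rng: np.random.Generator,
                            n_reps: int = 100) -> dict:
    """Mean +/- sd of the order-vs-arbitrary-rank correlation over replicates.

    The study's single-draw baseline is the ``n_reps=1`` case; averaging over
    seeds separates the composition-induced baseline from draw noise.
    """
    rs = []
    for _ in range(n_reps):
        arb = _with_arbitrary(records, scored, rng)
        r, _ = stats.spearmanr(records["order"], arb)
        rs.append(float(r))
    return {"mean": float(np.mean(rs)), "sd": float(np.std(rs, ddof=1)) if
            n_reps > 1 else 0.0, "n_reps": n_reps, "values": rs}


def williams_test(r12: float, r13: float, r23: float,
                  n: int) -> CorrelationComparison:
    """Williams (1959) t for comparing dependent overlapping correlations.

    Variable 1 is shared (here: click order); r12 and r13 are its
    correlations with the two rank variables, r23 the correlation between
    the rank variables. df = n - 3; two-sided p.
    """
    if n <= 3:
        raise ValueError("Williams' test needs n > 3")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} = {r} outside (-1, 1)")
    K = 1.0 - r12 ** 2 - r13 ** 2 - r23 ** 2 + 2.0 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * K * (n - 1.0) / (n - 3.0) + rbar ** 2 * (1.0 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1.0) * (1.0 + r23) / denom)
    df = n - 3
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationComparison(r12=r12, r13=r13, r23=r23, n=n, t=t,
                                 df=df, p=p)


def compare_size_vs_arbitrary(records: pd.DataFrame, scored: pd.DataFrame,
                              rng: np.random.Generator) -> CorrelationComparison:
    """Single-draw comparison: order-size vs order-arbitrary correlation."""
    arb = _with_arbitrary(records, scored, rng)
    r12, _ = stats.spearmanr(records["order"], records["size_rank"])
    r13, _ = stats.spearmanr(records["order"], arb)
    r23, _ = stats.spearmanr(records["size_rank"], arb)
    return williams_test(float(r12), float(r13), float(r23), len(records))


def color_match_by_order(records: pd.DataFrame) -> dict:
    """Per-order color-match fractions, RT splits, and order-match correlation."""
    rec = records.dropna(subset=["color_match"])
    if rec.empty:
        raise ValueError("no color-match information in the order records")
    per_order = []
    for k, grp in rec.groupby("order"):
        matched = grp[grp["color_match"] == 1]
        unmatched = grp[grp["color_match"] == 0]
        per_order.append({
            "order": int(k), "n": len(grp),
            "frac_color_match": float(grp["color_match"].mean()),
            "mean_rt_match": float(matched["t"].mean()) if len(matched) else np.nan,
            "mean_rt_nonmatch": (float(unmatched["t"].mean())
                                 if len(unmatched) else np.nan),
        })
    if rec["color_match"].nunique() > 1:
        r, p = stats.spearmanr(rec["order"], rec["color_match"])
    else:
        r, p = float("nan"), float("nan")
    return {"per_order": pd.DataFrame(per_order),
            "order_match_spearman_r": float(r),
            "order_match_spearman_p": float(p)}
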