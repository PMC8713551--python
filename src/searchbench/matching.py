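"""Assign participant selections to ground-truth instances.

Scoring works in two steps: a globally optimal one-to-one assignment that
minimizes total Euclidean distance between click points and bbox centers
(rectangular Hungarian assignment), followed by a distance filter that breaks
any matched pair separated by more than the per-trial threshold. The
threshold is the average bbox dimension of the search-class instances in the
trial, which scales the allowed click error with the apparent object size —
images vary in camera altitude, so a fixed pixel radius would be wrong.

No re-assignment pass follows the filter: a selection whose optimal partner
was too far away becomes a false positive even if some other instance is
within threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import Selection, TargetInstance, Trial

__all__ = [
    "MatchResult",
    "compute_match_threshold",
    "optimal_assignment",
    "classify_selections",
    "match_trial",
    "score_cohort",
    "scored_table",
    "brute_force_classify",
]


@dataclass
class MatchResult:
    """TP/FP/FN partition of one participant-trial.

    Every selection lands in exactly one of ``pairs`` / ``fp_selections`` and
    every instance in exactly one of ``pairs`` / ``fn_instances``.
    """

    trial_id: str
    participant_id: str
    pairs: list[tuple[Selection, TargetInstance, float]] = field(default_factory=list)
    fp_selections: list[Selection] = field(default_factory=list)
    fn_instances: list[TargetInstance] = field(default_factory=list)
    threshold: float = float("nan")

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_selections)

    @property
    def fn(self) -> int:
        return len(self.fn_instances)

    @property
    def n_selections(self) -> int:
        return self.tp + self.fp

    @property
    def n_targets(self) -> int:
        return self.tp + self.fn


def compute_match_threshold(
    instances: Sequence[TargetInstance], rule: str = "mean-dim"
) -> float:
    """Per-trial match radius from the search-class instances.

    ``mean-dim`` (default): mean over instances of (width + height) / 2.
    ``sqrt-area``: mean over instances of sqrt(width * height).
    """
    if not instances:
        raise ValueError("cannot compute a match threshold from zero instances")
    if rule == "mean-dim":
        dims = [0.5 * (i.width + i.height) for i in instances]
    elif rule == "sqrt-area":
        dims = [math.sqrt(i.width * i.height) for i in instances]
    else:
        raise ValueError(f"unknown threshold rule: {rule!r}")
    return float(sum(dims) / len(dims))


def _sorted_inputs(
    selections: Sequence[Selection], instances: Sequence[TargetInstance]
) -> tuple[list[Selection], list[TargetInstance]]:
    # deterministic tie-breaking: lowest order_index / instance_id first
    sels = sorted(selections, key=lambda s: (s.order_index, s.t))
    insts = sorted(instances, key=lambda i: i.instance_id)
    return sels, insts


def optimal_assignment(
    selections: Sequence[Selection], instances: Sequence[TargetInstance]
) -> list[tuple[Selection, TargetInstance, float]]:
    """Min-total-distance one-to-one assignment of clicks to instance centers.

    Returns min(|selections|, |instances|) pairs; the surplus side is left
    unassigned. Either side may be empty.
    """
    if not selections or not instances:
        return []
    sels, insts = _sorted_inputs(selections, instances)
    s_xy = np.array([[s.x, s.y] for s in sels])
    g_xy = np.array([[i.cx, i.cy] for i in insts])
    cost = np.linalg.norm(s_xy[:, None, :] - g_xy[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return [(sels[r], insts[c], float(cost[r, c])) for r, c in zip(rows, cols)]


def classify_selections(
    selections: Sequence[Selection],
    instances: Sequence[TargetInstance],
    threshold: float,
    trial_id: str = "",
    participant_id: str = "",
) -> MatchResult:
    """Partition selections/instances into TP pairs, FPs and FNs.

    Pairs from the optimal assignment whose distance exceeds ``threshold``
    are broken: the selection becomes a false positive and the instance a
    false negative.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    result = MatchResult(trial_id=trial_id, participant_id=participant_id,
                         threshold=threshold)
    assigned = optimal_assignment(selections, instances)
    kept_sel_ids = set()
    kept_inst_ids = set()
    for sel, inst, dist in assigned:
        if dist <= threshold:
            result.pairs.append((sel, inst, dist))
            kept_sel_ids.add(id(sel))
            kept_inst_ids.add(id(inst))
    sels, insts = _sorted_inputs(selections, instances)
    result.fp_selections = [s for s in sels if id(s) not in kept_sel_ids]
    result.fn_instances = [i for i in insts if id(i) not in kept_inst_ids]
    return result


def match_trial(
    trial: Trial,
    selections: Sequence[Selection],
    participant_id: str,
    rule: str = "mean-dim",
) -> MatchResult:
    """Score one participant's selections on one trial.

    The threshold is computed per trial from the search-class instances only.
    """
    search_insts = trial.search_instances()
    threshold = compute_match_threshold(search_insts, rule=rule)
    return classify_selections(
        selections, search_insts, threshold,
        trial_id=trial.trial_id, participant_id=participant_id,
    )


def score_cohort(
    trials: Sequence[Trial],
    selections: Sequence[Selection],
    participants: Sequence[str] | None = None,
    rule: str = "mean-dim",
) -> list[MatchResult]:
    """Score every participant-trial cell of a cohort.

    When ``participants`` is given, every participant is assumed to have seen
    every trial, so cells without clicks are scored as blank (all instances
    missed). Otherwise only cells present in the selection log are scored —
    blank trials are invisible in a bare click log.
    """
    by_trial = {t.trial_id: t for t in trials}
    cells: dict[tuple[str, str], list[Selection]] = {}
    for s in selections:
        if s.trial_id not in by_trial:
            raise ValueError(f"selection references unknown trial {s.trial_id}")
        cells.setdefault((s.participant_id, s.trial_id), []).append(s)
    if participants is not None:
        for pid in participants:
            for t in trials:
                cells.setdefault((pid, t.trial_id), [])
    return [
        match_trial(by_trial[tid], sels, participant_id=pid, rule=rule)
        for (pid, tid), sels in sorted(cells.items())
    ]


def scored_table(matches: Sequence[MatchResult],
                 trials: Sequence[Trial]) -> "pd.DataFrame":
    """Long-format scored table: one row per (participant, trial, object).

    TP rows carry both the click and the matched instance, FP rows the click
    only, FN rows the instance only. This is the central artifact the metric,
    model and order stages consume.
    """
    import pandas as pd

    from .io_formats import SCORED_COLUMNS

    by_trial = {t.trial_id: t for t in trials}
    rows = []

    def _row(m: MatchResult, role: str, sel: Selection | None,
             inst: TargetInstance | None, dist: float) -> dict:
        return {
            "participant_id": m.participant_id, "trial_id": m.trial_id,
            "role": role,
            "instance_id": inst.instance_id if inst else None,
            "x": sel.x if sel else np.nan, "y": sel.y if sel else np.nan,
            "t": sel.t if sel else np.nan,
            "order_index": sel.order_index if sel else np.nan,
            "cx": inst.cx if inst else np.nan,
            "cy": inst.cy if inst else np.nan,
            "width": inst.width if inst else np.nan,
            "height": inst.height if inst else np.nan,
            "area": inst.area if inst else np.nan,
            "distance": dist,
            "n_targets": m.n_targets,
            "clarity": inst.clarity if inst else np.nan,
            "color_match": inst.color_match if inst else np.nan,
            "threshold": m.threshold,
        }

    for m in matches:
        if m.trial_id not in by_trial:
            raise ValueError(f"match references unknown trial {m.trial_id}")
        for sel, inst, dist in m.pairs:
            rows.append(_row(m, "TP", sel, inst, dist))
        for sel in m.fp_selections:
            rows.append(_row(m, "FP", sel, None, np.nan))
        for inst in m.fn_instances:
            rows.append(_row(m, "FN", None, inst, np.nan))
    return pd.DataFrame(rows, columns=SCORED_COLUMNS)


def brute_force_classify(
    selections: Sequence[Selection],
    instances: Sequence[TargetInstance],
    threshold: float,
) -> tuple[int, int, int, float]:
    """Exhaustive oracle: best injective mapping, then the distance filter.

    Enumerates every injective mapping of the smaller side into the larger,
    applies the same over-threshold break, and returns (tp, fp, fn,
    total_assignment_distance) for the mapping with minimal total distance.
    Only feasible for small problems; used to validate the Hungarian path.
    """
    ns, ng = len(selections), len(instances)
    if ns == 0 or ng == 0:
        return 0, ns, ng, 0.0
    dist = np.array([[math.hypot(s.x - i.cx, s.y - i.cy) for i in instances]
                     for s in selections])
    k = min(ns, ng)
    best_total, best_pairs = math.inf, ()
    if ns <= ng:
        for cols in itertools.permutations(range(ng), k):
            total = sum(dist[r, c] for r, c in enumerate(cols))
            if total < best_total:
                best_total, best_pairs = total, tuple(enumerate(cols))
    else:
        for rows in itertools.permutations(range(ns), k):
            total = sum(dist[r, c] for c, r in enumerate(rows))
            if total < best_total:
                best_total, best_pairs = total, tuple(
                    (r, c) for c, r in enumerate(rows))
    tp = sum(1 for r, c in best_pairs if dist[r, c] <= threshold)
    return tp, ns - tp, ng - tp, float(best_total)
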