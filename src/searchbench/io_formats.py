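"""Data model and file I/O for point-click visual-search experiments.

The pipeline never touches image pixels: a trial is fully described by its
annotated ground-truth objects (bounding-box centers and extents) and the
point selections participants made on it.

Coordinate convention
---------------------
Internally all coordinates are image-Cartesian: the origin is the bottom-left
corner of the image and y increases upward, so the 3x3 analysis grid is
numbered from the bottom-left. Readers accept ``coords="screen"`` for sources
recorded with a top-left origin (y down) and convert via ``y' = image_side - y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "COLOR_VOCABULARY",
    "TargetInstance",
    "Selection",
    "Trial",
    "read_dota_annotations",
    "read_selection_log",
    "write_selection_log",
    "write_trials_table",
    "read_trials_table",
    "write_scored_table",
    "read_scored_table",
]

#: Fixed color vocabulary used for template / instance color ratings.
#: The rating scale offered eleven named colors plus "unknown".
COLOR_VOCABULARY: tuple[str, ...] = (
    "red", "orange", "yellow", "green", "blue", "purple",
    "pink", "brown", "black", "white", "gray",
)

MAX_INSTANCES_PER_TRIAL = 30
DEFAULT_CLASS_EXCLUSIONS = frozenset({"harbor", "bridge"})


@dataclass
class TargetInstance:
    """One annotated ground-truth object, represented by its bbox center."""

    instance_id: str
    trial_id: str
    cx: float
    cy: float
    width: float
    height: float
    class_label: str
    color_label: str = "unknown"
    clarity: int | None = None
    color_match: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"instance {self.instance_id}: non-positive extent "
                f"({self.width} x {self.height})"
            )
        if self.clarity is not None and self.clarity not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"instance {self.instance_id}: clarity {self.clarity} not in 1..5"
            )

    @property
    def area(self) -> float:
        """Bounding-box area in pixels squared."""
        return self.width * self.height

    @property
    def mean_dimension(self) -> float:
        """Average of the two bbox side lengths, (w + h) / 2, in pixels."""
        return 0.5 * (self.width + self.height)


@dataclass
class Selection:
    """One participant click: where, when, and in what order."""

    participant_id: str
    trial_id: str
    x: float
    y: float
    t: float
    order_index: int = 0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(
                f"selection by {self.participant_id} on {self.trial_id}: "
                f"negative timestamp {self.t}"
            )


@dataclass
class Trial:
    """One search trial: an image-sized canvas plus its ground-truth objects."""

    trial_id: str
    search_class: str
    instances: list[TargetInstance] = field(default_factory=list)
    image_side: float = 800.0
    template_clarity: int | None = None
    template_color: str | None = None
    difficulty_rating: float | None = None

    def __post_init__(self) -> None:
        if len(self.instances) > MAX_INSTANCES_PER_TRIAL:
            raise ValueError(
                f"trial {self.trial_id}: {len(self.instances)} instances exceeds "
                f"the maximum of {MAX_INSTANCES_PER_TRIAL}"
            )

    @property
    def n_targets(self) -> int:
        return len(self.instances)

    def search_instances(self) -> list[TargetInstance]:
        """Instances belonging to the trial's search class."""
        return [i for i in self.instances if i.class_label == self.search_class]


# ---------------------------------------------------------------------------
# DOTA-style annotation text format: one object per line,
#   x1 y1 x2 y2 x3 y3 x4 y4 class difficult
# ---------------------------------------------------------------------------

def _parse_dota_line(line: str, lineno: int) -> tuple[float, float, float, float, str]:
    tokens = line.split()
    if len(tokens) != 10:
        raise ValueError(
            f"line {lineno}: expected 10 tokens (8 coordinates, class, "
            f"difficulty), got {len(tokens)}"
        )
    try:
        coords = [float(v) for v in tokens[:8]]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric coordinate: {exc}") from None
    xs, ys = coords[0::2], coords[1::2]
    cx = sum(xs) / 4.0
    cy = sum(ys) / 4.0
    width = max(xs) - min(xs)
    height = max(ys) - min(ys)
    if width <= 0 or height <= 0:
        raise ValueError(f"line {lineno}: degenerate polygon (zero extent)")
    return cx, cy, width, height, tokens[8]


def read_dota_annotations(
    path,
    image_side: float = 800.0,
    class_exclusions: Iterable[str] = DEFAULT_CLASS_EXCLUSIONS,
    search_class: str | None = None,
    trial_id: str | None = None,
    coords: str = "screen",
) -> Trial:
    """Parse one DOTA-style annotation file into a Trial.

    Each line holds the four polygon corners of one object, its class label
    and a difficulty flag (parsed but unused). The bbox center is the mean of
    the corner coordinates and width/height are the axis-aligned extents of
    the polygon. Instances of excluded classes are dropped. DOTA files are
    recorded in screen coordinates (y down); pass ``coords="cartesian"`` if
    the source is already y-up.
    """
    if coords not in ("screen", "cartesian"):
        raise ValueError(f"unknown coordinate convention: {coords!r}")
    exclusions = {c.lower() for c in class_exclusions}
    path = str(path)
    tid = trial_id if trial_id is not None else path
    instances: list[TargetInstance] = []
    classes_seen: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("imagesource", "gsd")):
                continue
            cx, cy, w, h, cls = _parse_dota_line(line, lineno)
            if cls.lower() in exclusions:
                continue
            if coords == "screen":
                cy = image_side - cy
            classes_seen.append(cls)
            instances.append(
                TargetInstance(
                    instance_id=f"{tid}:{len(instances)}",
                    trial_id=tid,
                    cx=cx, cy=cy, width=w, height=h, class_label=cls,
                )
            )
    if search_class is None:
        # default to the most common remaining class
        if not classes_seen:
            raise ValueError(f"{path}: no instances remain after exclusions")
        search_class = max(set(classes_seen), key=classes_seen.count)
    return Trial(trial_id=tid, search_class=search_class,
                 instances=instances, image_side=image_side)


# ---------------------------------------------------------------------------
# Selection logs and tabular round-trips (CSV)
# ---------------------------------------------------------------------------

_SELECTION_COLUMNS = ["participant_id", "trial_id", "x", "y", "t"]


def read_selection_log(path, coords: str = "cartesian",
                       image_side: float = 800.0) -> list[Selection]:
    """Read a CSV of clicks and assign 1-based order indices by timestamp.

    Order within a (participant, trial) cell follows ascending timestamp;
    ties keep file order. Rows with missing or non-numeric fields are
    rejected with their row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SELECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    selections: list[Selection] = []
    for idx, row in df.iterrows():
        try:
            x, y, t = float(row["x"]), float(row["y"]), float(row["t"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: row {idx + 1}: non-numeric coordinate "
                             f"or timestamp") from None
        if pd.isna(x) or pd.isna(y) or pd.isna(t):
            raise ValueError(f"{path}: row {idx + 1}: missing value")
        if coords == "screen":
            y = image_side - y
        selections.append(Selection(str(row["participant_id"]),
                                    str(row["trial_id"]), x, y, t))
    return assign_order_indices(selections)


def assign_order_indices(selections: Sequence[Selection]) -> list[Selection]:
    """Return selections with order_index = click order within each cell."""
    out: list[Selection] = []
    df = pd.DataFrame({
        "cell": [(s.participant_id, s.trial_id) for s in selections],
        "t": [s.t for s in selections],
        "pos": range(len(selections)),
    })
    for _, grp in df.groupby("cell", sort=False):
        grp = grp.sort_values(["t", "pos"], kind="stable")
        for k, pos in enumerate(grp["pos"], start=1):
            out.append(replace(selections[pos], order_index=k))
    out.sort(key=lambda s: (s.participant_id, s.trial_id, s.order_index))
    return out


def write_selection_log(selections: Sequence[Selection], path) -> None:
    df = pd.DataFrame(
        [(s.participant_id, s.trial_id, s.x, s.y, s.t) for s in selections],
        columns=_SELECTION_COLUMNS,
    )
    df.to_csv(path, index=False)


_TRIAL_COLUMNS = [
    "trial_id", "search_class", "image_side", "template_clarity",
    "template_color", "difficulty_rating", "instance_id", "cx", "cy",
    "width", "height", "class_label", "color_label", "clarity", "color_match",
]


def write_trials_table(trials: Sequence[Trial], path) -> None:
    """Write trials as a flat instance table (one row per instance)."""
    rows = []
    for tr in trials:
        for inst in tr.instances:
            rows.append((tr.trial_id, tr.search_class, tr.image_side,
                         tr.template_clarity, tr.template_color,
                         tr.difficulty_rating, inst.instance_id, inst.cx,
                         inst.cy, inst.width, inst.height, inst.class_label,
                         inst.color_label, inst.clarity, inst.color_match))
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path, index=False)


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def read_trials_table(path) -> list[Trial]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    trials: list[Trial] = []
    for tid, grp in df.groupby("trial_id", sort=False):
        head = grp.iloc[0]
        instances = [
            TargetInstance(
                instance_id=str(r["instance_id"]), trial_id=str(tid),
                cx=float(r["cx"]), cy=float(r["cy"]),
                width=float(r["width"]), height=float(r["height"]),
                class_label=str(r["class_label"]),
                color_label=str(r["color_label"]),
                clarity=_opt_int(r["clarity"]),
                color_match=_opt_int(r["color_match"]),
            )
            for _, r in grp.iterrows()
        ]
        trials.append(Trial(
            trial_id=str(tid), search_class=str(head["search_class"]),
            instances=instances, image_side=float(head["image_side"]),
            template_clarity=_opt_int(head["template_clarity"]),
            template_color=(None if pd.isna(head["template_color"])
                            else str(head["template_color"])),
            difficulty_rating=(None if pd.isna(head["difficulty_rating"])
                               else float(head["difficulty_rating"])),
        ))
    return trials


# ---------------------------------------------------------------------------
# Scored long table: one row per (participant, trial, object) with its role
# ---------------------------------------------------------------------------

SCORED_COLUMNS = [
    "participant_id", "trial_id", "role", "instance_id", "x", "y", "t",
    "order_index", "cx", "cy", "width", "height", "area", "distance",
    "n_targets", "clarity", "color_match", "threshold",
]


def write_scored_table(scored: pd.DataFrame, path) -> None:
    """Write the long-format scored table (role in {TP, FP, FN}) to CSV."""
    missing = [c for c in SCORED_COLUMNS if c not in scored.columns]
    if missing:
        raise ValueError(f"scored table missing column(s) {missing}")
    scored.loc[:, SCORED_COLUMNS].to_csv(path, index=False)


def read_scored_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str,
                                  "instance_id": str},
                     float_precision="round_trip")
    bad = set(df["role"].dropna()) - {"TP", "FP", "FN"}
    if bad:
        raise ValueError(f"{path}: unknown role value(s) {sorted(bad)}")
    return df
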