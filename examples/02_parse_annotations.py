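"""Parse DOTA-style annotation files and a click log from disk.

Real data enters the pipeline as (a) one annotation file per image in the
DOTA text format — four corner points, a class label, and a difficulty
flag per line — and (b) a CSV click log with one row per selection.
This example writes small files inline and reads them back.
"""

import tempfile
from pathlib import Path

from searchbench import read_dota_annotations, read_selection_log
from searchbench.matching import classify_selections, compute_match_threshold

workdir = Path(tempfile.mkdtemp())

# -- annotations --------------------------------------------------------------
# Corner order is x1 y1 ... x4 y4; the parser takes the centroid and the
# axis-aligned extents, skips imagesource/gsd headers, and drops classes
# outside the searchable vocabulary (harbor, bridge).
ann = workdir / "P0001.txt"
ann.write_text(
    "imagesource:GoogleEarth\n"
    "gsd:0.146\n"
    "100 100 160 100 160 160 100 160 plane 0\n"
    "300 420 380 420 380 500 300 500 plane 0\n"
    "10 10 60 10 60 40 10 40 harbor 1\n"
)
trial = read_dota_annotations(ann, trial_id="P0001", coords="screen",
                              image_side=800.0)
instances = trial.instances
print(f"search class: {trial.search_class}")
for i in instances:
    print(f"{i.instance_id}: center ({i.cx:.0f}, {i.cy:.0f}), "
          f"{i.width:.0f}x{i.height:.0f} px, class {i.class_label}")

# -- click log ----------------------------------------------------------------
# Clicks get 1-based order indices per (participant, trial) by timestamp.
log = workdir / "clicks.csv"
log.write_text(
    "participant_id,trial_id,x,y,t\n"
    "w1,P0001,128,132,3.1\n"     # near the first plane (screen coords)
    "w1,P0001,650,200,7.9\n"     # nowhere near anything
    "w1,P0001,338,458,5.2\n"     # near the second plane
)
selections = read_selection_log(log, coords="screen", image_side=800.0)
for s in selections:
    print(f"click #{s.order_index} at ({s.x:.0f}, {s.y:.0f}), t={s.t}s")

# -- matching -----------------------------------------------------------------
# The per-trial threshold is the mean of (width + height) / 2 over the
# search-class instances; assignment happens first, the filter second.
threshold = compute_match_threshold(instances)
result = classify_selections(selections, instances, threshold)
print(f"threshold {threshold:.1f} px -> "
      f"TP={result.tp} FP={result.fp} FN={result.fn}")
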