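"""The whole protocol end to end on a synthetic 3-day time-lapse.

Generates 144 frames (30-min cadence, diel fish counts, occasional daytime
turbidity), then runs calibrate -> screen -> count -> rhythm analysis from
one RunConfig and prints the summary, comparing against the generator truth.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from reefwatch import RunConfig, run_pipeline
from reefwatch.synthetic import (
    DielProfile, SceneSpec, default_center_region, generate_sequence,
)

root = Path(tempfile.mkdtemp(prefix="reefwatch_"))
spec = SceneSpec(noise_sigma=2.0)
profile = DielProfile(day_mean=6.0, night_mean=1.0, turbidity_rate=0.12)
truth = generate_sequence(root / "frames", spec=spec, profile=profile,
                          days=3, seed=5)
training = truth.loc[truth.turbidity == 0, "filename"][::6].head(24).tolist()

config = RunConfig(
    image_dir=root / "frames",
    chart=spec.chart,
    center_region=default_center_region(),
    roi=spec.roi,
    training_ids=training,
    out_dir=root / "results",
)
summary = run_pipeline(config)

for key, value in summary.items():
    print(f"{key:26s}: {value}")
counts = pd.read_csv(root / "results" / "counts.csv").merge(
    truth, left_on="image_id", right_on="filename")
exact = (counts["count"] == counts["true_count"]).mean()
print(f"{'exact count recovery':26s}: {exact:.2%} of selected frames")
print(f"outputs in {root / 'results'}")
# Expect: most frames selected (turbid ones discarded), peak period 1440 min,
# onset near 08:00, and near-perfect per-frame count recovery.
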