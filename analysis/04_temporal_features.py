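"""Convert segmentations into the 24 per-subject microstate features.

Duration (ms), occurrence (1/s) and contribution per class A-D plus the
12 segment-wise transition probabilities, one row per subject, written
as the cohort feature table that the statistics and prediction stages
consume.
"""
from pathlib import Path

import pandas as pd

from eegstates.pipeline import load_config, stage_params

HERE = Path(__file__).resolve().parent
RUN_DIR = HERE.parent / "scratch" / "demo_run"   # bulky intermediates
RESULTS = HERE.parent / "results"


def main() -> None:
    config = load_config(HERE / "demo_config.yaml")
    out = stage_params(config, RUN_DIR)
    table = pd.read_csv(out)
    summary = table.groupby("group")[
        ["Duration_A", "Duration_B", "Duration_C", "Duration_D"]].mean().round(1)
    print("mean microstate durations (ms) per group:")
    print(summary)
    print("\nNote the graded microstate-D reduction planted in the patient "
          "groups (NRP < RP < HC).")
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "features.csv", index=False)
    print(f"wrote {RESULTS / 'features.csv'}")


if __name__ == "__main__":
    main()
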