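"""Simulate the demo EEG cohort and write it to disk.

Generates a miniature three-group cohort (healthy controls, responding
and non-responding depressed patients) from the shared demo
configuration: per-subject label paths with class-specific dwell times,
rendered into 19-channel recordings, plus the HAMD-24 outcome table.
"""
from pathlib import Path

from eegstates.io import read_metadata
from eegstates.pipeline import load_config, stage_simulate

HERE = Path(__file__).resolve().parent
RUN_DIR = HERE.parent / "scratch" / "demo_run"   # bulky intermediates
RESULTS = HERE.parent / "results"


def main() -> None:
    config = load_config(HERE / "demo_config.yaml")
    out = stage_simulate(config, RUN_DIR)
    meta = read_metadata(out / "metadata.csv")
    print(meta.groupby("group")[["hamd_baseline", "hamd_post"]]
          .agg(["mean", "count"]).round(2))
    print(f"\nwrote {len(meta)} recordings under {out}")


if __name__ == "__main__":
    main()
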