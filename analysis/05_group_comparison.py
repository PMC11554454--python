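"""Compare microstate features between controls and patients.

Runs per-feature pooled t-tests (HC vs all depressed subjects) with
Benjamini-Hochberg FDR adjustment across the 24 features, and Pearson
correlations of each feature with the baseline HAMD-24 score within the
patient group.
"""
from pathlib import Path

import pandas as pd

from eegstates.pipeline import load_config, stage_stats

HERE = Path(__file__).resolve().parent
RUN_DIR = HERE.parent / "scratch" / "demo_run"   # bulky intermediates
RESULTS = HERE.parent / "results"


def main() -> None:
    config = load_config(HERE / "demo_config.yaml")
    out = stage_stats(config, RUN_DIR)
    comparison = pd.read_csv(out)
    hits = comparison[comparison["significant"]]
    print("features significant after FDR (HC vs PSD):")
    print(hits[["parameter", "t", "p", "p_fdr"]].round(4).to_string(index=False))
    RESULTS.mkdir(exist_ok=True)
    comparison.to_csv(RESULTS / "comparison.csv", index=False)
    pd.read_csv(RUN_DIR / "correlation.csv").to_csv(
        RESULTS / "correlation.csv", index=False)
    print(f"\nfull tables: {RESULTS / 'comparison.csv'} and "
          f"{RESULTS / 'correlation.csv'}")


if __name__ == "__main__":
    main()
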