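#!/usr/bin/env python
"""Correlate the day-4 WT profile (top day-4-vs-day-0 DE genes) against the
region x age atlas and apply the two-SD match rule."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, RUN_DIR, config, ground_truth, publish  # noqa: E402

from ripnet.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    man = run_pipeline(config(stages=("atlas",), data_dir=DATA_DIR))
    sig = [tuple(s) for s in man["stages"]["atlas"]["significant"]]
    gt = ground_truth()
    truth = (str(gt["atlas_block"][0]), int(gt["atlas_block"][1]))
    calls = pd.read_csv(RUN_DIR / "atlas_calls.tsv", sep="\t")
    best = calls.sort_values("r", ascending=False).iloc[0]
    summary = {"significant_calls": sig,
               "planted_block": list(truth),
               "unique_correct": len(sig) == 1
               and (str(sig[0][0]), int(sig[0][1])) == truth,
               "best_r": float(best["r"])}
    publish("07_atlas_summary.json", summary)
    print(f"significant (region, age) calls: {sig}; planted block: {truth}; "
          f"best r = {best['r']:.3f}")


if __name__ == "__main__":
    main()
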