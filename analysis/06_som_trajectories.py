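#!/usr/bin/env python
"""Cluster persistently differentially expressed TFs by their normalized
fold-change trajectories with a growing SOM, and score against the planted
shape labels."""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, RUN_DIR, config, ground_truth, publish  # noqa: E402

from ripnet.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    man = run_pipeline(config(stages=("som",), data_dir=DATA_DIR))
    stage = man["stages"]["som"]
    gt = ground_truth()
    member = pd.read_csv(RUN_DIR / "som_membership.tsv", sep="\t", index_col=0)
    labels = [gt["planted_clusters"][g] for g in member.index]
    ari = float(adjusted_rand_score(labels, member["unit"].to_numpy()))
    summary = {"grid": stage["grid"],
               "avg_distortion": stage["avg_distortion"],
               "n_persistent_tfs": stage["n_tfs"],
               "ari_vs_planted_shapes": ari}
    publish("06_som_summary.json", summary)
    print(f"{stage['n_tfs']} persistently DE TFs on a "
          f"{stage['grid'][0]}x{stage['grid'][1]} grid "
          f"(distortion {stage['avg_distortion']:.3f}); "
          f"ARI vs planted shapes: {ari:.2f}")


if __name__ == "__main__":
    main()
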