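#!/usr/bin/env python
"""Signed wTO TF networks per condition and day (Pearson, 1000 bootstraps,
probability cut 0.10, RPKM >= 5 background)."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, RUN_DIR, config, publish  # noqa: E402

from ripnet.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    man = run_pipeline(config(stages=("wto",), data_dir=DATA_DIR))
    stage = man["stages"]["wto"]
    sizes = {}
    for f in sorted(RUN_DIR.glob("wto_*_day*.tsv")):
        sizes[f.stem] = len(pd.read_csv(f, sep="\t"))
    summary = {"n_tf_nodes": stage["n_nodes"],
               "n_expressed_background": stage["n_expressed"],
               "significant_links_per_network": sizes}
    publish("04_wto_summary.json", summary)
    print(f"{stage['n_nodes']} TF nodes over {stage['n_expressed']} "
          "expressed background genes")
    for name, n in sizes.items():
        print(f"  {name}: {n} links at p <= 0.10")


if __name__ == "__main__":
    main()
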