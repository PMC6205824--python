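#!/usr/bin/env python
"""High-confidence miRNA targets: WT-specific 3'UTR signal ∩ knockout
up-regulation ∩ annotated-target list, scored against the planted truth."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA_DIR, config, ground_truth, publish  # noqa: E402

from ripnet.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    man = run_pipeline(config(stages=("targets",), data_dir=DATA_DIR))
    stage = man["stages"]["targets"]
    gt = ground_truth()
    hc = set(stage["high_confidence"])
    tgt = set(gt["planted_targets"])
    summary = {
        "venn": stage["venn"],
        "n_high_confidence": len(hc),
        "precision": len(hc & tgt) / len(hc) if hc else 0.0,
        "recall": len(hc & tgt) / len(tgt),
    }
    publish("03_target_filter_summary.json", summary)
    print("Venn:", stage["venn"])
    print(f"high-confidence targets: {len(hc)} "
          f"(precision {summary['precision']:.2f}, recall {summary['recall']:.2f})")


if __name__ == "__main__":
    main()
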