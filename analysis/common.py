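"""Shared configuration for the numbered analysis drivers.

The synthetic study is generated once (driver 01) under ``scratch/run/data``
and every later driver resumes from the stage outputs in the same run
directory.  Seed 7 is the study's documented default; the SOM distortion cut
matches the z-scored nFC scale (see docs/methods.md).
"""

from __future__ import annotations

import json
from pathlib import Path

from ripnet.evaluation import NFC_DISTORTION_CUT
from ripnet.pipeline import PipelineConfig
from ripnet.synthio import SynthConfig

RUN_DIR = Path("scratch/run")
DATA_DIR = RUN_DIR / "data"
RESULTS = Path("results")
SEED = 7


def config(stages, data_dir=None) -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        outdir=str(RUN_DIR),
        data_dir=str(data_dir) if data_dir else None,
        stages=tuple(stages),
        synth=SynthConfig(seed=SEED),
        distortion_cut=NFC_DISTORTION_CUT,
    )


def ground_truth() -> dict:
    return json.loads((DATA_DIR / "ground_truth.json").read_text())


def publish(name: str, payload: dict) -> None:
    """Write one driver's summary table/record under results/."""
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / name).write_text(json.dumps(payload, indent=1, default=str))
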