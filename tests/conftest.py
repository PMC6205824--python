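"""Shared fixtures: one default synthetic study per session.

The default configuration (seed 7) is generated once and reused read-only
across test modules; tests that need other conditions build their own
configs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from ripnet.containers import ExpressionMatrix
from ripnet.synthio import SynthConfig, gen_expression, gen_mirna_counts, gen_pileups


@pytest.fixture(scope="session")
def cfg() -> SynthConfig:
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def pileup_data(cfg):
    return gen_pileups(cfg)


@pytest.fixture(scope="session")
def expression_data(cfg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_expression(cfg)


@pytest.fixture(scope="session")
def mirna_data(cfg):
    return gen_mirna_counts(cfg)


@pytest.fixture()
def small_expr() -> ExpressionMatrix:
    """Tiny deterministic two-condition matrix for arithmetic checks."""
    genes = ["g1", "g2", "g3"]
    cols = [f"{c}_t0_r{r}" for c in ("WT", "KO") for r in (1, 2, 3)]
    vals = pd.DataFrame(
        [[10.0, 10, 10, 20, 20, 20],
         [5.0, 6, 7, 5, 6, 7],
         [0.0, 0, 0, 0, 0, 0]],
        index=genes, columns=cols)
    samples = pd.DataFrame(
        {"condition": ["WT"] * 3 + ["KO"] * 3,
         "timepoint": [0] * 6,
         "replicate": [1, 2, 3, 1, 2, 3]}, index=cols)
    return ExpressionMatrix(vals, samples)


def make_expr(values: np.ndarray, genes, condition="A", timepoint=0) -> ExpressionMatrix:
    """One-group ExpressionMatrix around a plain array (genes x samples)."""
    n = values.shape[1]
    cols = [f"{condition}_t{timepoint}_r{i + 1}" for i in range(n)]
    vals = pd.DataFrame(values, index=list(genes), columns=cols)
    samples = pd.DataFrame({"condition": [condition] * n,
                            "timepoint": [timepoint] * n,
                            "replicate": list(range(1, n + 1))}, index=cols)
    return ExpressionMatrix(vals, samples)
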