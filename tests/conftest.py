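"""Shared fixtures: one full pipeline run reused by the recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from crac_decay.pipeline import PipelineResult, run_crac_pipeline
from crac_decay.synthetic_data import SimulationConfig

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def pipeline_result() -> PipelineResult:
    """Full CRAC arm at the default study conditions (expensive; run once)."""
    return run_crac_pipeline(SimulationConfig(seed=PIPELINE_SEED))


@pytest.fixture(scope="session")
def top_target_transcripts(pipeline_result) -> set[str]:
    top_genes = set(pipeline_result.ranking.top_genes)
    return {
        t
        for t, m in pipeline_result.sim.models.items()
        if m.gene_id in top_genes
    }


@pytest.fixture(scope="session")
def all_alignments(pipeline_result):
    return pipeline_result.alignments["rep1"] + pipeline_result.alignments["rep2"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
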