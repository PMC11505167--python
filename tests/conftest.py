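"""Shared fixtures.

The expensive fixture is ``pipeline_run``: one full desk-scale pipeline
execution (tokenize -> span-MLM pre-training -> embed -> UMAP -> TNF -> NMF
-> fuse -> adaptive DBSCAN) on a 150-contig synthetic community. It is
session-scoped so the end-to-end, feature-width, embedding-separation and
mode-comparison tests all share a single ~4-minute run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tetrabin.io import GroundTruth
from tetrabin.pipeline import PipelineConfig, PipelineResult, run_all
from tetrabin.simulate import CommunityConfig, simulate_community
from tetrabin.tokenizer import build_vocabulary

# umap/numba emit benign warnings about seeds and parallelism
warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary()


@pytest.fixture(scope="session")
def community(tmp_path_factory):
    """Well-separated 3-genome community (150 contigs) with its truth table."""
    out_dir = tmp_path_factory.mktemp("community")
    contigs, truth = simulate_community(CommunityConfig(seed=1), out_dir=out_dir)
    return contigs, truth, out_dir


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline_run(community, pipeline_config, tmp_path_factory) -> tuple[PipelineResult, GroundTruth]:
    contigs, truth, out_dir = community
    work_dir = tmp_path_factory.mktemp("pipeline_work")
    result = run_all(out_dir / "contigs.fasta", work_dir, config=pipeline_config, truth=truth)
    return result, truth
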