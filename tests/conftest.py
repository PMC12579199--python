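"""Shared fixtures: one default synthetic cohort per session, plus the full
pipeline report computed on it."""

from __future__ import annotations

import pytest
from hypothesis import settings

from ptriage.config import PipelineConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from ptriage.io import load_cohort
from ptriage.pipeline import run_pipeline
from ptriage.simulate import CohortConfig, generate_cohort

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    generate_cohort(CohortConfig(seed=DEFAULT_SEED), out_dir=d)
    return d


@pytest.fixture(scope="session")
def cohort(cohort_dir):
    return load_cohort(cohort_dir)


@pytest.fixture(scope="session")
def pipeline_report(cohort):
    cfg = PipelineConfig(seed=DEFAULT_SEED)
    cfg.excluded_project = "cell_line_cohort"
    return run_pipeline(cfg, cohort)


@pytest.fixture(scope="session")
def curation_results(cohort):
    from ptriage.curation import CurationEngine

    engine = CurationEngine(
        transcripts=cohort.transcripts,
        reference=cohort.reference,
        pext=cohort.pext,
        splice=cohort.splice,
        genotypes=cohort.genotypes,
        variants=cohort.variants,
    )
    return engine.curate_all()
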