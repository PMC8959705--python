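"""Shared fixtures: a session-wide pipeline run and small synthetic inputs."""

import pytest

from synergyscreen import PipelineConfig, SynthConfig, run_pipeline
from synergyscreen.synthetic import generate_inputs


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-scale pipeline run (seed 1), reused across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(out_dir=str(out), seed=1)
    summary = run_pipeline(config)
    return config, summary


@pytest.fixture(scope="session")
def small_config():
    """A reduced generator configuration for fast unit tests."""
    return SynthConfig(
        seed=11, n_prescriptions=2, herbs_per_prescription=(2, 3),
        compounds_per_herb=(3, 5), n_gene_universe=300,
        n_targets_universe=120, targets_per_compound=(5, 15),
        n_pathological_genes=60, n_gene_sets=24, gene_set_size=(5, 30))


@pytest.fixture(scope="session")
def small_inputs(small_config):
    return generate_inputs(small_config)
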