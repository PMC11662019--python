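import pytest

from chromkit.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic configuration.

    Shared across tests that check different facets of the same run.
    Returns (report, output directory).
    """
    out = tmp_path_factory.mktemp("pipeline_default")
    report = run_all(PipelineConfig(outdir=str(out), seed=1))
    return report, out
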