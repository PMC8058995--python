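import pytest

from lilimir.pipeline import run_pipeline
from lilimir.simulate import SimConfig, generate_reference


@pytest.fixture(scope="session")
def bundle():
    """Default five-stage synthetic study bundle."""
    return generate_reference(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A minimal bundle for focused single-site / degenerate tests."""
    cfg = SimConfig(
        seed=7, n_transcripts=14, n_known_mirnas=6, n_novel_mirnas=2,
        n_decoy_hairpins=2, n_target_sites=1, library_depth=4000,
    )
    return generate_reference(cfg)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """Full end-to-end run over the default bundle (shared across tests)."""
    return run_pipeline(bundle)
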