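import pytest

from ascoedit.io_formats import GeneModel, Segment
from ascoedit.pipeline import evaluate_recovery, run_simulated_study
from ascoedit.simulate import SimulationConfig


@pytest.fixture
def simple_model() -> GeneModel:
    """12-base gene: 5'UTR 1-3, CDS 4-9 (ATG TGA), 3'UTR 10-12."""
    return GeneModel(
        "g1",
        "CCTATGTGAAAA",
        (Segment("five_utr", 1, 3), Segment("cds", 4, 9), Segment("three_utr", 10, 12)),
    )


@pytest.fixture
def spliced_model() -> GeneModel:
    """Gene with an intron splitting the CDS: CDS 4-6 + 10-12, intron 7-9."""
    return GeneModel(
        "g2",
        "CCTATGGTAGAATTTTAA",
        (
            Segment("five_utr", 1, 3),
            Segment("cds", 4, 6),
            Segment("intron", 7, 9),
            Segment("cds", 10, 12),
            Segment("three_utr", 13, 18),
        ),
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by pipeline-level tests."""
    cfg = SimulationConfig(
        n_genes=12,
        n_specific_sites=8,
        n_stop_loss_sites=2,
        n_background_sites=24,
        n_reference_errors=2,
    )
    study, result = run_simulated_study(cfg, seed=7)
    return study, result, evaluate_recovery(study, result)
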