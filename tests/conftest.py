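import numpy as np
import pytest

from tibetscan.data_model import HaplotypePanel, site_frequency_table
from tibetscan.simulate import build_model


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture
def toy_panel():
    """Hand-built 6-haplotype, 5-site panel over two populations."""
    alleles = np.array(
        [
            [1, 0, 1, 0, 0],
            [1, 0, 1, 0, 0],
            [0, 1, 1, 0, 0],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 1, 1],
            [0, 0, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    inds = np.array(["t1", "t1", "t2", "h1", "h1", "h2"])
    pops = {"t1": "TIB", "t2": "TIB", "h1": "HAN", "h2": "HAN"}
    return HaplotypePanel(
        chromosome="1",
        positions=np.array([100, 2_000, 50_000, 120_000, 180_000]),
        alleles=alleles,
        haplotype_individuals=inds,
        individual_populations=pops,
    )


@pytest.fixture(scope="session")
def neutral_panel(model):
    """One mid-sized neutral panel shared across tests (seeded)."""
    from tibetscan.simulate import simulate_neutral

    return simulate_neutral(model, sequence_length=300_000, seed=20_240_001)


@pytest.fixture(scope="session")
def archaic_sim(model):
    """Archaic-admixture simulation with tracts, shared across tests."""
    from tibetscan.simulate import ArchaicScenario, AdmixturePulse, simulate_archaic

    scenario = ArchaicScenario(
        pulses=[
            AdmixturePulse(55_000.0, "NEA", "ANC", 0.02),
            AdmixturePulse(40_000.0, "DENI", "HAN", 0.02),
            AdmixturePulse(40_000.0, "DENI", "TIB", 0.02),
        ]
    )
    panel, sft, tracts = simulate_archaic(
        model, scenario, sequence_length=2_000_000, seed=20_240_002
    )
    return panel, sft, tracts, scenario
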