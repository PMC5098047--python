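import warnings

import pytest

from ptmfp.pipeline import PipelineConfig, run_pipeline
from ptmfp.simulate import SimulationConfig, simulate_dataset
from ptmfp.types import FamilyAlignment, ProteinEntry, PTMObservation


@pytest.fixture
def toy_alignment():
    """Four members, hand-traceable gapping."""
    return FamilyAlignment(
        "FAMX",
        [
            ("P1", "A-CDS"),
            ("P2", "ACCDS"),
            ("P3", "A-CDT"),
            ("P4", "AKC-S"),
        ],
    )


@pytest.fixture
def toy_entries(toy_alignment):
    return {
        uid: ProteinEntry(uid, row.replace("-", ""), "FAMX")
        for uid, row in toy_alignment.members
    }


def make_obs(uid, pos, residue, ptm_type="Phosphorylation", known=False, sources=0):
    return PTMObservation(uid, pos, residue, ptm_type, known, sources)


@pytest.fixture(scope="session")
def demo_dataset():
    """The default synthetic world: 12 families, seeded."""
    return simulate_dataset(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory, demo_dataset):
    """One full pipeline run on the demo world, shared across tests."""
    root = tmp_path_factory.mktemp("demo_run")
    inputs = root / "inputs"
    demo_dataset.write(inputs)
    config = PipelineConfig(input_dir=str(inputs), out_dir=str(root / "out"), seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(config, until="variants")
    return config, result
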