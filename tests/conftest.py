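import numpy as np
import pytest

from netpharm.model import (
    Biomarker,
    DockingScoreMatrix,
    Enzyme,
    Pathway,
    StudyBundle,
    TargetProtein,
)
from netpharm.simulate import FixtureSpec, SimulationSpec, gen_fixture_network, gen_study


@pytest.fixture
def toy_bundle() -> StudyBundle:
    """3 biomarkers / 2 enzymes / 2 targets; clean under validate_study."""
    biomarkers = {
        "HMDB0000001": Biomarker("HMDB0000001", "alpha", "GC-MS", "up"),
        "HMDB0000002": Biomarker("HMDB0000002", "beta", "LC-MS", "down"),
        "HMDB0000003": Biomarker("HMDB0000003", "gamma", "1H-NMR", "down"),
    }
    enzymes = {
        "P12345": Enzyme("P12345", "enzyme one", frozenset({"Hydrolase"})),
        "Q00001": Enzyme("Q00001", "enzyme two", frozenset({"Transferase", "Acyltransferase"})),
    }
    relations = [
        ("HMDB0000001", "P12345"),
        ("HMDB0000002", "P12345"),
        ("HMDB0000003", "Q00001"),
    ]
    targets = {
        "P04637": TargetProtein("P04637", "t-one", frozenset({"nervous"})),
        "P01375": TargetProtein("P01375", "t-two", frozenset({"nervous", "immune", "endocrine"})),
    }
    scores = DockingScoreMatrix(
        ["HMDB0000001", "HMDB0000002", "HMDB0000003"],
        ["P01375", "P04637"],
        np.array([[6.1, 5.0], [4.2, 7.3], [5.53, np.nan]]),
    )
    pathways = {
        "hsa00001": Pathway("hsa00001", "toy pathway", frozenset({"P04637", "P01375"})),
    }
    return StudyBundle(biomarkers=biomarkers, enzymes=enzymes, relations=relations,
                       targets=targets, scores=scores, pathways=pathways)


@pytest.fixture(scope="session")
def default_study() -> StudyBundle:
    return gen_study(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def nervous_fixture_net():
    return gen_fixture_network(FixtureSpec(13, 78, 232, seed=7))
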