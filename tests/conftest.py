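import pytest

from metactivity.model_io import MetabolicModel, Metabolite, Reaction
from metactivity.synthetic_data import mini_cholesterol_fixture


@pytest.fixture(scope="session")
def chain_model() -> MetabolicModel:
    """Minimal 3-reaction chain: uptake -> A, A -> B, B -> secretion."""
    return MetabolicModel(
        metabolites=(Metabolite("A"), Metabolite("B")),
        reactions=(
            Reaction("EX_in", {"A": 1.0}, 0.0, 10.0),
            Reaction("r_ab", {"A": -1.0, "B": 1.0}, 0.0, 10.0),
            Reaction("EX_out", {"B": -1.0}, 0.0, 10.0),
        ),
        genes=(),
    )


@pytest.fixture(scope="session")
def cholesterol_model() -> MetabolicModel:
    return mini_cholesterol_fixture()
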